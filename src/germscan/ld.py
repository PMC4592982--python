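"""Two-locus linkage disequilibrium on haploid-coded inbred genotypes.

Because accessions are het-masked homozygous inbreds, each accession called
at both loci of a pair contributes one observed two-locus haplotype — no EM
phasing is needed.  From the 2x2 haplotype counts the module computes r²,
D′, and a normalized-likelihood confidence interval for |D′| on a grid
(allele frequencies profiled at their sample estimates, the
Haploview/Gabriel convention), then classifies each pair:

* ``strong_ld``      — CI upper bound > 0.98 and lower bound > 0.7
* ``strong_recomb``  — CI upper bound < 0.9
* ``inconclusive``   — anything else
* ``uninformative``  — no joint calls or a locus monomorphic in the pair's
  subsample

Pairs are evaluated within a bp window along each chromosome; binned decay
curves and the empirical half-decay distance summarise the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import ALT_HOM, HET, MISSING, REF_HOM, GenotypeMatrix

STRONG_LD = "strong_ld"
STRONG_RECOMB = "strong_recomb"
INCONCLUSIVE = "inconclusive"
UNINFORMATIVE = "uninformative"

#: half-decay never reached within the curve's distance range
NOT_REACHED = math.inf

CI_GRID_STEP = 0.001

PAIR_COLUMNS = [
    "chromosome", "locus_a", "locus_b", "pos_a", "pos_b", "dist",
    "r2", "dprime", "ci_low", "ci_high", "pair_class",
    "region_a", "region_b",
]


@dataclass(frozen=True)
class HaplotypeCounts2:
    """Two-locus haplotype counts (nAB, nAb, naB, nab) over jointly called accessions."""

    nAB: int
    nAb: int
    naB: int
    nab: int

    @property
    def n(self) -> int:
        return self.nAB + self.nAb + self.naB + self.nab


def hap_counts(g: GenotypeMatrix, locus_a: str, locus_b: str) -> HaplotypeCounts2:
    """Count observed two-locus haplotypes; allele "A"/"B" denotes ALT at each locus."""
    if (g.calls == HET).any():
        raise ValueError("hap_counts requires het-masked input")
    ids = g.loci["locus_id"]
    ia = int(np.flatnonzero(ids == locus_a)[0])
    ib = int(np.flatnonzero(ids == locus_b)[0])
    if g.loci.iloc[ia]["chromosome"] != g.loci.iloc[ib]["chromosome"]:
        raise ValueError("locus pair must be on the same chromosome")
    a = g.calls[:, ia]
    b = g.calls[:, ib]
    both = (a != MISSING) & (b != MISSING)
    a_alt = a[both] == ALT_HOM
    b_alt = b[both] == ALT_HOM
    return HaplotypeCounts2(
        nAB=int(np.sum(a_alt & b_alt)),
        nAb=int(np.sum(a_alt & ~b_alt)),
        naB=int(np.sum(~a_alt & b_alt)),
        nab=int(np.sum(~a_alt & ~b_alt)),
    )


def ld_stats(c: HaplotypeCounts2) -> tuple[float, float]:
    """(r², D′) from haplotype counts; raises on an uninformative pair."""
    n = c.n
    if n == 0:
        raise ValueError("uninformative pair: no joint calls")
    pA = (c.nAB + c.nAb) / n
    pB = (c.nAB + c.naB) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("uninformative pair: monomorphic in subsample")
    d = c.nAB / n - pA * pB
    r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    if d > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif d < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return r2, 0.0
    return r2, abs(d) / dmax


def dprime_ci(
    c: HaplotypeCounts2, confidence: float = 0.95, grid_step: float = CI_GRID_STEP
) -> tuple[float, float]:
    """Normalized-likelihood percentile CI for |D′| on a [0, 1] grid.

    Alleles are relabelled so the observed D is nonnegative; the multinomial
    likelihood of the four counts is evaluated at each grid value of D′ with
    allele frequencies fixed at their sample estimates, normalized to sum 1,
    and the (1−confidence) and confidence percentiles of the resulting curve
    are returned.
    """
    n = c.n
    if n == 0:
        raise ValueError("uninformative pair: no joint calls")
    pA = (c.nAB + c.nAb) / n
    pB = (c.nAB + c.naB) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("uninformative pair: monomorphic in subsample")
    nAB, nAb, naB, nab = c.nAB, c.nAb, c.naB, c.nab
    if nAB / n - pA * pB < 0:  # flip the B labels so D >= 0
        nAB, nAb = nAb, nAB
        naB, nab = nab, naB
        pB = 1 - pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    dd = grid * dmax
    pAB = np.clip(pA * pB + dd, 1e-12, None)
    pAb = np.clip(pA * (1 - pB) - dd, 1e-12, None)
    paB = np.clip((1 - pA) * pB - dd, 1e-12, None)
    pab = np.clip((1 - pA) * (1 - pB) + dd, 1e-12, None)
    loglik = (
        nAB * np.log(pAB) + nAb * np.log(pAb) + naB * np.log(paB) + nab * np.log(pab)
    )
    lik = np.exp(loglik - loglik.max())
    cum = np.cumsum(lik) / lik.sum()
    lo_idx = int(np.searchsorted(cum, 1 - confidence))
    hi_idx = int(np.searchsorted(cum, confidence))
    return float(grid[min(lo_idx, len(grid) - 1)]), float(grid[min(hi_idx, len(grid) - 1)])


def classify_pair(ci_low: float, ci_high: float) -> str:
    if ci_high > 0.98 and ci_low > 0.7:
        return STRONG_LD
    if ci_high < 0.9:
        return STRONG_RECOMB
    return INCONCLUSIVE


# ----------------------------------------------------------------------
# vectorised window scan
# ----------------------------------------------------------------------

def window_pairs(
    g: GenotypeMatrix,
    max_bp: int = 1_000_000,
    confidence: float = 0.95,
    grid_step: float = CI_GRID_STEP,
    chunk: int = 4096,
) -> pd.DataFrame:
    """LD statistics for every same-chromosome locus pair within ``max_bp``.

    Equivalent to calling :func:`hap_counts` / :func:`ld_stats` /
    :func:`dprime_ci` per pair, but computed with matrix products and a
    chunked likelihood grid.  Uninformative pairs carry NaN statistics.
    """
    if (g.calls == HET).any():
        raise ValueError("window_pairs requires het-masked input")
    frames = []
    for chrom, sub in g.loci.groupby("chromosome", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["position"].to_numpy()
        m = len(idx)
        if m < 2:
            continue
        calls = g.calls[:, idx]
        alt = ((calls == ALT_HOM)).astype(np.float32)
        ref = ((calls == REF_HOM)).astype(np.float32)
        n11 = alt.T @ alt
        n10 = alt.T @ ref
        n01 = ref.T @ alt
        n00 = ref.T @ ref
        # pairs (i, j>i) within the window
        ii, jj = [], []
        hi = np.searchsorted(pos, pos + max_bp, side="right")
        for i in range(m):
            js = np.arange(i + 1, hi[i])
            ii.append(np.full(len(js), i))
            jj.append(js)
        if not ii:
            continue
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        if len(ii) == 0:
            continue
        nAB = n11[ii, jj].astype(np.float64)
        nAb = n10[ii, jj].astype(np.float64)
        naB = n01[ii, jj].astype(np.float64)
        nab = n00[ii, jj].astype(np.float64)
        n = nAB + nAb + naB + nab
        with np.errstate(invalid="ignore", divide="ignore"):
            pA = (nAB + nAb) / n
            pB = (nAB + naB) / n
        informative = (n > 0) & (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
        r2 = np.full(len(ii), np.nan)
        dprime = np.full(len(ii), np.nan)
        ci_lo = np.full(len(ii), np.nan)
        ci_hi = np.full(len(ii), np.nan)
        inf_idx = np.flatnonzero(informative)
        if len(inf_idx):
            pAi, pBi, ni = pA[inf_idx], pB[inf_idx], n[inf_idx]
            d = nAB[inf_idx] / ni - pAi * pBi
            r2[inf_idx] = d * d / (pAi * (1 - pAi) * pBi * (1 - pBi))
            # orient so D >= 0 (flip B labels where negative)
            flip = d < 0
            fAB = np.where(flip, nAb[inf_idx], nAB[inf_idx])
            fAb = np.where(flip, nAB[inf_idx], nAb[inf_idx])
            faB = np.where(flip, nab[inf_idx], naB[inf_idx])
            fab = np.where(flip, naB[inf_idx], nab[inf_idx])
            qB = np.where(flip, 1 - pBi, pBi)
            dmax = np.minimum(pAi * (1 - qB), (1 - pAi) * qB)
            dpos = np.abs(d)
            dprime[inf_idx] = np.where(dmax > 0, dpos / dmax, 0.0)
            grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
            for start in range(0, len(inf_idx), chunk):
                sl = slice(start, min(start + chunk, len(inf_idx)))
                dd = grid[:, None] * dmax[sl][None, :]
                pa_, qb_ = pAi[sl][None, :], qB[sl][None, :]
                ll = (
                    fAB[sl][None, :] * np.log(np.clip(pa_ * qb_ + dd, 1e-12, None))
                    + fAb[sl][None, :] * np.log(np.clip(pa_ * (1 - qb_) - dd, 1e-12, None))
                    + faB[sl][None, :] * np.log(np.clip((1 - pa_) * qb_ - dd, 1e-12, None))
                    + fab[sl][None, :] * np.log(np.clip((1 - pa_) * (1 - qb_) + dd, 1e-12, None))
                )
                lik = np.exp(ll - ll.max(axis=0, keepdims=True))
                cum = np.cumsum(lik, axis=0)
                cum /= cum[-1][None, :]
                lo = (cum < 1 - confidence).sum(axis=0)
                hi_i = (cum < confidence).sum(axis=0)
                ci_lo[inf_idx[sl]] = grid[np.minimum(lo, len(grid) - 1)]
                ci_hi[inf_idx[sl]] = grid[np.minimum(hi_i, len(grid) - 1)]
        klass = np.full(len(ii), UNINFORMATIVE, dtype=object)
        strong = informative & (ci_hi > 0.98) & (ci_lo > 0.7)
        recomb = informative & (ci_hi < 0.9)
        klass[informative] = INCONCLUSIVE
        klass[strong] = STRONG_LD
        klass[recomb] = STRONG_RECOMB
        lids = sub["locus_id"].to_numpy()
        regions = sub["region_class"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "locus_a": lids[ii],
                    "locus_b": lids[jj],
                    "pos_a": pos[ii],
                    "pos_b": pos[jj],
                    "dist": pos[jj] - pos[ii],
                    "r2": r2,
                    "dprime": dprime,
                    "ci_low": ci_lo,
                    "ci_high": ci_hi,
                    "pair_class": klass,
                    "region_a": regions[ii],
                    "region_b": regions[jj],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# decay curves
# ----------------------------------------------------------------------

def decay_curve(
    pairs: pd.DataFrame, bin_bp: int, region_class: str | None = None
) -> pd.DataFrame:
    """Mean r² per distance bin (half-open [start, end) bp bins).

    When ``region_class`` is given only pairs with BOTH loci in that class
    are used.  Empty bins carry NaN means, never zero.
    """
    sub = pairs.dropna(subset=["r2"])
    if region_class is not None:
        sub = sub[(sub["region_a"] == region_class) & (sub["region_b"] == region_class)]
    if sub.empty:
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])
    n_bins = int(sub["dist"].max() // bin_bp) + 1
    edges = np.arange(n_bins + 1) * bin_bp
    which = np.minimum(sub["dist"].to_numpy() // bin_bp, n_bins - 1).astype(int)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sub["r2"].to_numpy(), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "mean_r2": means,
            "n_pairs": counts,
        }
    )


def half_decay_distance(curve: pd.DataFrame) -> float:
    """Midpoint of the first bin whose mean r² falls to half the curve maximum.

    The maximum is the largest populated-bin mean anywhere on the curve;
    returns ``NOT_REACHED`` (inf) when no bin reaches half of it.
    """
    populated = curve[curve["n_pairs"] > 0]
    if len(populated) < 2:
        raise ValueError("half-decay needs at least two populated bins")
    peak = populated["mean_r2"].max()
    half = peak / 2.0
    for row in populated.sort_values("bin_start").itertuples():
        if row.mean_r2 <= half:
            return float((row.bin_start + row.bin_end) / 2.0)
    return NOT_REACHED
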