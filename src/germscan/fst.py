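"""Per-locus two-population Fst scans with genome-wide outlier thresholds.

Hudson's estimator is used on haploid-coded inbred calls:

    Fst = 1 - Hw / Hb,
    Hw  = mean over the two populations of  n/(n-1) * 2 p (1-p),
    Hb  = pA (1-pB) + pB (1-pA),

where p is the ALT allele frequency and n the number of non-missing calls
in a population at the locus.  The genome-wide significance threshold is
mean + z(1-alpha/2) * SD over all scanned loci, the construction that
reproduces the standard two-tailed 5% outlier cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import ALT_HOM, HET, MISSING, GenotypeMatrix


@dataclass
class FstScan:
    population_a: str
    population_b: str
    table: pd.DataFrame  # locus_id, chromosome, position, fst, n_a, n_b
    genome_mean: float
    genome_sd: float
    alpha: float
    threshold: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fst"] >= self.threshold]


def _pop_freqs(g: GenotypeMatrix, ids) -> tuple[np.ndarray, np.ndarray]:
    idx = g.accession_index(ids)
    calls = g.calls[idx]
    n = (calls != MISSING).sum(axis=0).astype(float)
    alt = (calls == ALT_HOM).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def hudson_fst(pa: float, pb: float, na: float, nb: float) -> float:
    """Hudson's two-population Fst for one locus from haploid frequencies/counts."""
    hw = 0.5 * (
        na / (na - 1.0) * 2.0 * pa * (1.0 - pa) + nb / (nb - 1.0) * 2.0 * pb * (1.0 - pb)
    )
    hb = pa * (1.0 - pb) + pb * (1.0 - pa)
    return 1.0 - hw / hb


def per_locus_fst(
    g: GenotypeMatrix, pop_a_ids, pop_b_ids, min_calls: int = 2
) -> pd.DataFrame:
    """Per-locus Hudson Fst between two accession sets.

    Loci with fewer than ``min_calls`` non-missing calls in either
    population, or monomorphic for the same allele in both (Hb = 0), are
    skipped.  Raw (possibly slightly negative) estimates are returned.
    """
    if (g.calls == HET).any():
        raise ValueError("per_locus_fst requires het-masked input")
    if len(pop_a_ids) == 0 or len(pop_b_ids) == 0:
        raise ValueError("both populations must be non-empty")
    pa, na = _pop_freqs(g, pop_a_ids)
    pb, nb = _pop_freqs(g, pop_b_ids)
    hb = pa * (1 - pb) + pb * (1 - pa)
    usable = (na >= min_calls) & (nb >= min_calls) & (hb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hw = 0.5 * (
            na / np.maximum(na - 1, 1) * 2 * pa * (1 - pa)
            + nb / np.maximum(nb - 1, 1) * 2 * pb * (1 - pb)
        )
        fst = 1.0 - hw / np.where(hb > 0, hb, np.nan)
    out = g.loci[["locus_id", "chromosome", "position"]].copy()
    out["fst"] = fst
    out["n_a"] = na
    out["n_b"] = nb
    out["p_a"] = pa
    out["p_b"] = pb
    return out[usable].reset_index(drop=True)


def genome_threshold(values, alpha: float = 0.05) -> tuple[float, float, float]:
    """(mean, SD, outlier threshold) over per-locus Fst values.

    Threshold = mean + z(1-alpha/2) * SD with the population SD, reported to
    three decimals.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 2:
        raise ValueError("need at least two Fst values")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    z = float(stats.norm.ppf(1 - alpha / 2))
    return mean, sd, round(mean + z * sd, 3)


def scan(
    g: GenotypeMatrix,
    pop_a_ids,
    pop_b_ids,
    labels: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> FstScan:
    table = per_locus_fst(g, pop_a_ids, pop_b_ids)
    mean, sd, threshold = genome_threshold(table["fst"], alpha=alpha)
    return FstScan(
        population_a=labels[0],
        population_b=labels[1],
        table=table,
        genome_mean=mean,
        genome_sd=sd,
        alpha=alpha,
        threshold=threshold,
    )


def chromosome_summary(s: FstScan) -> pd.DataFrame:
    """Per-chromosome mean Fst and the share of loci at or above the threshold."""
    rows = []
    for chrom, sub in s.table.groupby("chromosome", sort=True):
        n_sig = int((sub["fst"] >= s.threshold).sum())
        rows.append(
            {
                "chromosome": chrom,
                "n_loci": len(sub),
                "mean_fst": float(sub["fst"].mean()),
                "n_significant": n_sig,
                "percent_significant": 100.0 * n_sig / len(sub),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CandidateRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    locus_ids: tuple[str, ...]
    max_fst: float


def candidate_regions(s: FstScan, merge_gap_bp: int = 500_000) -> list[CandidateRegion]:
    """Merge threshold-exceeding loci into regions.

    Consecutive significant loci at most ``merge_gap_bp`` apart join the
    same region; region bounds are the first/last member positions.
    """
    regions: list[CandidateRegion] = []
    sig = s.significant().sort_values(["chromosome", "position"])
    for chrom, sub in sig.groupby("chromosome", sort=True):
        pos = sub["position"].to_numpy()
        lids = sub["locus_id"].to_list()
        vals = sub["fst"].to_numpy()
        start = 0
        for k in range(1, len(pos) + 1):
            if k == len(pos) or pos[k] - pos[k - 1] > merge_gap_bp:
                regions.append(
                    CandidateRegion(
                        chromosome=str(chrom),
                        start_bp=int(pos[start]),
                        end_bp=int(pos[k - 1]),
                        locus_ids=tuple(lids[start:k]),
                        max_fst=float(vals[start:k].max()),
                    )
                )
                start = k
    return regions
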