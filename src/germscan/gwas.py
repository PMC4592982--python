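"""Dichotomized case-control genome scan with stratification and genomic control.

Seed weight (g/100 seeds) is dichotomized — heavy accessions (>= ``hi``) are
cases, light ones (<= ``lo``) controls, the rest excluded — sidestepping
year/location effects on the quantitative record.  Association is tested per
locus with a Cochran–Mantel–Haenszel-type statistic over K cluster strata on
haploid allele counts:

    X^2 = (sum_k (a_k - E_k))^2 / sum_k V_k,
    E_k = R1k C1k / Nk,   V_k = R1k R2k C1k C2k / Nk^3,

with no continuity correction.  The N^3 variance (rather than the textbook
N^2 (N-1)) makes the K = 1 statistic coincide exactly with the classical
allelic Pearson chi-square on the pooled 2x2 table.  Residual inflation is
removed by genomic control: lambda = median(X^2) / 0.4549364 (clamped at 1),
adjusted statistics X^2 / lambda, and loci are called significant when
-log10(adjusted p) exceeds 3.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import ALT_HOM, HET, MISSING, REF_HOM, GenotypeMatrix

CASE = "case"
CONTROL = "control"
EXCLUDED = "excluded"

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = 0.4549364


def dichotomize(trait: pd.DataFrame, hi: float = 20.0, lo: float = 10.0) -> pd.DataFrame:
    """Label accessions case (weight >= hi), control (weight <= lo) or excluded."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if (trait["weight"] < 0).any():
        bad = trait.loc[trait["weight"] < 0, "accession"].iloc[0]
        raise ValueError(f"negative seed weight for accession {bad!r}")
    out = trait.copy()
    out["label"] = np.select(
        [out["weight"] >= hi, out["weight"] <= lo], [CASE, CONTROL], default=EXCLUDED
    )
    return out


def assign_clusters(
    g: GenotypeMatrix,
    k: int,
    seed: int = 0,
    n_components: int = 10,
    assignments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster accessions for stratification.

    When ``assignments`` (columns accession, cluster) is supplied it is
    passed through verbatim.  Otherwise accessions are clustered by k-means
    on the top principal components of the centered allele-count matrix
    (missing calls imputed to the locus mean).
    """
    if assignments is not None:
        return assignments[["accession", "cluster"]].copy()
    if not 1 <= k <= g.n_accessions:
        raise ValueError(f"K must be in [1, {g.n_accessions}]")
    if k == 1:
        return pd.DataFrame({"accession": g.accession_ids, "cluster": 1})
    dosage = g.calls.astype(float)
    dosage[g.calls == HET] = np.nan
    dosage[g.calls == MISSING] = np.nan
    dosage /= 2.0
    col_mean = np.nanmean(dosage, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
    inds = np.where(np.isnan(dosage))
    dosage[inds] = np.take(col_mean, inds[1])
    dosage -= dosage.mean(axis=0)
    if np.unique(dosage, axis=0).shape[0] < k:
        raise ValueError("K exceeds the number of distinct genotype rows")
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    n_comp = min(n_components, g.n_accessions - 1, g.n_loci)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(dosage)
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(pcs)
    return pd.DataFrame({"accession": g.accession_ids, "cluster": labels + 1})


def _strata_indices(
    g: GenotypeMatrix, pheno: pd.DataFrame, clusters: pd.DataFrame
) -> list[tuple[np.ndarray, np.ndarray]]:
    cluster_of = dict(zip(clusters["accession"], clusters["cluster"]))
    label_of = dict(zip(pheno["accession"], pheno["label"]))
    strata: dict = {}
    for i, acc in enumerate(g.accession_ids):
        lab = label_of.get(acc)
        if lab not in (CASE, CONTROL):
            continue
        ck = cluster_of.get(acc)
        if ck is None:
            raise ValueError(f"phenotyped accession {acc!r} has no cluster")
        strata.setdefault(ck, ([], []))[0 if lab == CASE else 1].append(i)
    return [
        (np.array(cases, dtype=np.intp), np.array(ctrls, dtype=np.intp))
        for cases, ctrls in strata.values()
    ]


def stratified_test(
    g: GenotypeMatrix, pheno: pd.DataFrame, clusters: pd.DataFrame, locus_id: str
) -> tuple[float, float]:
    """(chi-square, p) for one locus; see :func:`genome_scan` for the statistic."""
    res = genome_scan(g.subset_loci(g.loci["locus_id"] == locus_id), pheno, clusters)
    row = res.iloc[0]
    if math.isnan(row["chisq"]):
        raise ValueError(f"locus {locus_id!r}: all strata degenerate")
    return float(row["chisq"]), float(row["p_raw"])


def genome_scan(
    g: GenotypeMatrix, pheno: pd.DataFrame, clusters: pd.DataFrame
) -> pd.DataFrame:
    """CMH-type allele-count scan over all loci.

    Per stratum the 2x2 table is ALT/REF allele (haploid-coded) by
    case/control among non-missing accessions; strata with a zero margin
    contribute nothing, and loci where every stratum is degenerate carry
    NaN statistics.
    """
    if (g.calls == HET).any():
        raise ValueError("genome_scan requires het-masked input")
    strata = _strata_indices(g, pheno, clusters)
    if not strata:
        raise ValueError("no phenotyped accessions")
    num = np.zeros(g.n_loci)
    den = np.zeros(g.n_loci)
    for cases, ctrls in strata:
        case_alt = (g.calls[cases] == ALT_HOM).sum(axis=0).astype(float)
        case_ref = (g.calls[cases] == REF_HOM).sum(axis=0).astype(float)
        ctrl_alt = (g.calls[ctrls] == ALT_HOM).sum(axis=0).astype(float)
        ctrl_ref = (g.calls[ctrls] == REF_HOM).sum(axis=0).astype(float)
        r1 = case_alt + case_ref
        r2 = ctrl_alt + ctrl_ref
        c1 = case_alt + ctrl_alt
        c2 = case_ref + ctrl_ref
        n = r1 + r2
        ok = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = r1 * c1 / n
            v = r1 * r2 * c1 * c2 / n**3
        num += np.where(ok, case_alt - e, 0.0)
        den += np.where(ok, v, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chisq = np.where(den > 0, num**2 / np.maximum(den, 1e-300), np.nan)
    p = stats.chi2.sf(chisq, df=1)
    out = g.loci[["locus_id", "chromosome", "position"]].copy()
    out["chisq"] = chisq
    out["p_raw"] = p
    return out


def genomic_control(results: pd.DataFrame) -> pd.DataFrame:
    """Add lambda, adjusted chi-square/p and -log10(p) columns.

    lambda = median(raw chi-square) / median of the 1-df chi-square
    distribution, clamped at 1 per standard genomic-control practice.
    """
    tested = results.dropna(subset=["chisq"])
    if len(tested) < 100:
        warnings.warn(
            f"genomic control estimated from only {len(tested)} loci; "
            "lambda may be unstable"
        )
    lam = float(np.median(tested["chisq"])) / CHI2_1DF_MEDIAN
    lam = max(lam, 1.0)
    out = results.copy()
    out["lambda_gc"] = lam
    out["chisq_adj"] = out["chisq"] / lam
    out["p_adj"] = stats.chi2.sf(out["chisq_adj"], df=1)
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_adj"])
    return out


def call_significant(results: pd.DataFrame, threshold_neg_log10: float = 3.0) -> pd.DataFrame:
    """Flag loci with -log10(adjusted p) strictly greater than the threshold."""
    out = results.copy()
    out["significant"] = out["neg_log10_p"] > threshold_neg_log10
    return out
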