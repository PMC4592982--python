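"""Reading/writing genotype matrices and side tables, plus locus-level QC.

Two genotype formats are supported: biallelic-SNP VCF 4.x (read through
cyvcf2) and a plain TSV matrix whose header row carries accession ids and
whose rows are ``locus_id chrom pos ref alt call1..callN`` with calls in
{0,2,1,NA} for {REF_HOM, ALT_HOM, HET, MISSING}.

The QC filters implement the collection-fingerprinting conventions: a locus
is dropped when its combined heterozygous+missing call rate exceeds the
threshold (kept at exactly the threshold) or when fewer than two homozygous
states are observed; surviving heterozygous calls are then masked to
missing, and allele frequencies treat each inbred homozygote as a single
haploid observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import (
    ALT_HOM,
    HET,
    MISSING,
    REF_HOM,
    GenotypeMatrix,
    RegionClassMap,
    locus_table,
)


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the named format (vcf|matrix-tsv)."""
    if format == "vcf":
        return _read_vcf(path)
    if format in ("matrix-tsv", "tsv"):
        return _read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accessions = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ParseError(
                f"multi-allelic or non-SNP record rejected: "
                f"{rec.ID or f'{rec.CHROM}:{rec.POS}'}"
            )
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(accessions), 0), dtype=np.int8)
    )
    loci = locus_table(ids, chroms, poss, refs, alts)
    return GenotypeMatrix(accessions, loci, calls)


def _read_matrix_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    required = ["locus_id", "chrom", "pos", "ref", "alt"]
    if list(df.columns[:5]) != required:
        raise ParseError(
            f"matrix TSV must start with columns {required}, got {list(df.columns[:5])}"
        )
    accessions = list(df.columns[5:])
    sub = df[accessions]
    calls = np.full((len(accessions), len(df)), MISSING, dtype=np.int8)
    for j, col in enumerate(accessions):
        vals = sub[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        unparsed = numeric.isna() & (vals.astype(str) != "NA")
        bad = unparsed | (numeric.notna() & ~numeric.isin([0, 1, 2]))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ParseError(f"bad call {vals[bad].iloc[0]!r} at line {line}")
        calls[j] = numeric.fillna(MISSING).astype(np.int8).to_numpy()
    loci = locus_table(df["locus_id"], df["chrom"], df["pos"], df["ref"], df["alt"])
    return GenotypeMatrix(accessions, loci, calls)


def write_matrix_tsv(g: GenotypeMatrix, path) -> None:
    meta = g.loci[["locus_id", "chromosome", "position", "ref", "alt"]]
    data = dict(zip(["locus_id", "chrom", "pos", "ref", "alt"], (meta[c] for c in meta)))
    for i, acc in enumerate(g.accession_ids):
        col = g.calls[i]
        data[acc] = ["NA" if v == MISSING else int(v) for v in col]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


_VCF_GT = {REF_HOM: "0/0", HET: "0/1", ALT_HOM: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal biallelic-SNP VCF 4.2 with diploid GT strings."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.accession_ids)
            + "\n"
        )
        for j in range(g.n_loci):
            row = g.loci.iloc[j]
            gts = "\t".join(_VCF_GT[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.locus_id}\t"
                f"{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_region_bed(path) -> RegionClassMap:
    """Read a region-class map from BED (chrom, 0-based start, end, label)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "label"],
        dtype={"chrom": str},
        comment="#",
    )
    bad = ~df["label"].isin(["euchromatic", "heterochromatic"])
    if bad.any():
        raise ParseError(f"unknown region label {df.loc[bad, 'label'].iloc[0]!r}")
    intervals = {
        chrom: sub[["start", "end", "label"]].reset_index(drop=True)
        for chrom, sub in df.groupby("chrom")
    }
    return RegionClassMap(intervals)


def write_region_bed(regions: RegionClassMap, path) -> None:
    rows = []
    for chrom in regions.chromosomes():
        for _, r in regions.intervals[chrom].iterrows():
            rows.append((chrom, int(r.start), int(r.end), r.label))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genetic_map(path) -> pd.DataFrame:
    """Genetic map TSV: locus_id, chrom, pos, cM."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"locus_id", "chrom", "pos", "cM"}.issubset(df.columns):
        raise ParseError("genetic map needs columns locus_id, chrom, pos, cM")
    return df


def read_trait_table(path) -> pd.DataFrame:
    """Trait TSV: accession, weight (g/100 seeds)."""
    df = pd.read_csv(path, sep="\t")
    if not {"accession", "weight"}.issubset(df.columns):
        raise ParseError("trait table needs columns accession, weight")
    return df


def read_gene_table(path) -> pd.DataFrame:
    """Gene list TSV: chrom, start (1-based), gene_id."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "start", "gene_id"}.issubset(df.columns):
        raise ParseError("gene table needs columns chrom, start, gene_id")
    return df


# ----------------------------------------------------------------------
# QC filters
# ----------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-reason locus removal counts from :func:`filter_loci`."""

    n_input: int
    n_bad_rate: int
    n_monomorphic: int
    n_kept: int


def filter_loci(
    g: GenotypeMatrix, max_bad_rate: float = 0.1, return_report: bool = False
):
    """Drop loci whose het+missing call rate exceeds ``max_bad_rate`` (strictly)
    or that lack two distinct homozygous states.

    Rates are computed jointly over heterozygous and missing calls before any
    het masking; loci at exactly the threshold are retained.
    """
    if not 0 <= max_bad_rate <= 1:
        raise ValueError(f"max_bad_rate must be in [0,1], got {max_bad_rate}")
    if g.n_loci == 0 or g.n_accessions == 0:
        raise ValueError("empty genotype matrix")
    calls = g.calls
    bad = ((calls == HET) | (calls == MISSING)).sum(axis=0) / g.n_accessions
    has_ref = (calls == REF_HOM).any(axis=0)
    has_alt = (calls == ALT_HOM).any(axis=0)
    rate_ok = bad <= max_bad_rate
    poly_ok = has_ref & has_alt
    keep = rate_ok & poly_ok
    out = g.subset_loci(keep)
    if return_report:
        report = FilterReport(
            n_input=g.n_loci,
            n_bad_rate=int((~rate_ok).sum()),
            n_monomorphic=int((rate_ok & ~poly_ok).sum()),
            n_kept=out.n_loci,
        )
        return out, report
    return out


def apply_het_to_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Mask every heterozygous call to missing (idempotent)."""
    out = g.copy()
    out.calls[out.calls == HET] = MISSING
    return out


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """ALT allele frequency per locus over non-missing haploid-coded calls.

    Requires het-masked input; loci with no non-missing calls yield NaN.
    """
    if (g.calls == HET).any():
        raise ValueError("allele frequencies require het-masked input")
    alt = (g.calls == ALT_HOM).sum(axis=0).astype(float)
    called = (g.calls != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, alt / called, np.nan)


def maf_filter(g: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep loci with minor allele frequency >= ``min_maf`` (boundary inclusive).

    Each inbred homozygote contributes one haploid allele observation;
    loci with zero non-missing calls are removed.
    """
    p = allele_frequencies(g)
    maf = np.minimum(p, 1 - p)
    keep = ~np.isnan(maf) & (maf >= min_maf)
    return g.subset_loci(keep)


def assign_region_class(g: GenotypeMatrix, regions: RegionClassMap) -> GenotypeMatrix:
    """Label every locus with the region class containing its position."""
    out = g.copy()
    labels = []
    for chrom, pos in zip(out.loci["chromosome"], out.loci["position"]):
        labels.append(regions.class_of(str(chrom), int(pos)))
    out.loci["region_class"] = labels
    return out
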