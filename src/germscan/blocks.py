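"""Haplotype-block detection, summaries, cross-population sharing and annotation.

A candidate block is a run of consecutive filtered SNPs [i..j] on one
chromosome whose outermost pair is in strong LD and in which, among all
informative pairs (strong-LD or strong-recombination) inside the interval,
the strong-LD fraction is at least 0.95; spans are capped at the LD window
(pairs beyond it were never computed).  Candidates are accepted greedily by
decreasing bp span (ties: leftmost), skipping any candidate that overlaps an
accepted block, so the final map is non-overlapping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    ALT_HOM,
    MISSING,
    UNASSIGNED,
    GenotypeMatrix,
    RegionClassMap,
)
from .ld import STRONG_LD, STRONG_RECOMB

MAX_SPAN_BP = 1_000_000


@dataclass
class HaplotypeBlock:
    chromosome: str
    locus_ids: list[str]
    start_bp: int
    end_bp: int
    region_class: str = UNASSIGNED
    haplotypes: list[tuple[str, int]] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_snps(self) -> int:
        return len(self.locus_ids)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class BlockMap:
    population: str
    blocks: list[HaplotypeBlock]
    locus_ids: list[str]

    def by_chromosome(self) -> dict[str, list[HaplotypeBlock]]:
        out: dict[str, list[HaplotypeBlock]] = {}
        for b in self.blocks:
            out.setdefault(b.chromosome, []).append(b)
        return out


# ----------------------------------------------------------------------
# detection
# ----------------------------------------------------------------------

def find_blocks(
    pair_stats: pd.DataFrame,
    loci: pd.DataFrame,
    population: str = "",
    max_span_bp: int = MAX_SPAN_BP,
    min_strong_fraction: float = 0.95,
) -> BlockMap:
    """Gabriel-style block map from classified pair statistics.

    ``pair_stats`` is the output of :func:`germscan.ld.window_pairs` on the
    same filtered locus set described by ``loci``.
    """
    blocks: list[HaplotypeBlock] = []
    class_by_pair = dict(
        zip(zip(pair_stats["locus_a"], pair_stats["locus_b"]), pair_stats["pair_class"])
    )
    for chrom, sub in loci.groupby("chromosome", sort=True):
        sub = sub.sort_values("position")
        lids = sub["locus_id"].to_list()
        pos = sub["position"].to_numpy()
        regions = sub["region_class"].to_list()
        m = len(lids)
        if m < 2:
            continue
        strong = np.zeros((m, m), dtype=bool)
        informative = np.zeros((m, m), dtype=bool)
        for i in range(m):
            for j in range(i + 1, m):
                cls = class_by_pair.get((lids[i], lids[j])) or class_by_pair.get(
                    (lids[j], lids[i])
                )
                if cls == STRONG_LD:
                    strong[i, j] = informative[i, j] = True
                elif cls == STRONG_RECOMB:
                    informative[i, j] = True
        t_strong = _interval_pair_counts(strong)
        t_inf = _interval_pair_counts(informative)
        span = pos[None, :] - pos[:, None]
        iu, ju = np.triu_indices(m, k=1)
        ok = (
            strong[iu, ju]
            & (span[iu, ju] <= max_span_bp)
            & (t_inf[iu, ju] > 0)
            & (t_strong[iu, ju] >= min_strong_fraction * t_inf[iu, ju])
        )
        cands = [
            (int(span[i, j]), int(i), int(j))
            for i, j in zip(iu[ok], ju[ok])
        ]
        cands.sort(key=lambda c: (-c[0], c[1]))
        occupied = np.zeros(m, dtype=bool)
        for sp, i, j in cands:
            if occupied[i : j + 1].any():
                continue
            occupied[i : j + 1] = True
            members = lids[i : j + 1]
            klass = Counter(regions[i : j + 1]).most_common(1)[0][0]
            blocks.append(
                HaplotypeBlock(
                    chromosome=str(chrom),
                    locus_ids=members,
                    start_bp=int(pos[i]),
                    end_bp=int(pos[j]),
                    region_class=klass,
                )
            )
    blocks.sort(key=lambda b: (b.chromosome, b.start_bp))
    return BlockMap(population=population, blocks=blocks, locus_ids=list(loci["locus_id"]))


def _interval_pair_counts(upper: np.ndarray) -> np.ndarray:
    """T[i, j] = number of True entries (a, b) with i <= a < b <= j.

    ``upper`` is a strictly-upper-triangular boolean matrix.
    """
    r = np.cumsum(upper, axis=1)  # R[i, j] = count of True in row i up to col j
    t = np.cumsum(r[::-1], axis=0)[::-1]  # sum rows i..m-1; rows > j contribute 0 cols<=j
    return t


# ----------------------------------------------------------------------
# haplotype enumeration
# ----------------------------------------------------------------------

def enumerate_haplotypes(g: GenotypeMatrix, block: HaplotypeBlock) -> list[tuple[str, int]]:
    """Tally allele strings over accessions fully called inside the block.

    Alleles are written as the ref/alt bases of each member locus; any
    accession with a missing call inside the block is excluded.
    """
    lookup = {lid: k for k, lid in enumerate(g.loci["locus_id"])}
    try:
        cols = [lookup[lid] for lid in block.locus_ids]
    except KeyError as exc:
        raise KeyError(f"block locus {exc.args[0]!r} absent from matrix") from None
    calls = g.calls[:, cols]
    full = ~(calls == MISSING).any(axis=1)
    ref = g.loci["ref"].to_numpy()[cols]
    alt = g.loci["alt"].to_numpy()[cols]
    tally: Counter[str] = Counter()
    for row in calls[full]:
        tally["".join(alt[k] if row[k] == ALT_HOM else ref[k] for k in range(len(cols)))] += 1
    return sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))


def annotate_haplotypes(bmap: BlockMap, g: GenotypeMatrix) -> BlockMap:
    for b in bmap.blocks:
        b.haplotypes = enumerate_haplotypes(g, b)
    return bmap


# ----------------------------------------------------------------------
# summaries (Table 2/3-style)
# ----------------------------------------------------------------------

def summarize_blocks(
    bmap: BlockMap,
    regions: RegionClassMap | None = None,
    histogram_edges_kb=(0, 5, 15, 20, 50, 100, 500, 900, float("inf")),
    common_haplotype_freq: float = 0.10,
) -> dict:
    """Per-region-class block summary: counts, total/mean kb, SNPs and
    haplotypes per block, fraction of the region in blocks, block-size
    histogram, and the share of haplotypes above ``common_haplotype_freq``.
    """
    classes = sorted({b.region_class for b in bmap.blocks})
    rows = []
    for klass in classes + ["genome"]:
        sel = [b for b in bmap.blocks if klass == "genome" or b.region_class == klass]
        n_blocks = len(sel)
        total_kb = sum(b.span_bp for b in sel) / 1000.0
        n_snps = sum(b.n_snps for b in sel)
        n_haps = sum(b.n_haplotypes for b in sel)
        n_common = 0
        for b in sel:
            retained = sum(c for _, c in b.haplotypes)
            n_common += sum(
                1 for _, c in b.haplotypes if retained and c / retained > common_haplotype_freq
            )
        class_bp = None
        if regions is not None and klass != "genome":
            class_bp = regions.class_bp(klass)
        rows.append(
            {
                "region_class": klass,
                "n_blocks": n_blocks,
                "total_kb": round(total_kb, 1),
                "mean_kb": round(total_kb / n_blocks, 1) if n_blocks else float("nan"),
                "fraction_of_region_in_blocks": (
                    round(total_kb * 1000.0 / class_bp, 2) if class_bp else float("nan")
                ),
                "n_snps_in_blocks": n_snps,
                "snps_per_block": round(n_snps / n_blocks, 1) if n_blocks else float("nan"),
                "n_haplotypes": n_haps,
                "haplotypes_per_block": round(n_haps / n_blocks, 1) if n_blocks else float("nan"),
                "n_common_haplotypes": n_common,
            }
        )
    edges = [e * 1000.0 for e in histogram_edges_kb]
    hist_rows = []
    for klass in classes:
        spans = [b.span_bp for b in bmap.blocks if b.region_class == klass]
        counts, _ = np.histogram(spans, bins=edges)
        for k in range(len(counts)):
            hist_rows.append(
                {
                    "region_class": klass,
                    "bin_start_kb": histogram_edges_kb[k],
                    "bin_end_kb": histogram_edges_kb[k + 1],
                    "n_blocks": int(counts[k]),
                }
            )
    return {
        "table": pd.DataFrame(rows),
        "histogram": pd.DataFrame(
            hist_rows, columns=["region_class", "bin_start_kb", "bin_end_kb", "n_blocks"]
        ),
    }


# ----------------------------------------------------------------------
# sharing
# ----------------------------------------------------------------------

def _coblocked_pairs(bmap: BlockMap, common: set[str]) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for b in bmap.blocks:
        members = [lid for lid in b.locus_ids if lid in common]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(frozenset((members[i], members[j])))
    return pairs


@dataclass(frozen=True)
class SharingResult:
    population_a: str
    population_b: str
    concordant: int
    nonconcordant: int

    @property
    def sharing_percent(self) -> float:
        total = self.concordant + self.nonconcordant
        if total == 0:
            return float("nan")
        return 100.0 * self.concordant / total


def block_sharing(map_a: BlockMap, map_b: BlockMap) -> SharingResult:
    """Concordance of co-blocked SNP pairs between two block maps.

    The pair universe is every SNP pair (over loci present in both maps'
    locus sets) co-blocked in either map; a pair is concordant when it is
    co-blocked in both.  Symmetric by construction.
    """
    common = set(map_a.locus_ids) & set(map_b.locus_ids)
    pa = _coblocked_pairs(map_a, common)
    pb = _coblocked_pairs(map_b, common)
    concordant = len(pa & pb)
    universe = len(pa | pb)
    return SharingResult(
        population_a=map_a.population,
        population_b=map_b.population,
        concordant=concordant,
        nonconcordant=universe - concordant,
    )


# ----------------------------------------------------------------------
# annotation: genes and recombination
# ----------------------------------------------------------------------

def gene_block_contrast(
    bmap: BlockMap, genes: pd.DataFrame, regions: RegionClassMap
) -> pd.DataFrame:
    """Observed vs expected in-block gene counts per region class.

    A gene is "in blocks" when its start position lies inside a block of
    that class; the expectation assumes genes uniform over the class:
    expected = (genes in class) x (class bp in blocks) / (class bp).
    Genes on chromosomes absent from the region map are skipped.
    """
    rows = []
    classes = sorted({b.region_class for b in bmap.blocks} | {"euchromatic", "heterochromatic"})
    known = set(regions.chromosomes())
    usable = genes[genes["chrom"].astype(str).isin(known)]
    gene_class = [
        regions.class_of(str(c), int(s)) for c, s in zip(usable["chrom"], usable["start"])
    ]
    usable = usable.assign(region_class=gene_class)
    for klass in classes:
        class_bp = regions.class_bp(klass)
        sel = [b for b in bmap.blocks if b.region_class == klass]
        block_bp = sum(b.span_bp for b in sel)
        in_class = usable[usable["region_class"] == klass]
        observed = 0
        for b in sel:
            observed += int(
                (
                    (in_class["chrom"].astype(str) == b.chromosome)
                    & (in_class["start"] >= b.start_bp)
                    & (in_class["start"] <= b.end_bp)
                ).sum()
            )
        expected = len(in_class) * block_bp / class_bp if class_bp else 0.0
        rows.append(
            {
                "region_class": klass,
                "n_genes_in_class": len(in_class),
                "observed_in_blocks": observed,
                "expected_in_blocks": expected,
                "ratio": observed / expected if expected > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def recombination_in_blocks(
    bmap: BlockMap, gmap: pd.DataFrame, regions: RegionClassMap
) -> pd.DataFrame:
    """Observed vs expected recombination rate (cM/Mb) inside blocks per class.

    Observed = total cM between each block's outermost mapped SNPs over the
    total block bp; expected = the same ratio over the whole class, using the
    outermost mapped SNPs of that class on each chromosome.  Blocks without
    at least two mapped member SNPs are skipped.
    """
    cm = dict(zip(gmap["locus_id"], gmap["cM"]))
    for chrom, sub in gmap.groupby("chrom"):
        sub = sub.sort_values("pos")
        if not sub["cM"].is_monotonic_increasing:
            raise ValueError(f"genetic map non-monotone on {chrom}")
    gmap = gmap.assign(
        region_class=[
            regions.class_of(str(c), int(p)) for c, p in zip(gmap["chrom"], gmap["pos"])
        ]
    )
    rows = []
    classes = sorted({b.region_class for b in bmap.blocks})
    for klass in classes:
        obs_cm = obs_bp = 0.0
        for b in bmap.blocks:
            if b.region_class != klass:
                continue
            mapped = [lid for lid in b.locus_ids if lid in cm]
            if len(mapped) < 2:
                continue
            obs_cm += abs(cm[mapped[-1]] - cm[mapped[0]])
            obs_bp += b.span_bp
        exp_cm = exp_bp = 0.0
        for chrom, sub in gmap[gmap["region_class"] == klass].groupby("chrom"):
            if len(sub) < 2:
                continue
            sub = sub.sort_values("pos")
            exp_cm += abs(float(sub["cM"].iloc[-1]) - float(sub["cM"].iloc[0]))
            exp_bp += float(sub["pos"].iloc[-1]) - float(sub["pos"].iloc[0])
        obs_rate = obs_cm / (obs_bp / 1e6) if obs_bp > 0 else float("nan")
        exp_rate = exp_cm / (exp_bp / 1e6) if exp_bp > 0 else float("nan")
        rows.append(
            {
                "region_class": klass,
                "observed_cm_per_mb": obs_rate,
                "expected_cm_per_mb": exp_rate,
                "ratio": obs_rate / exp_rate if exp_rate and exp_rate > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
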