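"""Block detection (with brute-force oracle), summaries, sharing, annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from germscan import blocks, ld, simulate
from germscan.blocks import BlockMap, HaplotypeBlock
from germscan.genotypes import EUCHROMATIC, HETEROCHROMATIC, RegionClassMap, locus_table

from conftest import make_matrix


def _pair_frame(classes: dict, positions) -> pd.DataFrame:
    """Build a pair_stats frame from {(i, j): class} over locus indices."""
    rows = []
    for (i, j), cls in classes.items():
        rows.append(
            {
                "chromosome": "Chr01",
                "locus_a": f"L{i + 1:03d}",
                "locus_b": f"L{j + 1:03d}",
                "pos_a": positions[i],
                "pos_b": positions[j],
                "dist": positions[j] - positions[i],
                "pair_class": cls,
            }
        )
    return pd.DataFrame(rows)


def _loci(positions):
    n = len(positions)
    df = locus_table(
        [f"L{k + 1:03d}" for k in range(n)], ["Chr01"] * n, positions
    )
    return df


def brute_force_blocks(classes, positions, max_span=1_000_000, min_frac=0.95):
    """Naive re-implementation: enumerate qualifying intervals, accept by
    decreasing span then leftmost, skipping overlaps."""
    n = len(positions)
    cands = []
    for i in range(n):
        for j in range(i + 1, n):
            if positions[j] - positions[i] > max_span:
                continue
            if classes.get((i, j)) != ld.STRONG_LD:
                continue
            informative = strong = 0
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    cls = classes.get((a, b))
                    if cls == ld.STRONG_LD:
                        strong += 1
                        informative += 1
                    elif cls == ld.STRONG_RECOMB:
                        informative += 1
            if informative and strong >= min_frac * informative:
                cands.append((positions[j] - positions[i], i, j))
    cands.sort(key=lambda c: (-c[0], c[1]))
    taken, used = [], set()
    for span, i, j in cands:
        if any(k in used for k in range(i, j + 1)):
            continue
        used.update(range(i, j + 1))
        taken.append((i, j))
    return sorted(taken)


def test_all_strong_pairs_single_block():
    positions = [1000, 2000, 3000]
    classes = {(0, 1): ld.STRONG_LD, (1, 2): ld.STRONG_LD, (0, 2): ld.STRONG_LD}
    bmap = blocks.find_blocks(_pair_frame(classes, positions), _loci(positions))
    assert len(bmap.blocks) == 1
    assert bmap.blocks[0].locus_ids == ["L001", "L002", "L003"]
    assert bmap.blocks[0].span_bp == 2000


def test_find_blocks_matches_brute_force_on_random_instances():
    """Greedy detection equals naive enumeration on 400 random instances of
    up to 8 loci with random pair classes."""
    rng = np.random.default_rng(42)
    labels = [ld.STRONG_LD, ld.STRONG_RECOMB, ld.INCONCLUSIVE]
    for trial in range(400):
        n = int(rng.integers(2, 9))
        positions = np.sort(rng.choice(np.arange(1, 3_000_000, 1000), n, replace=False))
        classes = {
            (i, j): labels[rng.integers(0, 3)]
            for i in range(n)
            for j in range(i + 1, n)
        }
        bmap = blocks.find_blocks(_pair_frame(classes, positions), _loci(positions))
        got = sorted(
            (positions.tolist().index(b.start_bp), positions.tolist().index(b.end_bp))
            for b in bmap.blocks
        )
        expected = brute_force_blocks(classes, positions.tolist())
        assert got == expected, f"trial {trial}: {got} != {expected}"


def test_planted_blocks_recovered(collection, population_ld):
    """In the wild population (crisp boundaries) planted blocks come back
    with high locus-set overlap."""
    wild = population_ld["wild"]
    jac = simulate.planted_block_jaccard(collection.truth, wild["blocks"])
    assert jac >= 0.8


def test_no_block_overlap_and_rule_audit(population_ld):
    """Accepted blocks never overlap; every block re-passes the 95% rule."""
    for pop, stuff in population_ld.items():
        bmap, pairs = stuff["blocks"], stuff["pairs"]
        cls = dict(zip(zip(pairs["locus_a"], pairs["locus_b"]), pairs["pair_class"]))
        for chrom, blist in bmap.by_chromosome().items():
            spans = sorted((b.start_bp, b.end_bp) for b in blist)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2
        for b in bmap.blocks:
            strong = informative = 0
            for x, y in itertools.combinations(b.locus_ids, 2):
                c = cls.get((x, y)) or cls.get((y, x))
                if c == ld.STRONG_LD:
                    strong += 1
                    informative += 1
                elif c == ld.STRONG_RECOMB:
                    informative += 1
            assert informative > 0 and strong >= 0.95 * informative
            assert b.span_bp <= 1_000_000


def test_haplotype_enumeration():
    """Fully-called accessions tally into allele strings; missing excludes."""
    g = make_matrix(np.array([[2, 2], [2, 2], [0, 0], [-1, 2]]))
    g.loci.loc[:, "ref"] = ["A", "C"]
    g.loci.loc[:, "alt"] = ["G", "T"]
    block = HaplotypeBlock("Chr01", ["L001", "L002"], 1000, 2000)
    haps = blocks.enumerate_haplotypes(g, block)
    assert haps == [("GT", 2), ("AC", 1)]


def test_summary_arithmetic_from_constructed_maps():
    """Mean size, SNPs/block and haplotypes/block reproduce printed-table
    style arithmetic from raw totals."""
    def synthetic_map(n_blocks, total_kb, klass):
        spans = np.full(n_blocks, (total_kb * 1000) // n_blocks, dtype=int)
        spans[: int(total_kb * 1000 - spans.sum())] += 1
        blist = []
        cursor = 1
        for k, sp in enumerate(spans):
            blist.append(
                HaplotypeBlock(
                    "Chr01", [f"A{k}", f"B{k}"], cursor, cursor + int(sp), region_class=klass
                )
            )
            cursor += int(sp) + 10
        return BlockMap("pop", blist, [])

    bmap = synthetic_map(4331, 46_246, EUCHROMATIC)
    table = blocks.summarize_blocks(bmap)["table"]
    row = table[table["region_class"] == EUCHROMATIC].iloc[0]
    assert row["n_blocks"] == 4331
    assert row["total_kb"] == pytest.approx(46_246, abs=0.5)
    assert row["mean_kb"] == 10.7
    one = BlockMap(
        "p",
        [HaplotypeBlock("Chr01", ["a", "b"], 1, 10_001, region_class=EUCHROMATIC)],
        [],
    )
    regions = RegionClassMap(
        {"Chr01": pd.DataFrame({"start": [0], "end": [100_000], "label": [EUCHROMATIC]})}
    )
    frac = blocks.summarize_blocks(one, regions)["table"]
    assert frac[frac["region_class"] == EUCHROMATIC]["fraction_of_region_in_blocks"].iloc[0] == 0.10


def test_block_sharing_hand_example():
    """A={1,2,3} vs B={1,2},{3}: universe {12,13,23}, concordant {12} -> 33.3%."""
    map_a = BlockMap("a", [HaplotypeBlock("c", ["s1", "s2", "s3"], 1, 3)], ["s1", "s2", "s3"])
    map_b = BlockMap(
        "b",
        [HaplotypeBlock("c", ["s1", "s2"], 1, 2)],
        ["s1", "s2", "s3"],
    )
    res = blocks.block_sharing(map_a, map_b)
    assert (res.concordant, res.nonconcordant) == (1, 2)
    assert res.sharing_percent == pytest.approx(100 / 3)
    sym = blocks.block_sharing(map_b, map_a)
    assert (sym.concordant, sym.nonconcordant) == (1, 2)


def test_block_sharing_identical_and_disjoint():
    m1 = BlockMap("x", [HaplotypeBlock("c", ["s1", "s2"], 1, 2)], ["s1", "s2", "s3", "s4"])
    assert blocks.block_sharing(m1, m1).sharing_percent == 100.0
    m2 = BlockMap("y", [HaplotypeBlock("c", ["s3", "s4"], 3, 4)], ["s1", "s2", "s3", "s4"])
    res = blocks.block_sharing(m1, m2)
    assert res.sharing_percent == 0.0
    empty = blocks.block_sharing(BlockMap("e", [], ["s1"]), BlockMap("f", [], ["s1"]))
    assert np.isnan(empty.sharing_percent)


def test_gene_contrast_proportional_expectation():
    """100 genes in a 1000-kb class with 200 kb in blocks -> expected 20;
    uniform placement drives observed/expected toward 1."""
    regions = RegionClassMap(
        {"Chr01": pd.DataFrame({"start": [0], "end": [1_000_000], "label": [EUCHROMATIC]})}
    )
    bmap = BlockMap(
        "p",
        [HaplotypeBlock("Chr01", ["a", "b"], 100_000, 300_000, region_class=EUCHROMATIC)],
        [],
    )
    genes = pd.DataFrame(
        {
            "chrom": ["Chr01"] * 100,
            "start": np.arange(5_000, 1_000_000, 9_950)[:100],
            "gene_id": [f"g{k}" for k in range(100)],
        }
    )
    table = blocks.gene_block_contrast(bmap, genes, regions)
    row = table[table["region_class"] == EUCHROMATIC].iloc[0]
    assert row["expected_in_blocks"] == pytest.approx(20, abs=0.2)
    # uniform genes: observed matches expectation closely at larger n
    big = pd.DataFrame(
        {
            "chrom": "Chr01",
            "start": np.linspace(1, 999_999, 10_000).astype(int),
            "gene_id": [f"h{k}" for k in range(10_000)],
        }
    )
    row2 = blocks.gene_block_contrast(bmap, big, regions)
    r = row2[row2["region_class"] == EUCHROMATIC].iloc[0]
    assert r["ratio"] == pytest.approx(1.0, abs=0.05)


def test_recombination_suppressed_in_planted_blocks(collection, population_ld):
    """The genetic map was built with zero recombination inside planted
    blocks, so the in-block rate falls below the class-wide expectation."""
    wild = population_ld["wild"]
    table = blocks.recombination_in_blocks(
        wild["blocks"], collection.genetic_map, collection.regions
    )
    eu = table[table["region_class"] == EUCHROMATIC].iloc[0]
    assert eu["ratio"] < 1.0


def test_recombination_nonmonotone_map_rejected(collection, population_ld):
    gmap = collection.genetic_map.copy()
    gmap.loc[gmap.index[5], "cM"] = 1e9  # spike out of order
    with pytest.raises(ValueError, match="non-monotone"):
        blocks.recombination_in_blocks(
            population_ld["wild"]["blocks"], gmap, collection.regions
        )
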