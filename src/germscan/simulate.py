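"""Synthetic inbred-collection generator with planted ground truth.

The generator emulates the statistical structure of a selfing germplasm
collection at desk scale:

* near-fully homozygous genotypes with sparse heterozygous/missing calls;
* three nested populations — wild accessions drawn as recombinant mosaics of
  a founder haplotype pool, landraces as mosaics of a small subset of wild
  haplotypes (a domestication bottleneck), and cultivars as mosaics of a
  small subset of landrace haplotypes (an introduction/breeding bottleneck)
  with selected loci pushed toward fixation — so LD tract length and
  haplotype-block size increase down the chain;
* euchromatic and heterochromatic compartments with different locus density
  and recombination intensity;
* planted haplotype blocks (intervals with recombination suppressed and only
  two founder haplotypes segregating), planted duplicate accessions with a
  configurable corruption rate, and a seed-weight trait (g/100 seeds)
  controlled by a few planted causal loci plus Gaussian noise.

Every draw flows from one :class:`numpy.random.Generator` seeded by the
config, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import (
    EUCHROMATIC,
    HETEROCHROMATIC,
    GenotypeMatrix,
    RegionClassMap,
    locus_table,
)

WILD = "wild"
LANDRACE = "landrace"
CULTIVAR = "cultivar"

_COUNTRIES = {
    WILD: ["China", "Korea", "Japan", "Russia"],
    LANDRACE: ["China", "Korea", "Japan"],
    CULTIVAR: ["United States", "Canada"],
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    loci_per_chromosome: int = 300
    chromosome_bp: int = 6_000_000
    euchromatic_fraction: float = 0.6
    euchromatic_locus_fraction: float = 0.75
    # founder pools / bottlenecks; founders are themselves mosaics of a few
    # deep "proto" haplotypes so short-range haplotype structure exists even
    # in the wild population
    n_proto: int = 6
    proto_switch_per_bp: float = 1.0e-5
    n_founders: int = 30
    n_wild: int = 100
    n_landrace: int = 100
    n_cultivar: int = 70
    landrace_founder_count: int = 12
    cultivar_founder_count: int = 6
    # per-bp founder-switch (recombination) rates by population;
    # heterochromatin switches at a fraction of the euchromatic rate
    wild_switch_per_bp: float = 6.0e-5
    landrace_switch_per_bp: float = 5.0e-6
    cultivar_switch_per_bp: float = 1.5e-6
    heterochromatic_multiplier: float = 0.25
    # planted structure
    planted_blocks_per_chromosome: int = 2
    planted_block_span_bp: int = 80_000
    n_duplicate_pairs: int = 8
    duplicate_corruption_rate: float = 0.0
    # call noise
    het_rate: float = 0.005
    missing_rate: float = 0.02
    # trait
    n_causal: int = 3
    causal_effects: tuple = (9.0, 7.0, 6.0)
    trait_base: float = 7.0
    trait_noise_sd: float = 1.5
    # selection planted into the cultivar bottleneck
    n_selected: int = 6
    selection_freq: float = 0.97
    # annotation
    n_genes: int = 400
    map_cm_per_mb_eu: float = 4.0
    map_cm_per_mb_het: float = 1.0

    def validate(self) -> None:
        for name in (
            "euchromatic_fraction", "euchromatic_locus_fraction",
            "duplicate_corruption_rate", "het_rate", "missing_rate", "selection_freq",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.landrace_founder_count > self.n_founders:
            raise ValueError("landrace founder count exceeds the founder pool")
        if self.cultivar_founder_count > self.landrace_founder_count:
            raise ValueError("cultivar founder count exceeds the landrace pool")
        total_loci = self.n_chromosomes * self.loci_per_chromosome
        if self.n_causal + self.n_selected > total_loci:
            raise ValueError("more planted causal+selected loci than loci")
        if len(self.causal_effects) != self.n_causal:
            raise ValueError("causal_effects length must equal n_causal")


@dataclass
class SyntheticTruth:
    duplicate_groups: list[tuple[str, ...]]
    planted_blocks: list[dict]
    selected_loci: list[str]
    causal_loci: list[str]
    causal_effects: dict[str, float]
    population_frequencies: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "duplicate_groups": [list(grp) for grp in self.duplicate_groups],
            "planted_blocks": self.planted_blocks,
            "selected_loci": self.selected_loci,
            "causal_loci": self.causal_loci,
            "causal_effects": self.causal_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedCollection:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    regions: RegionClassMap
    genetic_map: pd.DataFrame
    genes: pd.DataFrame
    trait: pd.DataFrame
    truth: SyntheticTruth

    def population_ids(self, population: str) -> list[str]:
        meta = self.genotypes.accession_meta
        return list(meta.index[meta["population"] == population])


# ----------------------------------------------------------------------

def _mosaic(rng, pool: np.ndarray, switch_p: np.ndarray) -> np.ndarray:
    """One haplotype: founder indices switch between loci with prob ``switch_p``."""
    m = pool.shape[1]
    switch = np.empty(m, dtype=bool)
    switch[0] = True
    switch[1:] = rng.random(m - 1) < switch_p
    draws = rng.integers(0, pool.shape[0], size=m)
    last = np.maximum.accumulate(np.where(switch, np.arange(m), 0))
    return pool[draws[last], np.arange(m)]


def simulate_collection(cfg: SimulationConfig) -> SimulatedCollection:
    """Generate the full synthetic collection (genotypes, side tables, truth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- chromosome layout ------------------------------------------------
    chrom_names = [f"Chr{c + 1:02d}" for c in range(cfg.n_chromosomes)]
    eu_end = int(cfg.euchromatic_fraction * cfg.chromosome_bp)
    regions = RegionClassMap(
        {
            c: pd.DataFrame(
                {
                    "start": [0, eu_end],
                    "end": [eu_end, cfg.chromosome_bp],
                    "label": [EUCHROMATIC, HETEROCHROMATIC],
                }
            )
            for c in chrom_names
        }
    )
    n_eu = int(round(cfg.euchromatic_locus_fraction * cfg.loci_per_chromosome))
    n_het = cfg.loci_per_chromosome - n_eu
    positions, chroms = [], []
    for c in chrom_names:
        pos_eu = rng.choice(np.arange(1, eu_end), size=n_eu, replace=False)
        pos_het = rng.choice(np.arange(eu_end + 1, cfg.chromosome_bp), size=n_het, replace=False)
        pos = np.sort(np.concatenate([pos_eu, pos_het]))
        positions.append(pos)
        chroms.extend([c] * cfg.loci_per_chromosome)
    positions = np.concatenate(positions)
    total = len(positions)
    locus_ids = [f"ss{k + 1:05d}" for k in range(total)]
    ref = rng.choice(list("ACGT"), size=total)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    loci = locus_table(locus_ids, chroms, positions, ref, alt)
    loci["region_class"] = [
        regions.class_of(c, int(p)) for c, p in zip(loci["chromosome"], loci["position"])
    ]
    pos_by_chrom = {c: loci.loc[loci["chromosome"] == c, "position"].to_numpy() for c in chrom_names}
    idx_by_chrom = {c: loci.index[loci["chromosome"] == c].to_numpy() for c in chrom_names}

    # --- planted blocks ---------------------------------------------------
    planted_blocks: list[dict] = []
    block_mask = np.zeros(total, dtype=bool)  # loci inside planted blocks
    suppress_gap = {c: np.zeros(cfg.loci_per_chromosome - 1, dtype=bool) for c in chrom_names}
    for c in chrom_names:
        pos = pos_by_chrom[c]
        # spread block starts over the euchromatic arm, away from each other
        for b in range(cfg.planted_blocks_per_chromosome):
            lo = int((b + 0.3) * eu_end / max(cfg.planted_blocks_per_chromosome, 1))
            start = lo
            end = start + cfg.planted_block_span_bp
            inside = np.flatnonzero((pos >= start) & (pos <= end))
            if len(inside) < 3:
                continue
            gidx = idx_by_chrom[c][inside]
            block_mask[gidx] = True
            suppress_gap[c][inside[0] : inside[-1]] = True
            planted_blocks.append(
                {
                    "chromosome": c,
                    "start_bp": int(pos[inside[0]]),
                    "end_bp": int(pos[inside[-1]]),
                    "locus_ids": [locus_ids[k] for k in gidx],
                }
            )

    # --- founder haplotype pool ------------------------------------------
    freq = rng.uniform(0.15, 0.85, size=total)
    protos = (rng.random((cfg.n_proto, total)) < freq).astype(np.int8)
    proto_probs = {}
    for c in chrom_names:
        pos = pos_by_chrom[c]
        mid = (pos[:-1] + pos[1:]) / 2
        rate = np.where(
            mid < eu_end,
            cfg.proto_switch_per_bp,
            cfg.proto_switch_per_bp * cfg.heterochromatic_multiplier,
        )
        p = 1.0 - np.exp(-rate * np.diff(pos))
        p[suppress_gap[c]] = 0.0
        proto_probs[c] = p
    founders = np.empty((cfg.n_founders, total), dtype=np.int8)
    for c in chrom_names:
        cols = idx_by_chrom[c]
        sub = protos[:, cols]
        for f in range(cfg.n_founders):
            founders[f, cols] = _mosaic(rng, sub, proto_probs[c])
    # inside planted blocks only two complementary haplotypes segregate
    for blk in planted_blocks:
        cols = [locus_ids.index(lid) for lid in blk["locus_ids"]]
        hap = (rng.random(len(cols)) < 0.5).astype(np.int8)
        carrier = rng.random(cfg.n_founders) < rng.uniform(0.3, 0.7)
        for f in range(cfg.n_founders):
            founders[f, cols] = hap if carrier[f] else 1 - hap

    # --- per-gap switch probabilities ------------------------------------
    def gap_probs(rate_eu: float) -> dict[str, np.ndarray]:
        out = {}
        for c in chrom_names:
            pos = pos_by_chrom[c]
            gaps = np.diff(pos)
            mid = (pos[:-1] + pos[1:]) / 2
            rate = np.where(mid < eu_end, rate_eu, rate_eu * cfg.heterochromatic_multiplier)
            p = 1.0 - np.exp(-rate * gaps)
            p[suppress_gap[c]] = 0.0
            out[c] = p
        return out

    def draw_population(pool: np.ndarray, n: int, rate: float) -> np.ndarray:
        probs = gap_probs(rate)
        hap = np.empty((n, total), dtype=np.int8)
        for c in chrom_names:
            cols = idx_by_chrom[c]
            sub = pool[:, cols]
            for a in range(n):
                hap[a, cols] = _mosaic(rng, sub, probs[c])
        return hap

    # nested founder bottlenecks: each cultivated pool is a small subset of
    # the previous pool's haplotypes, so diversity shrinks and LD lengthens
    # down the chain
    wild = draw_population(founders, cfg.n_wild, cfg.wild_switch_per_bp)
    landrace_pool = founders[
        rng.choice(cfg.n_founders, size=cfg.landrace_founder_count, replace=False)
    ]
    landrace = draw_population(landrace_pool, cfg.n_landrace, cfg.landrace_switch_per_bp)
    cultivar_pool = landrace_pool[
        rng.choice(cfg.landrace_founder_count, size=cfg.cultivar_founder_count, replace=False)
    ]
    cultivar = draw_population(cultivar_pool, cfg.n_cultivar, cfg.cultivar_switch_per_bp)

    # --- planted selection in the cultivar bottleneck ---------------------
    candidates = np.flatnonzero(~block_mask)
    rng.shuffle(candidates)
    selected_idx = np.sort(candidates[: cfg.n_selected])
    # causal loci need a workable frequency in the cultivated material, else
    # the dichotomized trait degenerates to all-case or all-control
    if cfg.n_causal:
        cultivated = np.vstack([landrace, cultivar])
        cult_freq = cultivated.mean(axis=0)
        pool_left = candidates[cfg.n_selected :]
        eligible = pool_left[(cult_freq[pool_left] >= 0.2) & (cult_freq[pool_left] <= 0.5)]
        if len(eligible) < cfg.n_causal:
            eligible = pool_left[(cult_freq[pool_left] >= 0.1) & (cult_freq[pool_left] <= 0.6)]
        if len(eligible) < cfg.n_causal:
            raise ValueError("too few polymorphic loci for the requested causal loci")
        causal_idx = np.sort(rng.choice(eligible, size=cfg.n_causal, replace=False))
    else:
        causal_idx = np.array([], dtype=int)
    for k in selected_idx:
        p_land = landrace[:, k].mean()
        target = 1 if p_land < 0.5 else 0  # push the landrace-minor allele up
        force = rng.random(cfg.n_cultivar) < cfg.selection_freq
        cultivar[force, k] = target

    haplotypes = np.vstack([wild, landrace, cultivar])
    pops = [WILD] * cfg.n_wild + [LANDRACE] * cfg.n_landrace + [CULTIVAR] * cfg.n_cultivar
    ids = (
        [f"W{k + 1:04d}" for k in range(cfg.n_wild)]
        + [f"L{k + 1:04d}" for k in range(cfg.n_landrace)]
        + [f"C{k + 1:04d}" for k in range(cfg.n_cultivar)]
    )

    pop_freq = pd.DataFrame(
        {
            "locus_id": locus_ids,
            WILD: wild.mean(axis=0),
            LANDRACE: landrace.mean(axis=0),
            CULTIVAR: cultivar.mean(axis=0),
        }
    )

    # --- trait (seed weight recorded for cultivated material only) --------
    effects = np.asarray(cfg.causal_effects, dtype=float)
    genetic = haplotypes[:, causal_idx] @ effects if cfg.n_causal else np.zeros(len(ids))
    weight = cfg.trait_base + genetic + rng.normal(0, cfg.trait_noise_sd, size=len(ids))
    weight = np.clip(weight, 0.1, None)

    # --- inbred calls + noise --------------------------------------------
    calls = (haplotypes * 2).astype(np.int8)
    u = rng.random(calls.shape)
    calls[u < cfg.het_rate] = 1
    calls[(u >= cfg.het_rate) & (u < cfg.het_rate + cfg.missing_rate)] = -1

    # --- planted duplicates (copied AFTER noise so corruption alone differs)
    dup_groups: list[tuple[str, ...]] = []
    dup_rows, dup_ids, dup_pops, dup_weights = [], [], [], []
    src_choices = rng.choice(len(ids), size=cfg.n_duplicate_pairs, replace=False)
    for s in src_choices:
        dup_id = f"{ids[s]}dup"
        row = calls[s].copy()
        if cfg.duplicate_corruption_rate > 0:
            called = row != -1
            flip = called & (rng.random(total) < cfg.duplicate_corruption_rate)
            row[flip] = 2 - row[flip]  # flip between the homozygous states
        dup_rows.append(row)
        dup_ids.append(dup_id)
        dup_pops.append(pops[s])
        dup_weights.append(weight[s])
        dup_groups.append((ids[s], dup_id))
    if dup_rows:
        calls = np.vstack([calls, np.array(dup_rows, dtype=np.int8)])
        ids = ids + dup_ids
        pops = pops + dup_pops
        weight = np.concatenate([weight, dup_weights])

    meta = pd.DataFrame(
        {
            "population": pops,
            "country": [rng.choice(_COUNTRIES[p]) for p in pops],
        },
        index=pd.Index(ids, name="accession"),
    )
    genotypes = GenotypeMatrix(ids, loci, calls, accession_meta=meta)

    # --- genetic map and genes -------------------------------------------
    map_rows = []
    for c in chrom_names:
        pos = pos_by_chrom[c]
        gaps = np.diff(pos)
        mid = (pos[:-1] + pos[1:]) / 2
        rate = np.where(
            mid < eu_end, cfg.map_cm_per_mb_eu, cfg.map_cm_per_mb_het
        ) / 1e6
        rate = np.where(suppress_gap[c], 0.0, rate)
        cm = np.concatenate([[0.0], np.cumsum(rate * gaps)])
        for lid_idx, p, v in zip(idx_by_chrom[c], pos, cm):
            map_rows.append((locus_ids[lid_idx], c, int(p), float(v)))
    genetic_map = pd.DataFrame(map_rows, columns=["locus_id", "chrom", "pos", "cM"])

    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    gene_rows = []
    gid = 1
    for c, n_g in zip(chrom_names, per_chrom):
        for p in np.sort(rng.integers(1, cfg.chromosome_bp, size=n_g)):
            gene_rows.append((c, int(p), f"Gene{gid:05d}"))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "gene_id"])

    cultivated_rows = [k for k, p in enumerate(pops) if p in (LANDRACE, CULTIVAR)]
    trait = pd.DataFrame(
        {
            "accession": [ids[k] for k in cultivated_rows],
            "weight": np.round(weight[cultivated_rows], 2),
        }
    )

    truth = SyntheticTruth(
        duplicate_groups=dup_groups,
        planted_blocks=planted_blocks,
        selected_loci=[locus_ids[k] for k in selected_idx],
        causal_loci=[locus_ids[k] for k in causal_idx],
        causal_effects={locus_ids[k]: float(e) for k, e in zip(causal_idx, effects)},
        population_frequencies=pop_freq,
    )
    return SimulatedCollection(
        config=cfg,
        genotypes=genotypes,
        regions=regions,
        genetic_map=genetic_map,
        genes=genes,
        trait=trait,
        truth=truth,
    )


# ----------------------------------------------------------------------
# small purpose-built generators
# ----------------------------------------------------------------------

def two_island_genotypes(
    freqs_a, freqs_b, n_per_pop: int, seed: int = 0
) -> GenotypeMatrix:
    """Independent-locus two-population sample at the given ALT frequencies."""
    rng = np.random.default_rng(seed)
    freqs_a = np.asarray(freqs_a, float)
    freqs_b = np.asarray(freqs_b, float)
    m = len(freqs_a)
    a = (rng.random((n_per_pop, m)) < freqs_a).astype(np.int8) * 2
    b = (rng.random((n_per_pop, m)) < freqs_b).astype(np.int8) * 2
    ids = [f"A{k:04d}" for k in range(n_per_pop)] + [f"B{k:04d}" for k in range(n_per_pop)]
    loci = locus_table(
        [f"m{k:05d}" for k in range(m)], ["Chr01"] * m, np.arange(1, m + 1) * 1000
    )
    meta = pd.DataFrame(
        {"population": ["A"] * n_per_pop + ["B"] * n_per_pop},
        index=pd.Index(ids, name="accession"),
    )
    return GenotypeMatrix(ids, loci, np.vstack([a, b]), accession_meta=meta)


# ----------------------------------------------------------------------
# truth scoring
# ----------------------------------------------------------------------

def _group_pairs(groups) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for grp in groups:
        members = list(grp)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(frozenset((members[i], members[j])))
    return pairs


def duplicate_scores(truth: SyntheticTruth, groups) -> dict[str, float]:
    """Pair-level precision/recall of recovered duplicate groups."""
    true_pairs = _group_pairs(truth.duplicate_groups)
    pred_pairs = _group_pairs([g.members for g in groups])
    tp = len(true_pairs & pred_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else float("nan")
    recall = tp / len(true_pairs) if true_pairs else float("nan")
    return {"precision": precision, "recall": recall}


def planted_block_jaccard(truth: SyntheticTruth, bmap) -> float:
    """Mean over planted blocks of the best locus-set Jaccard with a found block."""
    scores = []
    for blk in truth.planted_blocks:
        target = set(blk["locus_ids"])
        best = 0.0
        for b in bmap.blocks:
            if b.chromosome != blk["chromosome"]:
                continue
            found = set(b.locus_ids)
            inter = len(target & found)
            union = len(target | found)
            if union:
                best = max(best, inter / union)
        scores.append(best)
    return float(np.mean(scores)) if scores else float("nan")


def selected_locus_ranks(truth: SyntheticTruth, scan) -> pd.DataFrame:
    """Rank percentile (1 = top) and significance of each planted selected locus."""
    table = scan.table.sort_values("fst", ascending=False).reset_index(drop=True)
    rank = {lid: k for k, lid in enumerate(table["locus_id"])}
    rows = []
    for lid in truth.selected_loci:
        if lid not in rank:
            continue
        r = rank[lid]
        rows.append(
            {
                "locus_id": lid,
                "rank": r + 1,
                "percentile": 1.0 - r / len(table),
                "significant": bool(table.loc[r, "fst"] >= scan.threshold),
            }
        )
    return pd.DataFrame(rows)


def causal_locus_recovery(truth: SyntheticTruth, results: pd.DataFrame) -> float:
    """Fraction of planted causal loci called significant in the GWAS results."""
    sig = set(results.loc[results["significant"], "locus_id"])
    if not truth.causal_loci:
        return float("nan")
    return sum(lid in sig for lid in truth.causal_loci) / len(truth.causal_loci)


def truth_report(
    truth: SyntheticTruth,
    groups=None,
    block_map=None,
    fst_scan=None,
    gwas_results=None,
) -> dict:
    """Scorecard of pipeline outputs against the planted truth."""
    report: dict = {}
    if groups is not None:
        report["duplicates"] = duplicate_scores(truth, groups)
    if block_map is not None:
        report["block_jaccard"] = planted_block_jaccard(truth, block_map)
    if fst_scan is not None:
        ranks = selected_locus_ranks(truth, fst_scan)
        report["selected_loci"] = {
            "n_planted": len(truth.selected_loci),
            "n_significant": int(ranks["significant"].sum()) if len(ranks) else 0,
            "mean_percentile": float(ranks["percentile"].mean()) if len(ranks) else float("nan"),
        }
    if gwas_results is not None:
        report["causal_recovery"] = causal_locus_recovery(truth, gwas_results)
    return report
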