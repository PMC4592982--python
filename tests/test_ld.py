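"""Two-locus LD statistics, D' confidence intervals and decay curves."""

import math

import numpy as np
import pandas as pd
import pytest

from germscan import ALT_HOM, MISSING, REF_HOM, io, ld, simulate

from conftest import make_matrix

A, B, N = REF_HOM, ALT_HOM, MISSING


def counts(nAB, nAb, naB, nab):
    return ld.HaplotypeCounts2(nAB, nAb, naB, nab)


def test_hap_counts_from_inbred_calls():
    """Each jointly called accession contributes one two-locus haplotype;
    missing at either locus excludes the accession."""
    g = make_matrix(np.array([
        [B, B], [B, B], [A, A], [A, A], [N, B], [B, N],
    ]))
    c = ld.hap_counts(g, "L001", "L002")
    assert (c.nAB, c.nAb, c.naB, c.nab) == (2, 0, 0, 2)
    assert c.n == 4


def test_hap_counts_rejects_cross_chromosome():
    g = make_matrix(np.array([[B, B]]), chromosomes=["Chr01", "Chr02"])
    with pytest.raises(ValueError, match="same chromosome"):
        ld.hap_counts(g, "L001", "L002")


@pytest.mark.parametrize(
    "c, r2, dprime",
    [
        (counts(50, 0, 0, 50), 1.0, 1.0),  # perfect LD
        (counts(40, 10, 10, 40), 0.36, 0.6),  # D=0.15, closed forms
        (counts(25, 25, 25, 25), 0.0, 0.0),  # independence
    ],
)
def test_ld_stats_closed_forms(c, r2, dprime):
    got_r2, got_dp = ld.ld_stats(c)
    assert got_r2 == pytest.approx(r2)
    assert got_dp == pytest.approx(dprime)


def test_ld_stats_label_and_locus_swap_invariance():
    c = counts(40, 10, 5, 45)
    base = ld.ld_stats(c)
    swapped_allele = counts(10, 40, 45, 5)  # relabel locus A's alleles
    swapped_locus = counts(40, 5, 10, 45)  # swap the two loci
    assert ld.ld_stats(swapped_allele) == pytest.approx(base)
    assert ld.ld_stats(swapped_locus) == pytest.approx(base)


def test_ld_stats_uninformative():
    with pytest.raises(ValueError):
        ld.ld_stats(counts(10, 0, 10, 0))  # locus B monomorphic


def _ci_oracle(c, confidence=0.95, step=0.001):
    """Independent likelihood-grid evaluation (plain Python, no shortcuts)."""
    n = c.n
    pA = (c.nAB + c.nAb) / n
    pB = (c.nAB + c.naB) / n
    nAB, nAb, naB, nab = c.nAB, c.nAb, c.naB, c.nab
    if nAB / n - pA * pB < 0:
        nAB, nAb, naB, nab = nAb, nAB, nab, naB
        pB = 1 - pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    grid = [k * step for k in range(int(round(1 / step)) + 1)]
    liks = []
    for dp in grid:
        d = dp * dmax
        probs = [pA * pB + d, pA * (1 - pB) - d, (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d]
        ll = 0.0
        for cnt, p in zip((nAB, nAb, naB, nab), probs):
            ll += cnt * math.log(max(p, 1e-12))
        liks.append(ll)
    mx = max(liks)
    weights = [math.exp(v - mx) for v in liks]
    total = sum(weights)
    cum, lo, hi = 0.0, None, None
    for gval, w in zip(grid, weights):
        cum += w / total
        if lo is None and cum >= 1 - confidence:
            lo = gval
        if hi is None and cum >= confidence:
            hi = gval
    return lo, hi


@pytest.mark.parametrize(
    "c",
    [
        counts(100, 0, 0, 100),
        counts(5, 5, 5, 5),
        counts(40, 10, 10, 40),
        counts(70, 3, 2, 25),
        counts(12, 30, 28, 10),
    ],
)
def test_dprime_ci_matches_independent_grid_oracle(c):
    assert ld.dprime_ci(c) == pytest.approx(_ci_oracle(c), abs=1e-12)


def test_dprime_ci_concentration():
    """Perfect-LD counts concentrate the CI near 1 (strong LD); a flat 4x5
    table fails the strong-LD criterion; doubling counts never widens the CI."""
    lo, hi = ld.dprime_ci(counts(100, 0, 0, 100))
    assert lo > 0.9 and hi > 0.98
    assert ld.classify_pair(lo, hi) == ld.STRONG_LD
    lo_flat, hi_flat = ld.dprime_ci(counts(5, 5, 5, 5))
    assert hi_flat < 0.98
    lo1, hi1 = ld.dprime_ci(counts(30, 6, 7, 29))
    lo2, hi2 = ld.dprime_ci(counts(60, 12, 14, 58))
    assert hi2 - lo2 <= hi1 - lo1 + 1e-12


def test_window_pair_combinatorics():
    """5 loci within the window give 10 pairs; a pair past the window or on
    another chromosome is never emitted."""
    calls = np.tile([[B] * 7, [B] * 7, [A] * 7, [A] * 7], 1)
    g = make_matrix(
        np.array(calls),
        positions=[1, 1000, 2000, 3000, 4000, 1_000_002, 500],
        chromosomes=["Chr01"] * 6 + ["Chr02"],
    )
    g.loci.loc[:, "region_class"] = "euchromatic"
    pairs = ld.window_pairs(g, max_bp=1_000_000)
    first_five = {f"L{k:03d}" for k in range(1, 6)}
    within = pairs[pairs["locus_a"].isin(first_five) & pairs["locus_b"].isin(first_five)]
    assert len(within) == 10
    assert not ((pairs["locus_a"] == "L001") & (pairs["locus_b"] == "L006")).any()
    assert not (pairs["locus_a"] == "L007").any() or not (
        pairs[pairs["locus_a"] == "L007"]["chromosome"] != "Chr02"
    ).any()


def test_window_pairs_match_scalar_path(qc_matrix):
    """Vectorised window statistics equal the per-pair scalar functions."""
    sub = qc_matrix.subset_loci(np.arange(25))
    pairs = ld.window_pairs(sub)
    sample = pairs.dropna(subset=["r2"]).sample(15, random_state=0)
    for row in sample.itertuples():
        c = ld.hap_counts(sub, row.locus_a, row.locus_b)
        r2, dp = ld.ld_stats(c)
        lo, hi = ld.dprime_ci(c)
        assert row.r2 == pytest.approx(r2)
        assert row.dprime == pytest.approx(dp)
        assert (row.ci_low, row.ci_high) == pytest.approx((lo, hi))
        assert row.pair_class == ld.classify_pair(lo, hi)


def test_point_estimate_within_ci(qc_matrix):
    """The percentile CI brackets the D' point estimate when the estimate is
    interior; at the 0/1 boundaries the percentile construction may sit a few
    grid steps inside, so those estimates are excluded."""
    pairs = ld.window_pairs(qc_matrix.subset_loci(np.arange(60)))
    interior = pairs.dropna(subset=["dprime"]).query("0.05 < dprime < 0.95")
    assert len(interior) > 50
    grid_tol = 2 * ld.CI_GRID_STEP
    assert (interior["ci_low"] <= interior["dprime"] + grid_tol).all()
    assert (interior["ci_high"] >= interior["dprime"] - grid_tol).all()


def test_decay_curve_binning_and_empty_bins():
    pairs = pd.DataFrame(
        {
            "dist": [5_000, 5_500, 25_000],
            "r2": [0.2, 0.4, 0.1],
            "region_a": ["euchromatic"] * 3,
            "region_b": ["euchromatic"] * 3,
        }
    )
    curve = ld.decay_curve(pairs, bin_bp=10_000, region_class="euchromatic")
    assert curve.loc[0, "mean_r2"] == pytest.approx(0.3)
    assert curve.loc[1, "n_pairs"] == 0 and np.isnan(curve.loc[1, "mean_r2"])
    assert ld.decay_curve(pairs, 10_000, region_class="heterochromatic").empty


def test_half_decay_rule():
    """First bin at or below half of the curve maximum, by midpoint."""
    curve = pd.DataFrame(
        {
            "bin_start": [0, 10_000, 20_000, 30_000],
            "bin_end": [10_000, 20_000, 30_000, 40_000],
            "mean_r2": [0.6, 0.5, 0.29, 0.2],
            "n_pairs": [5, 5, 5, 5],
        }
    )
    assert ld.half_decay_distance(curve) == 25_000
    flat = curve.assign(mean_r2=[0.4] * 4)
    assert ld.half_decay_distance(flat) == ld.NOT_REACHED
    # maximum taken from the curve peak wherever it sits
    humped = curve.assign(mean_r2=[0.5, 0.8, 0.45, 0.3])
    assert ld.half_decay_distance(humped) == 35_000
    with pytest.raises(ValueError):
        ld.half_decay_distance(curve.iloc[:1])


def test_perfect_ld_limit_two_haplotype_system():
    """With recombination off and two complementary founder haplotypes every
    polymorphic pair is in perfect LD."""
    cfg = simulate.SimulationConfig(
        seed=5, n_chromosomes=1, loci_per_chromosome=40, n_proto=2,
        proto_switch_per_bp=0.0, n_founders=4,
        landrace_founder_count=4, cultivar_founder_count=2,
        wild_switch_per_bp=0.0, landrace_switch_per_bp=0.0, cultivar_switch_per_bp=0.0,
        het_rate=0.0, missing_rate=0.0, planted_blocks_per_chromosome=0,
        n_selected=0, n_causal=0, causal_effects=(), n_duplicate_pairs=0,
    )
    sim = simulate.simulate_collection(cfg)
    g = io.maf_filter(io.apply_het_to_missing(sim.genotypes))
    pairs = ld.window_pairs(g, max_bp=10_000_000)
    informative = pairs.dropna(subset=["r2"])
    assert len(informative) > 0
    assert np.allclose(informative["r2"], 1.0)


# ----------------------------------------------------------------------
# property tests
# ----------------------------------------------------------------------

from hypothesis import given, settings, strategies as st

_count = st.integers(min_value=0, max_value=500)


@settings(derandomize=True, max_examples=200)
@given(nAB=_count, nAb=_count, naB=_count, nab=_count)
def test_ld_stats_bounds_and_symmetries(nAB, nAb, naB, nab):
    """For every informative table: r2, D' in [0,1]; invariance under allele
    relabelling at either locus and under swapping the loci; CI ordered."""
    c = counts(nAB, nAb, naB, nab)
    n = c.n
    if n == 0:
        return
    pA = (nAB + nAb) / n
    pB = (nAB + naB) / n
    if pA in (0, 1) or pB in (0, 1):
        with pytest.raises(ValueError):
            ld.ld_stats(c)
        return
    r2, dp = ld.ld_stats(c)
    assert -1e-12 <= r2 <= 1 + 1e-12
    assert -1e-12 <= dp <= 1 + 1e-12
    for other in (
        counts(nAb, nAB, nab, naB),  # flip locus A alleles
        counts(naB, nab, nAB, nAb),  # flip locus B alleles
        counts(nAB, naB, nAb, nab),  # swap the two loci
    ):
        assert ld.ld_stats(other) == pytest.approx((r2, dp))
    lo, hi = ld.dprime_ci(c)
    assert 0 <= lo <= hi <= 1
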