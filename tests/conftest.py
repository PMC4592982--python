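"""Shared fixtures: tiny hand-built matrices and one full synthetic collection.

The expensive pieces (the simulated collection and its per-population LD /
block maps) are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from germscan import GenotypeMatrix, RegionClassMap, io, ld, blocks, locus_table, simulate


def make_matrix(calls, positions=None, chromosomes=None, accession_ids=None,
                locus_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list of calls (accessions x loci)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_loci = calls.shape
    if accession_ids is None:
        accession_ids = [f"acc{k + 1:02d}" for k in range(n_acc)]
    if positions is None:
        positions = (np.arange(n_loci) + 1) * 1000
    if chromosomes is None:
        chromosomes = ["Chr01"] * n_loci
    if locus_ids is None:
        locus_ids = [f"L{k + 1:03d}" for k in range(n_loci)]
    return GenotypeMatrix(
        accession_ids=list(accession_ids),
        loci=locus_table(locus_ids, chromosomes, positions),
        calls=calls,
    )


@pytest.fixture(scope="session")
def collection():
    """Default-configuration synthetic collection (seed 1)."""
    return simulate.simulate_collection(simulate.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def qc_matrix(collection):
    """Collection genotypes after the full QC chain (filters, masking, MAF)."""
    g = io.filter_loci(collection.genotypes)
    g = io.apply_het_to_missing(g)
    g = io.maf_filter(g)
    return io.assign_region_class(g, collection.regions)


@pytest.fixture(scope="session")
def population_ld(collection, qc_matrix):
    """Per-population LD pair tables and block maps on the QC'd matrix."""
    out = {}
    for pop in ("wild", "landrace", "cultivar"):
        sub = io.maf_filter(qc_matrix.subset_accessions(collection.population_ids(pop)))
        pairs = ld.window_pairs(sub)
        bmap = blocks.find_blocks(pairs, sub.loci, population=pop)
        out[pop] = {"matrix": sub, "pairs": pairs, "blocks": bmap}
    return out
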