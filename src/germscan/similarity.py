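"""Pairwise accession similarity and redundancy-group construction.

Similarity between two accessions is the fraction of loci, called in both,
at which the two calls are identical.  Redundancy groups are the
single-linkage connected components of the graph whose edges join pairs at
or above a similarity threshold — i.e. an accession belongs to a group as
soon as it is sufficiently similar to at least one other accession.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import HET, MISSING, GenotypeMatrix

PAIR_COLUMNS = ["accession_a", "accession_b", "shared_called", "identical", "similarity"]


@dataclass(frozen=True)
class RedundancyGroup:
    members: tuple[str, ...]
    representative: str
    threshold: float

    def __len__(self) -> int:
        return len(self.members)


def pairwise_similarity(
    g: GenotypeMatrix, within=None, block_size: int = 256
) -> pd.DataFrame:
    """All unordered accession pairs with shared/identical counts and similarity.

    Loci missing in either member are excluded from both numerator and
    denominator; a pair with no shared called locus gets similarity NaN.
    Computation is blocked over accessions to bound memory; results equal the
    naive all-pairs loop.
    """
    if (g.calls == HET).any():
        raise ValueError("pairwise similarity requires het-masked input")
    ids = list(g.accession_ids) if within is None else list(within)
    if len(ids) < 2:
        warnings.warn("fewer than 2 accessions: no pairs to compare")
        return pd.DataFrame(columns=PAIR_COLUMNS)
    idx = g.accession_index(ids)
    calls = g.calls[idx]
    called = calls != MISSING
    n = len(ids)
    rows_a, rows_b, shared_all, ident_all = [], [], [], []
    calledf = called.astype(np.float32)
    # alt indicator on called loci; missing contributes 0 to both products
    altf = ((calls == 2) & called).astype(np.float32)
    reff = ((calls == 0) & called).astype(np.float32)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        shared = calledf[start:stop] @ calledf.T
        ident = altf[start:stop] @ altf.T + reff[start:stop] @ reff.T
        for bi in range(start, stop):
            js = np.arange(bi + 1, n)
            rows_a.extend([ids[bi]] * len(js))
            rows_b.extend(ids[j] for j in js)
            shared_all.append(shared[bi - start, js])
            ident_all.append(ident[bi - start, js])
    shared_arr = np.concatenate(shared_all).astype(np.int64) if shared_all else np.empty(0, np.int64)
    ident_arr = np.concatenate(ident_all).astype(np.int64) if ident_all else np.empty(0, np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(shared_arr > 0, ident_arr / np.maximum(shared_arr, 1), np.nan)
    return pd.DataFrame(
        {
            "accession_a": rows_a,
            "accession_b": rows_b,
            "shared_called": shared_arr,
            "identical": ident_arr,
            "similarity": sim,
        }
    )


def redundancy_groups(pairs: pd.DataFrame, threshold: float) -> list[RedundancyGroup]:
    """Single-linkage groups over edges with similarity >= ``threshold``.

    Singletons are not reported; each group's representative is its
    lexicographically smallest member id.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    edges = pairs[pairs["similarity"] >= threshold]
    graph = nx.Graph()
    graph.add_edges_from(zip(edges["accession_a"], edges["accession_b"]))
    groups = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        if len(members) >= 2:
            groups.append(
                RedundancyGroup(members=members, representative=members[0], threshold=threshold)
            )
    groups.sort(key=lambda grp: grp.representative)
    return groups


def grouped_accessions(groups) -> set[str]:
    out: set[str] = set()
    for grp in groups:
        out.update(grp.members)
    return out


def summarize_redundancy(groups_100, groups_999, n_total: int) -> pd.DataFrame:
    """Collection-level redundancy summary at the 100% and 99.9% thresholds.

    Reports the number of accessions belonging to any group at each
    threshold and that count as a percentage of the collection, rounded to
    the nearest integer percent.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    rows = []
    for label, groups in (("identical", groups_100), ("similar_999", groups_999)):
        count = len(grouped_accessions(groups))
        rows.append(
            {
                "threshold": label,
                "n_grouped": count,
                "n_total": n_total,
                "percent": int(round(100.0 * count / n_total)),
            }
        )
    return pd.DataFrame(rows)


def deduplicate(g: GenotypeMatrix, groups) -> GenotypeMatrix:
    """Keep one representative per redundancy group plus all ungrouped accessions."""
    drop: set[str] = set()
    seen: set[str] = set()
    for grp in groups:
        for m in grp.members:
            if m not in g.accession_ids:
                raise KeyError(f"group member {m!r} absent from genotype matrix")
            if m in seen:
                raise ValueError(f"accession {m!r} appears in more than one group")
            seen.add(m)
            if m != grp.representative:
                drop.add(m)
    keep = [a for a in g.accession_ids if a not in drop]
    return g.subset_accessions(keep)
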