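"""Allelic-dissimilarity distances and Saitou–Nei neighbor joining.

Distances are pairwise-deletion p-distances (1 − similarity); no
evolutionary-model correction is applied.  The NJ implementation is
deterministic: Q-matrix ties break on the smallest (i, j) index pair, and
negative branch lengths are clamped to zero with the deficit transferred to
the sister branch so Newick consumers see nonnegative lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix
from .similarity import pairwise_similarity


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")


def distance_matrix(g: GenotypeMatrix, within=None) -> DistanceMatrix:
    """1 − similarity over all accession pairs; errors when any pair shares no calls."""
    ids = list(g.accession_ids) if within is None else list(within)
    pairs = pairwise_similarity(g, within=ids)
    undefined = pairs[pairs["shared_called"] == 0]
    if len(undefined):
        listing = ", ".join(
            f"({r.accession_a},{r.accession_b})" for r in undefined.head(10).itertuples()
        )
        raise ValueError(f"pairs with no shared called loci: {listing}")
    pos = {a: i for i, a in enumerate(ids)}
    d = np.zeros((len(ids), len(ids)))
    for r in pairs.itertuples():
        i, j = pos[r.accession_a], pos[r.accession_b]
        d[i, j] = d[j, i] = 1.0 - r.similarity
    return DistanceMatrix(ids=ids, values=d)


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c._nwk()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def _clamp_pair(bi: float, bj: float) -> tuple[float, float]:
    # move any negative-length deficit onto the sister branch
    if bi < 0:
        bj = max(bj + bi, 0.0)
        bi = 0.0
    elif bj < 0:
        bi = max(bi + bj, 0.0)
        bj = 0.0
    return bi, bj


def neighbor_joining(d: DistanceMatrix) -> str:
    """Build an unrooted NJ tree from ``d``; returns a Newick string.

    Requires at least 3 taxa.  Agglomeration order is deterministic
    (smallest (i, j) among Q minima); the final three lineages are joined by
    the three-point formulas.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [_Node(label=str(t)) for t in d.ids]
    dist = d.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: first (i,j) in row-major order at the minimum
        flat = np.argmin(q)
        ai, aj = np.unravel_index(flat, q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        bi = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2.0 * (m - 2))
        bj = sub[ai, aj] - bi
        bi, bj = _clamp_pair(bi, bj)
        new = _Node(children=[(nodes[i], bi), (nodes[j], bj)])
        # distances from the new node to every remaining taxon
        newdist = 0.5 * (dist[i] + dist[j] - dist[i, j])
        k = len(nodes)
        nodes.append(new)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[k, :k] = newdist[:k]
        dist[:k, k] = newdist[:k]
        active = [a for a in active if a not in (i, j)] + [k]

    i, j, k = active
    bi = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    bj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    bk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    bi, bj, bk = (max(b, 0.0) for b in (bi, bj, bk))
    root = _Node(children=[(nodes[i], bi), (nodes[j], bj), (nodes[k], bk)])
    return root.newick()


def write_phylip(d: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix export."""
    with open(path, "w") as fh:
        fh.write(f"{len(d.ids)}\n")
        for i, name in enumerate(d.ids):
            row = " ".join(f"{v:.6f}" for v in d.values[i])
            fh.write(f"{name:<10s} {row}\n")
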