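"""Core containers for inbred SNP genotype data.

Calls are stored as a dense ``int8`` matrix (accessions x loci) with the
coding used by the TSV matrix format:

====  =========
code  state
====  =========
0     REF_HOM
1     HET
2     ALT_HOM
-1    MISSING
====  =========

Because the accessions are near-fully homozygous inbreds, a homozygous
genotype is treated downstream as a single haploid observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REF_HOM: int = 0
HET: int = 1
ALT_HOM: int = 2
MISSING: int = -1

#: region-class labels
EUCHROMATIC = "euchromatic"
HETEROCHROMATIC = "heterochromatic"
UNASSIGNED = "unassigned"

LOCUS_COLUMNS = ["locus_id", "chromosome", "position", "ref", "alt", "region_class"]
#: columns carried by the interchange formats (region class is an annotation)
CORE_LOCUS_COLUMNS = ["locus_id", "chromosome", "position", "ref", "alt"]


def locus_table(
    locus_ids,
    chromosomes,
    positions,
    ref=None,
    alt=None,
    region_class=None,
) -> pd.DataFrame:
    """Assemble a locus-index DataFrame with the canonical columns."""
    n = len(locus_ids)
    df = pd.DataFrame(
        {
            "locus_id": list(locus_ids),
            "chromosome": list(chromosomes),
            "position": np.asarray(positions, dtype=np.int64),
            "ref": list(ref) if ref is not None else ["A"] * n,
            "alt": list(alt) if alt is not None else ["T"] * n,
            "region_class": list(region_class)
            if region_class is not None
            else [UNASSIGNED] * n,
        }
    )
    return df


@dataclass
class GenotypeMatrix:
    """Accessions x loci call matrix with locus and accession metadata.

    Loci are kept sorted by (chromosome, position); accession ids are unique.
    """

    accession_ids: list[str]
    loci: pd.DataFrame
    calls: np.ndarray
    accession_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids must be unique")
        if self.calls.shape != (len(self.accession_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, [REF_HOM, HET, ALT_HOM, MISSING])
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,-1}")
        self._sort_loci()

    def _sort_loci(self) -> None:
        order = np.lexsort(
            (self.loci["position"].to_numpy(), self.loci["chromosome"].to_numpy())
        )
        if not np.array_equal(order, np.arange(len(self.loci))):
            self.loci = self.loci.iloc[order].reset_index(drop=True)
            self.calls = self.calls[:, order]
        else:
            self.loci = self.loci.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def accession_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown accession id {exc.args[0]!r}") from None

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the loci selected by ``keep`` (bool or index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            loci=self.loci.iloc[keep].reset_index(drop=True),
            calls=self.calls[:, keep].copy(),
            accession_meta=self.accession_meta,
        )

    def subset_accessions(self, ids) -> "GenotypeMatrix":
        idx = self.accession_index(ids)
        meta = self.accession_meta
        if meta is not None:
            meta = meta.loc[meta.index.intersection(list(ids))]
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in idx],
            loci=self.loci.copy(),
            calls=self.calls[idx].copy(),
            accession_meta=meta,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            loci=self.loci.copy(),
            calls=self.calls.copy(),
            accession_meta=None if self.accession_meta is None else self.accession_meta.copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality over accession ids, core locus metadata and calls."""
        return (
            self.accession_ids == other.accession_ids
            and self.loci[CORE_LOCUS_COLUMNS].equals(other.loci[CORE_LOCUS_COLUMNS])
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class RegionClassMap:
    """Per-chromosome half-open [start, end) bp intervals labelled by region class.

    ``intervals`` maps chromosome -> DataFrame(start, end, label) with
    non-overlapping rows sorted by start.  Starts/ends are 0-based half-open
    (BED convention); locus positions are 1-based.
    """

    intervals: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, df in self.intervals.items():
            df = df.sort_values("start").reset_index(drop=True)
            if (df["end"] <= df["start"]).any():
                raise ValueError(f"empty interval on {chrom}")
            if (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
            self.intervals[chrom] = df

    def class_of(self, chrom: str, position: int) -> str:
        """Region class of a 1-based position; UNASSIGNED when uncovered."""
        df = self.intervals.get(chrom)
        if df is None:
            return UNASSIGNED
        pos0 = position - 1  # convert to 0-based for half-open test
        hit = df[(df["start"] <= pos0) & (pos0 < df["end"])]
        if hit.empty:
            return UNASSIGNED
        return str(hit.iloc[0]["label"])

    def class_bp(self, label: str, chrom: str | None = None) -> int:
        """Total bp covered by intervals of ``label`` (optionally one chromosome)."""
        total = 0
        for c, df in self.intervals.items():
            if chrom is not None and c != chrom:
                continue
            sub = df[df["label"] == label]
            total += int((sub["end"] - sub["start"]).sum())
        return total

    def chromosomes(self) -> list[str]:
        return sorted(self.intervals)
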