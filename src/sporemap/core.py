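"""Core in-memory containers shared across the pipeline.

Genotypes are coded as ``int8``: 1 = first parent, 2 = second parent,
0 = missing.  Spores within a tetrad are indexed 1..4; the fixed sister-pair
convention is {1,2} and {3,4} (spores 1,2 are the two chromatids of the
first-parent homolog before recombination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

MISSING = 0
P1 = 1
P2 = 2

#: the four non-sister chromatid pairs under the {1,2}/{3,4} sister convention
NON_SISTER_PAIRS: tuple[tuple[int, int], ...] = ((1, 3), (1, 4), (2, 3), (2, 4))

#: event-class labels (single-tetrad allelic segregation taxonomy):
#:   a  CO without conversion tract
#:   b  CO with a contiguous tract on an involved chromatid
#:   c  CO with a tract detached from the exchange on an involved chromatid
#:   d  CO with a tract on a chromatid not involved in the CO
#:   e  CO with a complex (multi-chromatid / fragmented) tract
#:   f  CO with tracts on both an involved and an uninvolved chromatid
#:   g  double CO (same chromatid pair) without tract
#:   h  double CO with tract
#:   i  double CO with complex tract
#:   j  simple NCO (3:1 tract, flanking phase unchanged)
#:   k  4:0 conversion tract
EVENT_CLASSES: tuple[str, ...] = tuple("abcdefghijk")
CO_CLASSES: frozenset[str] = frozenset("abcdefghi")
NCO_CLASSES: frozenset[str] = frozenset("jk")
TRACT_CO_CLASSES: frozenset[str] = frozenset("bcdefhi")


@dataclass
class MarkerMap:
    """Sorted marker positions per chromosome (0-based bp)."""

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions on {chrom!r} not strictly increasing")
            self.positions[chrom] = pos

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.positions[chrom]

    def median_spacing(self) -> float:
        gaps = np.concatenate(
            [np.diff(p) for p in self.positions.values() if len(p) > 1]
        )
        return float(np.median(gaps)) if len(gaps) else float("nan")


@dataclass
class TetradSet:
    """Four-spore genotypes for a set of tetrads on a shared marker map.

    ``genotypes[chrom]`` has shape ``(n_tetrads, 4, n_markers)`` with codes
    {0, 1, 2}.  The marker axis is shared by every tetrad.
    """

    markers: MarkerMap
    tetrad_names: list[str]
    genotypes: dict[str, np.ndarray]
    aneuploid_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.tetrad_names)
        for chrom, g in self.genotypes.items():
            g = np.asarray(g, dtype=np.int8)
            expected = (n, 4, len(self.markers[chrom]))
            if g.shape != expected:
                raise ValueError(
                    f"genotype array for {chrom!r} has shape {g.shape}, "
                    f"expected {expected}"
                )
            self.genotypes[chrom] = g

    @property
    def n_tetrads(self) -> int:
        return len(self.tetrad_names)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.genotypes)

    def spore_columns(self) -> list[str]:
        return [f"{t}_{s}" for t in self.tetrad_names for s in "abcd"]

    def copy(self) -> "TetradSet":
        return TetradSet(
            markers=MarkerMap({c: p.copy() for c, p in self.markers.positions.items()}),
            tetrad_names=list(self.tetrad_names),
            genotypes={c: g.copy() for c, g in self.genotypes.items()},
            aneuploid_flags=set(self.aneuploid_flags),
        )


EVENT_COLUMNS = [
    "tetrad", "chrom", "kind", "cls", "start", "end", "pos",
    "chromatids", "tract_start", "tract_end", "tract_len", "n_markers",
]


@dataclass
class EventCatalog:
    """Typed recombination events plus provenance.

    One row per event.  ``kind`` is "CO" or "NCO"; ``cls`` the taxonomy label
    (see :data:`EVENT_CLASSES`).  ``[start, end)`` is the exchange interval
    between flanking informative markers and ``pos`` its midpoint; tract
    columns are NaN when no conversion tract is detectable.  ``chromatids``
    is a "+"-joined list of spore indices (e.g. ``"2+3"``).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        self.df = self.df.sort_values(["tetrad", "chrom", "pos"], kind="stable")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def empty(cls, provenance: dict | None = None) -> "EventCatalog":
        return cls(events_frame([]), provenance or {})

    def __len__(self) -> int:
        return len(self.df)

    @property
    def crossovers(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "CO"]

    @property
    def noncrossovers(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "NCO"]

    def per_tetrad_counts(self, kind: str | None = None) -> pd.Series:
        df = self.df if kind is None else self.df[self.df["kind"] == kind]
        counts = df.groupby("tetrad").size()
        return counts


def events_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Build a normalized event DataFrame from row dicts."""
    rows = list(rows)
    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    df = pd.DataFrame(rows)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[EVENT_COLUMNS + [c for c in df.columns if c not in EVENT_COLUMNS]]
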