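"""Genome layout, genomic intervals and masks.

All coordinates are 0-based, half-open ``[start, end)`` internally.  1-based
inclusive coordinates appear only at TSV boundaries (see :mod:`sporemap.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Chromosome:
    """A chromosome with an optional centromere position (bp)."""

    name: str
    length: int
    centromere: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")
        if self.centromere is not None and not (0 <= self.centromere <= self.length):
            raise ValueError(
                f"chromosome {self.name!r}: centromere {self.centromere} outside "
                f"[0, {self.length}]"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome set defining the coordinate space of an analysis."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @classmethod
    def from_lengths(
        cls,
        lengths: dict[str, int],
        centromeres: dict[str, int] | None = None,
    ) -> "GenomeLayout":
        cen = centromeres or {}
        return cls(
            tuple(Chromosome(n, l, cen.get(n)) for n, l in lengths.items())
        )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def subset(self, names: Iterable[str]) -> "GenomeLayout":
        keep = set(names)
        return GenomeLayout(tuple(c for c in self.chromosomes if c.name in keep))


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent half-open intervals, sorted by (chrom, start)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end < start:
            raise ValueError(f"interval end < start: {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        cur_s, cur_e = None, None
        for s, e in sorted(by_chrom[chrom]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return merged


@dataclass
class MaskSet:
    """Excluded genomic territory: merged intervals plus whole-chromosome drops.

    ``analyzed_length(layout)`` is the genome length remaining after masking;
    for the hybrid studied here roughly 5.7 Mb of the 10.2 Mb genome remains
    once the two aneuploid chromosomes, LOH tracts and translocation
    breakpoints are removed.
    """

    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    excluded_chromosomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def add(self, chrom: str, start: int, end: int) -> None:
        self.intervals = merge_intervals(self.intervals + [(chrom, start, end)])

    def masked_length(self, layout: GenomeLayout) -> int:
        total = 0
        for name in self.excluded_chromosomes:
            total += layout[name].length
        for chrom, start, end in self.intervals:
            if chrom in self.excluded_chromosomes:
                continue  # counted once via the whole-chromosome drop
            if chrom not in layout:
                raise ValueError(f"mask interval on unknown chromosome {chrom!r}")
            if start < 0 or end > layout[chrom].length:
                raise ValueError(
                    f"mask interval {chrom}:{start}-{end} outside chromosome bounds"
                )
            total += end - start
        return total

    def analyzed_length(self, layout: GenomeLayout) -> int:
        return layout.total_length - self.masked_length(layout)

    def is_masked(self, chrom: str, pos: int) -> bool:
        if chrom in self.excluded_chromosomes:
            return True
        for c, s, e in self.intervals:
            if c == chrom and s <= pos < e:
                return True
        return False

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom in self.excluded_chromosomes:
            return True
        for c, s, e in self.intervals:
            if c == chrom and start < e and s < end:
                return True
        return False

    def masked_fraction(self, chrom: str, start: int, end: int) -> float:
        """Fraction of ``[start, end)`` covered by the mask."""
        if chrom in self.excluded_chromosomes:
            return 1.0
        if end <= start:
            return 0.0
        covered = 0
        for c, s, e in self.intervals:
            if c == chrom:
                covered += max(0, min(e, end) - max(s, start))
        return covered / (end - start)


# Default layouts.  The reference genome spans ~10.2 Mb over eight chromosomes
# (A-H); chromosome A is 1.12 Mb.  The remaining lengths are approximate
# placeholders that preserve the printed totals: chromosomes B and D together
# ~2.35 Mb (the aneuploid pair excluded from recombination analysis), the six
# euploid chromosomes ~7.85 Mb.
WALTII_CHROMOSOME_LENGTHS: dict[str, int] = {
    "A": 1_120_000,
    "B": 1_300_000,
    "C": 1_250_000,
    "D": 1_050_000,
    "E": 1_420_000,
    "F": 1_620_000,
    "G": 1_280_000,
    "H": 1_160_000,
}

ANEUPLOID_CHROMOSOMES: tuple[str, ...] = ("B", "D")

# The analyzed (post-masking) territory totals 5.7 Mb over the six euploid
# chromosomes.  Lengths are the euploid chromosomes scaled to that total and
# rounded to 20 kb so that both the 5 kb and 20 kb window tilings are exact.
ANALYZED_CHROMOSOME_LENGTHS: dict[str, int] = {
    "A": 820_000,
    "C": 900_000,
    "E": 1_040_000,
    "F": 1_180_000,
    "G": 920_000,
    "H": 840_000,
}


def waltii_layout() -> GenomeLayout:
    """Full eight-chromosome layout (~10.2 Mb)."""
    return GenomeLayout.from_lengths(WALTII_CHROMOSOME_LENGTHS)


def analyzed_layout() -> GenomeLayout:
    """Six-chromosome layout of the analyzed territory (5.7 Mb total)."""
    return GenomeLayout.from_lengths(ANALYZED_CHROMOSOME_LENGTHS)
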