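"""Per-marker segregation classes, LOH/aneuploidy detection and mask building.

In a hybrid diploid every genuine heterozygous marker should segregate 2:2
among the four spores of a tetrad.  Markers inside loss-of-heterozygosity
(LOH) tracts of the parental hybrid segregate 4:0/0:4 in every tetrad;
chromosomes carried in extra copies (aneuploidy) deviate from 2:2 with a
complex, chromosome-wide pattern.  Both signals must be masked before
recombination events are called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MarkerMap, TetradSet
from .genome import GenomeLayout, MaskSet, merge_intervals

CLASSES = ("2:2", "3:1", "1:3", "4:0", "0:4", "incomplete")


def _classify_matrix(g: np.ndarray) -> np.ndarray:
    """Class index per (tetrad, marker) from a (n_tetrads, 4, n_markers) array.

    Indices follow :data:`CLASSES`.  Any missing spore makes the tetrad's
    call at that marker ``incomplete``.
    """
    n1 = (g == 1).sum(axis=1)
    n2 = (g == 2).sum(axis=1)
    complete = (n1 + n2) == 4
    out = np.full(n1.shape, 5, dtype=np.int8)  # incomplete
    out[complete & (n1 == 2)] = 0
    out[complete & (n1 == 3)] = 1
    out[complete & (n1 == 1)] = 2
    out[complete & (n1 == 4)] = 3
    out[complete & (n1 == 0)] = 4
    return out


@dataclass
class SegregationTable:
    """Per-marker segregation classes.

    ``per_tetrad[chrom]`` holds the class index per (tetrad, marker);
    ``modal[chrom]`` the modal class per marker across tetrads (ignoring
    ``incomplete`` calls when any complete call exists).
    """

    markers: MarkerMap
    per_tetrad: dict[str, np.ndarray]
    modal: dict[str, np.ndarray]

    def class_fractions(self, chrom: str) -> pd.Series:
        """Fractions of each class among all (tetrad, marker) calls."""
        counts = np.bincount(self.per_tetrad[chrom].ravel(), minlength=6)
        total = counts.sum()
        return pd.Series(counts / total if total else counts, index=CLASSES)

    def genome_class_fractions(self) -> pd.Series:
        counts = np.zeros(6, dtype=np.int64)
        for arr in self.per_tetrad.values():
            counts += np.bincount(arr.ravel(), minlength=6)
        total = counts.sum()
        return pd.Series(counts / total if total else counts, index=CLASSES)

    def summary_frame(self) -> pd.DataFrame:
        rows = {c: self.class_fractions(c) for c in self.per_tetrad}
        return pd.DataFrame(rows).T.rename_axis("chrom")


def classify_segregation(tetrads: TetradSet) -> SegregationTable:
    """Classify every marker's segregation in every tetrad.

    The modal class per marker summarizes the across-tetrad behavior: a
    marker inside a parental LOH tract is modal 4:0 or 0:4, a genuine
    heterozygous marker is modal 2:2.
    """
    if tetrads.n_tetrads < 1:
        raise ValueError("need at least one tetrad")
    per_tetrad: dict[str, np.ndarray] = {}
    modal: dict[str, np.ndarray] = {}
    for chrom, g in tetrads.genotypes.items():
        cls = _classify_matrix(g)
        per_tetrad[chrom] = cls
        n_m = cls.shape[1]
        mode = np.empty(n_m, dtype=np.int8)
        for m in range(n_m):
            counts = np.bincount(cls[:, m], minlength=6)
            informative = counts[:5]
            mode[m] = int(np.argmax(informative)) if informative.sum() else 5
        modal[chrom] = mode
    return SegregationTable(tetrads.markers, per_tetrad, modal)


def detect_loh_regions(
    seg: SegregationTable,
    window: int = 50_000,
    max_het_fraction: float = 0.05,
) -> list[tuple[str, int, int]]:
    """LOH intervals from the density of heterozygously-behaving markers.

    A marker "behaves heterozygously" when its modal class across tetrads is
    not 4:0/0:4.  Windows (default 50 kb) in which the fraction of such
    markers is at most ``max_het_fraction`` are merged into maximal runs and
    clipped to the outermost homozygous markers they contain.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    intervals: list[tuple[str, int, int]] = []
    for chrom, mode in seg.modal.items():
        pos = seg.markers[chrom]
        if len(pos) == 0:
            continue
        length = int(pos[-1]) + 1
        het = ~np.isin(mode, (3, 4))
        n_win = max(1, -(-length // window))
        flag = np.zeros(n_win, dtype=bool)
        idx = np.minimum(pos // window, n_win - 1)
        for w in range(n_win):
            sel = idx == w
            n = int(sel.sum())
            if n == 0:
                continue
            if het[sel].sum() / n <= max_het_fraction:
                flag[w] = True
        # merge runs of flagged windows, clip to outermost non-het markers
        w = 0
        while w < n_win:
            if not flag[w]:
                w += 1
                continue
            w2 = w
            while w2 + 1 < n_win and flag[w2 + 1]:
                w2 += 1
            in_run = (idx >= w) & (idx <= w2) & ~het
            if in_run.any():
                lo = int(pos[in_run][0])
                hi = int(pos[in_run][-1]) + 1
                intervals.append((chrom, lo, hi))
            w = w2 + 1
    return merge_intervals(intervals)


def detect_aneuploidy(
    seg: SegregationTable,
    complex_fraction_threshold: float = 0.20,
) -> list[str]:
    """Chromosomes whose segregation deviates from 2:2 chromosome-wide.

    The fraction of markers with a complex modal class (3:1/1:3, i.e.
    neither clean 2:2 nor the contiguous 4:0/0:4 of an LOH tract) is
    computed per chromosome; chromosomes above the threshold are flagged for
    exclusion.  A trisomy perturbs most markers along the chromosome whereas
    LOH perturbs contiguous blocks toward 4:0/0:4 only, so LOH-only
    deviation is not flagged.
    """
    flagged = []
    for chrom, mode in seg.modal.items():
        if len(mode) == 0:
            continue
        complex_frac = np.isin(mode, (1, 2)).mean()
        # also catch per-tetrad scatter: markers that are modal 2:2 but
        # frequently non-2:2 across tetrads
        cls = seg.per_tetrad[chrom]
        informative = cls < 5
        non22 = np.isin(cls, (1, 2))
        scatter = non22.sum() / max(informative.sum(), 1)
        if max(complex_frac, scatter) > complex_fraction_threshold:
            flagged.append(chrom)
    return flagged


def check_tetrad_consistency(
    tetrads: TetradSet,
    min_consistent_fraction: float = 0.95,
) -> list[str]:
    """Tetrads containing a spore incompatible with its three siblings.

    For every spore, the fraction of fully-genotyped markers at which adding
    the spore to its three siblings yields 2:2 segregation is computed
    genome-wide; a tetrad is suspect when any spore falls below the
    threshold.  Suspects are reported, not removed.
    """
    suspects: list[str] = []
    for t_idx, tname in enumerate(tetrads.tetrad_names):
        worst = 1.0
        n_total = 0
        consistent = np.zeros(4, dtype=np.int64)
        informative = np.zeros(4, dtype=np.int64)
        for chrom, g in tetrads.genotypes.items():
            gt = g[t_idx]
            complete = (gt != 0).all(axis=0)
            if not complete.any():
                continue
            gc = gt[:, complete]
            n1 = (gc == 1).sum(axis=0)
            for s in range(4):
                others1 = n1 - (gc[s] == 1)
                # spore s is consistent where the 4-spore pattern is 2:2
                ok = n1 == 2
                # informative: the three siblings leave a determined complement
                det = (others1 == 1) | (others1 == 2)
                informative[s] += int(det.sum())
                consistent[s] += int((ok & det).sum())
            n_total += int(complete.sum())
        if n_total == 0:
            suspects.append(tname)
            continue
        with np.errstate(invalid="ignore"):
            frac = np.where(informative > 0, consistent / np.maximum(informative, 1), 0.0)
        worst = float(frac.min())
        if worst < min_consistent_fraction:
            suspects.append(tname)
    return suspects


def build_mask(
    layout: GenomeLayout,
    loh_intervals: list[tuple[str, int, int]] | None = None,
    aneuploid_chromosomes: set[str] | list[str] | None = None,
    extra_intervals: list[tuple[str, int, int]] | None = None,
) -> MaskSet:
    """Combine LOH tracts, excluded chromosomes and extra intervals.

    Intervals are merged; ``analyzed_length`` of the result equals the total
    layout length minus the masked territory (counted once).
    """
    intervals = list(loh_intervals or []) + list(extra_intervals or [])
    for chrom, start, end in intervals:
        if chrom not in layout:
            raise ValueError(f"mask interval on unknown chromosome {chrom!r}")
        if start < 0 or end > layout[chrom].length:
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
    return MaskSet(
        intervals=intervals,
        excluded_chromosomes=set(aneuploid_chromosomes or ()),
    )
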