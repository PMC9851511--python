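"""Windowed crossover density, hotspot/coldspot permutation calling and
chromosome-scale recombination statistics.

Hotspots and coldspots are windows with significantly more / fewer
crossovers than an equal-probability permutation null: the observed events
are re-placed uniformly over the scan windows many times, the per-simulation
maximum (or minimum) window count is recorded, and the threshold is the
``ceil(fdr * n_perm)``-th most extreme of those extrema.  Significance is
strict (count > hotspot threshold, count < coldspot threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EventCatalog
from .genome import GenomeLayout, MaskSet


@dataclass
class WindowTrack:
    """Tiled windows with per-window CO counts and masked fractions.

    ``df`` columns: chrom, start, end, count, masked_fraction, in_scan.
    Windows tile each chromosome from 0 without overlap; the trailing
    partial window is kept.  Windows with masked fraction > 0.5 are flagged
    out of the scan set (``in_scan=False``) but still counted.
    """

    window: int
    df: pd.DataFrame

    @property
    def n_scan_windows(self) -> int:
        return int(self.df["in_scan"].sum())

    @property
    def total_count(self) -> int:
        return int(self.df["count"].sum())


@dataclass
class SpotCall:
    kind: str               # "hotspot" | "coldspot"
    chrom: str
    start: int
    end: int
    peak: int
    mean_count: float
    threshold: int
    n_windows: int


def window_counts(
    catalog: EventCatalog,
    layout: GenomeLayout,
    window: int,
    mask: MaskSet | None = None,
) -> WindowTrack:
    """Count crossovers per tiling window (assignment by CO midpoint)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    co = catalog.crossovers
    rows = []
    for chrom in layout.chromosomes:
        if mask is not None and chrom.name in mask.excluded_chromosomes:
            continue
        n_win = max(1, -(-chrom.length // window))
        counts = np.zeros(n_win, dtype=np.int64)
        sub = co[co["chrom"] == chrom.name]
        if len(sub):
            idx = np.minimum(
                sub["pos"].to_numpy(dtype=np.int64) // window, n_win - 1
            )
            np.add.at(counts, idx, 1)
        for w in range(n_win):
            start = w * window
            end = min((w + 1) * window, chrom.length)
            mf = mask.masked_fraction(chrom.name, start, start + window) if mask else 0.0
            rows.append(dict(
                chrom=chrom.name, start=start, end=end,
                count=int(counts[w]), masked_fraction=mf,
                in_scan=mf <= 0.5,
            ))
    return WindowTrack(window, pd.DataFrame(rows))


def permutation_threshold(
    n_events: int,
    n_windows: int,
    n_perm: int = 100_000,
    fdr: float = 0.02,
    tail: str = "max",
    seed: int | np.random.Generator = 0,
    chunk: int = 2_000,
) -> int:
    """Permutation significance threshold for windowed event counts.

    Places ``n_events`` into ``n_windows`` equal-probability windows
    (multinomial) ``n_perm`` times; returns the ``ceil(fdr * n_perm)``-th
    highest per-simulation maximum (``tail="max"``) or lowest minimum
    (``tail="min"``).  Significance against the returned threshold is
    strict: hotspot windows exceed it, coldspot windows fall below it.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if n_perm * fdr < 1:
        raise ValueError("n_perm * fdr must be >= 1")
    if tail not in ("max", "min"):
        raise ValueError("tail must be 'max' or 'min'")
    if n_events == 0:
        return 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.full(n_windows, 1.0 / n_windows)
    extrema = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        draws = rng.multinomial(n_events, p, size=m)
        extrema[done:done + m] = draws.max(axis=1) if tail == "max" else draws.min(axis=1)
        done += m
    k = math.ceil(fdr * n_perm)
    extrema.sort()
    if tail == "max":
        return int(extrema[n_perm - k])   # k-th highest
    return int(extrema[k - 1])            # k-th lowest


def call_spots(
    track: WindowTrack,
    hot_threshold: int,
    cold_threshold: int,
) -> list[SpotCall]:
    """Merge maximal runs of adjacent significant windows into spot calls.

    Adjacency requires contiguous coordinates within one chromosome; scan
    windows separated by excluded (heavily masked) windows do not merge.
    """
    spots: list[SpotCall] = []
    scan = track.df[track.df["in_scan"]]
    for kind, check in (
        ("hotspot", lambda c: c > hot_threshold),
        ("coldspot", lambda c: c < cold_threshold),
    ):
        for chrom, grp in scan.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            run: list[pd.Series] = []
            prev_end = None
            for _, w in grp.iterrows():
                significant = check(w["count"])
                contiguous = prev_end is not None and w["start"] == prev_end
                if significant and run and contiguous:
                    run.append(w)
                elif significant:
                    if run:
                        spots.append(_spot_from_run(kind, run, hot_threshold, cold_threshold))
                    run = [w]
                else:
                    if run:
                        spots.append(_spot_from_run(kind, run, hot_threshold, cold_threshold))
                    run = []
                prev_end = w["end"] if significant else None
            if run:
                spots.append(_spot_from_run(kind, run, hot_threshold, cold_threshold))
    spots.sort(key=lambda s: (s.chrom, s.start))
    return spots


def _spot_from_run(kind, run, hot_threshold, cold_threshold) -> SpotCall:
    counts = [int(w["count"]) for w in run]
    return SpotCall(
        kind=kind, chrom=run[0]["chrom"],
        start=int(run[0]["start"]), end=int(run[-1]["end"]),
        peak=max(counts) if kind == "hotspot" else min(counts),
        mean_count=float(np.mean(counts)),
        threshold=hot_threshold if kind == "hotspot" else cold_threshold,
        n_windows=len(run),
    )


def e0_statistics(
    catalog: EventCatalog,
    chromosomes: list[str],
    n_tetrads: int | None = None,
) -> dict:
    """Non-exchange (E0) chromosome statistics.

    A chromosome is E0 in a meiosis when that meiosis shows zero called
    crossovers on it.  Returns the per-chromosome E0 fraction and the
    fractions of meioses with at least one / at least two E0 chromosomes.
    """
    n_tetrads = n_tetrads or int(catalog.provenance.get("n_tetrads") or
                                 catalog.df["tetrad"].nunique())
    co = catalog.crossovers
    tetrads = sorted(set(co["tetrad"])) if len(co) else []
    if n_tetrads > len(tetrads):
        tetrads = tetrads + [f"__absent{i}" for i in range(n_tetrads - len(tetrads))]
    counts = pd.DataFrame(0, index=tetrads, columns=chromosomes, dtype=int)
    for (tet, chrom), grp in co.groupby(["tetrad", "chrom"]):
        if chrom in counts.columns and tet in counts.index:
            counts.loc[tet, chrom] = len(grp)
    e0 = counts == 0
    per_chrom = e0.mean(axis=0)
    n_e0 = e0.sum(axis=1)
    return dict(
        per_chromosome=per_chrom.to_dict(),
        frac_ge1=float((n_e0 >= 1).mean()),
        frac_ge2=float((n_e0 >= 2).mean()),
        n_tetrads=len(tetrads),
    )


def event_rates(
    catalog: EventCatalog,
    analyzed_length: int,
    n_meioses: int,
    genome_total: int | None = None,
) -> dict:
    """Per-Mb event rates and genome-wide extrapolation.

    Both mean- and median-based per-meiosis rates are reported: rate =
    per-meiosis event count / analyzed Mb; the extrapolation multiplies the
    rate by the total genome size in Mb.
    """
    if analyzed_length <= 0:
        raise ValueError("analyzed_length must be > 0")
    mb = analyzed_length / 1e6
    out: dict = dict(analyzed_mb=mb, n_meioses=n_meioses)
    # pooled density over all meioses (events per Mb of analyzed genome)
    out["co_density"] = len(catalog.crossovers) / mb
    out["nco_density"] = len(catalog.noncrossovers) / mb
    for kind, label in (("CO", "co"), ("NCO", "nco")):
        sub = catalog.df[catalog.df["kind"] == kind]
        counts = sub.groupby("tetrad").size().reindex(
            sub["tetrad"].unique(), fill_value=0
        ).to_numpy() if len(sub) else np.array([0])
        if n_meioses > len(counts):
            counts = np.concatenate([counts, np.zeros(n_meioses - len(counts), dtype=int)])
        mean_c = float(np.mean(counts))
        median_c = float(np.median(counts))
        out[f"{label}_per_meiosis_mean"] = mean_c
        out[f"{label}_per_meiosis_median"] = median_c
        out[f"{label}_rate_mean"] = mean_c / mb
        out[f"{label}_rate_median"] = median_c / mb
        if genome_total:
            out[f"{label}_genomewide_mean"] = mean_c / mb * genome_total / 1e6
            out[f"{label}_genomewide_median"] = median_c / mb * genome_total / 1e6
    return out


def chromosome_regression(
    co_means: dict[str, float],
    analyzed_sizes: dict[str, int],
    full_sizes: dict[str, int] | None = None,
    co_rate_per_mb: float | None = None,
) -> dict:
    """Least-squares regression of per-chromosome CO frequency on size.

    Returns the observed ordinary-least-squares intercept/slope on
    (analyzed size, mean CO count) and, when full sizes are given, a
    size-corrected variant extending each chromosome's count to its full
    length.  Also reports the correlation of the recombination rate (cM/kb,
    using 50 cM per CO per meiosis) with chromosome size.
    """
    chroms = sorted(co_means)
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes for a regression")
    x = np.array([analyzed_sizes[c] for c in chroms], dtype=float)
    y = np.array([co_means[c] for c in chroms], dtype=float)
    obs = stats.linregress(x, y)
    out = dict(
        observed=dict(intercept=float(obs.intercept), slope=float(obs.slope),
                      r=float(obs.rvalue)),
    )
    if full_sizes:
        xf = np.array([full_sizes[c] for c in chroms], dtype=float)
        yc = y * xf / x
        cor = stats.linregress(xf, yc)
        out["corrected"] = dict(intercept=float(cor.intercept),
                                slope=float(cor.slope), r=float(cor.rvalue))
        # recombination rate in cM/kb vs size (map length = 50 cM per CO)
        rate = 50.0 * yc / (xf / 1e3)
        rr = stats.pearsonr(xf, rate)
        out["rate_vs_size"] = dict(r=float(rr.statistic), p=float(rr.pvalue))
    return out


def tract_statistics(catalog: EventCatalog) -> dict:
    """Median conversion-tract lengths (kb) for GCco and NCO tracts.

    Reports both medians, the full length arrays, and a two-sided
    Mann-Whitney U comparison between the crossover-associated and
    noncrossover tract-length distributions.
    """
    df = catalog.df
    has_tract = df["tract_len"].notna()
    gcco = df[(df["kind"] == "CO") & has_tract]["tract_len"].to_numpy(dtype=float)
    nco = df[(df["kind"] == "NCO") & has_tract]["tract_len"].to_numpy(dtype=float)
    out: dict = dict(
        gcco_n=len(gcco), nco_n=len(nco),
        gcco_median_kb=float(np.median(gcco)) / 1e3 if len(gcco) else float("nan"),
        nco_median_kb=float(np.median(nco)) / 1e3 if len(nco) else float("nan"),
        gcco_lengths=gcco, nco_lengths=nco,
    )
    if len(gcco) and len(nco):
        mw = stats.mannwhitneyu(gcco, nco, alternative="two-sided")
        out["mannwhitney_u"] = float(mw.statistic)
        out["mannwhitney_p"] = float(mw.pvalue)
    return out
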