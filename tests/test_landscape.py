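import numpy as np
import pandas as pd
import pytest

import sporemap as sm
from sporemap.core import EventCatalog, events_frame


def _catalog_from_positions(pos_by_chrom, n_tetrads=1, kind="CO"):
    rows = []
    for chrom, positions in pos_by_chrom.items():
        for k, p in enumerate(positions):
            rows.append(dict(
                tetrad=f"T{(k % n_tetrads) + 1:03d}", chrom=chrom, kind=kind,
                cls="a" if kind == "CO" else "j", start=int(p) - 500,
                end=int(p) + 500, pos=int(p), chromatids="2+3",
                tract_start=np.nan, tract_end=np.nan, tract_len=np.nan,
                n_markers=1,
            ))
    return EventCatalog(events_frame(rows), dict(n_tetrads=n_tetrads))


def test_window_assignment_and_count_conservation():
    layout = sm.GenomeLayout.from_lengths({"A": 23_000})
    catalog = _catalog_from_positions({"A": [7_400, 7_500, 21_000]})
    track = sm.window_counts(catalog, layout, 5_000)
    df = track.df
    assert list(df["start"]) == [0, 5_000, 10_000, 15_000, 20_000]
    assert df.loc[df["start"] == 5_000, "count"].item() == 2
    assert df["end"].iloc[-1] == 23_000        # trailing partial kept
    assert track.total_count == 3              # conservation


def test_heavily_masked_windows_leave_scan_set():
    layout = sm.GenomeLayout.from_lengths({"A": 20_000, "B": 20_000})
    mask = sm.MaskSet(intervals=[("A", 0, 14_000)])
    catalog = _catalog_from_positions({"A": [1_000], "B": [1_000]})
    track = sm.window_counts(catalog, layout, 5_000, mask)
    a = track.df[track.df["chrom"] == "A"]
    assert list(a["in_scan"]) == [False, False, False, True]
    assert track.total_count == 2              # masked windows still counted
    full = sm.MaskSet(excluded_chromosomes={"A"})
    t2 = sm.window_counts(catalog, layout, 5_000, full)
    assert not (t2.df["chrom"] == "A").any()


def test_permutation_threshold_against_exact_enumeration():
    """4 events in 2 equal windows: the max of the placement is 4 with
    probability 2/16 and >=3 with probability 10/16 (exact enumeration of
    the 2^4 assignments), fixing the expected order statistics."""
    hot_strict = sm.permutation_threshold(4, 2, n_perm=40_000, fdr=0.02, seed=9)
    assert hot_strict == 4                     # P(max=4)=0.125 > 0.02
    hot_median = sm.permutation_threshold(4, 2, n_perm=40_000, fdr=0.5, seed=9)
    assert hot_median == 3                     # P(max>=3)=0.625 >= 0.5
    lo = sm.permutation_threshold(4, 2, n_perm=40_000, fdr=0.5, tail="min", seed=9)
    assert lo == 1                             # P(min<=0)=0.125, P(min<=1)=0.625


def test_permutation_threshold_edges():
    assert sm.permutation_threshold(0, 10) == 0
    with pytest.raises(ValueError):
        sm.permutation_threshold(10, 1)
    with pytest.raises(ValueError):
        sm.permutation_threshold(10, 5, n_perm=10, fdr=0.01)
    with pytest.raises(ValueError):
        sm.permutation_threshold(10, 5, tail="sideways")


def test_permutation_threshold_monotonicity():
    """Hotspot threshold grows with event count, shrinks with window count."""
    rng_seed = 3
    t_events = [
        sm.permutation_threshold(n, 100, n_perm=20_000, fdr=0.05, seed=rng_seed)
        for n in (300, 1_000, 3_000)
    ]
    assert t_events == sorted(t_events)
    t_windows = [
        sm.permutation_threshold(1_000, w, n_perm=20_000, fdr=0.05, seed=rng_seed)
        for w in (50, 100, 400)
    ]
    assert t_windows == sorted(t_windows, reverse=True)


def test_hotspot_null_calibration():
    """Uniformly placed events exceed the threshold in ~fdr of scans."""
    layout = sm.GenomeLayout.from_lengths({"A": 500_000})
    fdr = 0.05
    n_windows = 100
    thr = sm.permutation_threshold(400, n_windows, n_perm=20_000, fdr=fdr, seed=0)
    rng = np.random.default_rng(42)
    exceed = 0
    reps = 60
    for _ in range(reps):
        pos = rng.uniform(0, 500_000, size=400)
        catalog = _catalog_from_positions({"A": pos})
        track = sm.window_counts(catalog, layout, 5_000)
        if track.df["count"].max() > thr:
            exceed += 1
    # binomial(60, 0.05): central 99.9% within [0, 10]
    assert exceed <= 10


def test_call_spots_merging_rules():
    layout = sm.GenomeLayout.from_lengths({"A": 40_000})
    counts = [1, 14, 15, 2, 0, 2, 14, 2]
    pos = []
    for w, c in enumerate(counts):
        pos += [w * 5_000 + 2_500] * c
    track = sm.window_counts(_catalog_from_positions({"A": pos}), layout, 5_000)
    spots = sm.call_spots(track, hot_threshold=13, cold_threshold=1)
    hot = [s for s in spots if s.kind == "hotspot"]
    assert len(hot) == 2                       # adjacent pair merged, lone kept
    assert (hot[0].start, hot[0].end) == (5_000, 15_000)
    assert hot[0].peak == 15 and hot[0].n_windows == 2
    cold = [s for s in spots if s.kind == "coldspot"]
    assert len(cold) == 1 and cold[0].start == 20_000


def test_e0_statistics_degenerate_and_poisson():
    one = _catalog_from_positions({"A": []}, n_tetrads=1)
    stats = sm.e0_statistics(one, ["A"], n_tetrads=1)
    assert stats["per_chromosome"]["A"] == 1.0 and stats["frac_ge1"] == 1.0

    rng = np.random.default_rng(11)
    lam = 3.8
    n = 10_000
    rows = []
    counts = rng.poisson(lam, size=n)
    for t, c in enumerate(counts):
        for k in range(c):
            rows.append(dict(tetrad=f"T{t:05d}", chrom="A", kind="CO", cls="a",
                             start=k * 1000, end=k * 1000 + 1, pos=k * 1000,
                             chromatids="2+3", tract_start=np.nan,
                             tract_end=np.nan, tract_len=np.nan, n_markers=1))
    catalog = EventCatalog(events_frame(rows), dict(n_tetrads=n))
    stats = sm.e0_statistics(catalog, ["A"], n_tetrads=n)
    expected = np.exp(-lam)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(stats["per_chromosome"]["A"] - expected) < 3 * se


def test_event_rates_arithmetic():
    rows = []
    for t in range(4):
        for k in range(21):
            rows.append(dict(tetrad=f"T{t}", chrom="A", kind="CO", cls="a",
                             start=k, end=k + 1, pos=k, chromatids="2+3",
                             tract_start=np.nan, tract_end=np.nan,
                             tract_len=np.nan, n_markers=1))
    catalog = EventCatalog(events_frame(rows), dict(n_tetrads=4))
    rates = sm.event_rates(catalog, 5_700_000, 4, genome_total=10_200_000)
    assert rates["co_rate_mean"] == pytest.approx(21 / 5.7)
    assert rates["co_rate_mean"] == pytest.approx(3.68, abs=0.01)
    assert rates["co_genomewide_mean"] == pytest.approx(21 / 5.7 * 10.2)
    # a 3.4/Mb rate extrapolates to ~34.7 genome wide
    assert 3.4 * 10.2 == pytest.approx(34.7, abs=0.05)
    empty = sm.event_rates(EventCatalog.empty(dict(n_tetrads=4)), 5_700_000, 4)
    assert empty["co_rate_mean"] == 0.0


def test_chromosome_regression_exact_and_against_ols_oracle():
    sizes = {c: s for c, s in zip("ABCDEF", [4e5, 6e5, 8e5, 1e6, 1.2e6, 1.4e6])}
    means = {c: 1.0 + 2e-6 * s for c, s in sizes.items()}
    fit = sm.chromosome_regression(means, {c: int(s) for c, s in sizes.items()})
    assert fit["observed"]["intercept"] == pytest.approx(1.0, abs=1e-9)
    assert fit["observed"]["slope"] == pytest.approx(2e-6, abs=1e-12)

    rng = np.random.default_rng(5)
    noisy = {c: float(v + rng.normal(0, 0.3)) for c, v in means.items()}
    fit = sm.chromosome_regression(noisy, {c: int(s) for c, s in sizes.items()})
    x = np.array([sizes[c] for c in sorted(sizes)])
    y = np.array([noisy[c] for c in sorted(sizes)])
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)   # closed-form normal equations
    assert fit["observed"]["intercept"] == pytest.approx(beta[0], abs=1e-10)
    assert fit["observed"]["slope"] == pytest.approx(beta[1], abs=1e-10)

    with pytest.raises(ValueError):
        sm.chromosome_regression({"A": 1.0, "B": 2.0}, {"A": 1, "B": 2})


def test_tract_statistics_medians_and_ranksum():
    rows = []
    for i, ln in enumerate([1_000.0, 2_000.0, 3_000.0]):
        rows.append(dict(tetrad="T1", chrom="A", kind="CO", cls="b",
                         start=i, end=i + 1, pos=i, chromatids="2+3",
                         tract_start=0.0, tract_end=ln, tract_len=ln,
                         n_markers=2))
    for i, ln in enumerate([1_000.0, 2_000.0, 3_000.0]):
        rows.append(dict(tetrad="T1", chrom="B", kind="NCO", cls="j",
                         start=i, end=i + 1, pos=i, chromatids="1",
                         tract_start=0.0, tract_end=ln, tract_len=ln,
                         n_markers=2))
    catalog = EventCatalog(events_frame(rows), dict(n_tetrads=1))
    stats = sm.tract_statistics(catalog)
    assert stats["gcco_median_kb"] == 2.0
    assert stats["nco_median_kb"] == 2.0
    # identical distributions are not called different
    assert stats["mannwhitney_p"] > 0.5
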