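import numpy as np
import pandas as pd
import pytest

import sporemap as sm
from sporemap.core import MarkerMap, TetradSet
from sporemap.events import CallerParams

from conftest import tetrad_from_matrix
from oracles import genotype_from_events, minimal_event_count


def _call_one(positions, genotypes, **caller_kw):
    tetrads = tetrad_from_matrix(positions, genotypes)
    params = CallerParams(**dict(dict(min_tract_markers=1), **caller_kw))
    return sm.call_events(tetrads, params=params)


def test_canonical_crossover_class_a():
    """Phase (1,1,2,2) -> (1,2,1,2) at one point: class-a CO on spores 2,3."""
    positions = np.arange(1, 11) * 1000
    g = np.tile([[1], [1], [2], [2]], (1, 10)).astype(np.int8)
    g[1, 5:] = 2
    g[2, 5:] = 1
    catalog = _call_one(positions, g)
    assert len(catalog) == 1
    row = catalog.df.iloc[0]
    assert row["kind"] == "CO" and row["cls"] == "a"
    assert row["chromatids"] == "2+3"
    assert row["start"] == 5000 and row["end"] == 6000
    assert row["pos"] == 5500


def test_canonical_nco_class_j():
    """Interior 3:1 run on one spore, flanking phase unchanged: class j."""
    positions = np.arange(1, 13) * 1000
    g = np.tile([[1], [1], [2], [2]], (1, 12)).astype(np.int8)
    g[0, 4:7] = 2
    catalog = _call_one(positions, g)
    assert len(catalog) == 1
    row = catalog.df.iloc[0]
    assert row["kind"] == "NCO" and row["cls"] == "j"
    assert row["chromatids"] == "1"
    assert row["tract_start"] == 5000 and row["tract_end"] == 7001


def test_crossover_with_conversion_tract_class_b():
    """Offset reciprocal switches: 3:1 heteroduplex region between them."""
    positions = np.arange(1, 16) * 1000
    g = np.tile([[1], [1], [2], [2]], (1, 15)).astype(np.int8)
    g[1, 6:] = 2          # spore 2 switches at ~6-7 kb
    g[2, 9:] = 1          # spore 3 switches at ~9-10 kb
    catalog = _call_one(positions, g)
    assert len(catalog) == 1
    row = catalog.df.iloc[0]
    assert row["kind"] == "CO" and row["cls"] == "b"
    assert row["chromatids"] == "2+3"
    assert row["tract_start"] == 7000 and row["tract_end"] == 9001


def test_four_strand_double_crossover_gives_two_events():
    positions = np.arange(1, 11) * 1000
    g = np.tile([[1], [1], [2], [2]], (1, 10)).astype(np.int8)
    g[:, 5:] = 3 - g[:, 5:]       # all four spores switch at one point
    catalog = _call_one(positions, g)
    assert len(catalog) == 2
    assert set(catalog.df["kind"]) == {"CO"}
    pairs = set(catalog.df["chromatids"])
    assert pairs in ({"1+3", "2+4"}, {"1+4", "2+3"})


def test_double_crossover_class_g_needs_intervening_marker():
    positions = np.arange(1, 13) * 1000
    g = np.tile([[1], [1], [2], [2]], (1, 12)).astype(np.int8)
    g[1, 4:8] = 2                 # same non-sister pair out and back
    g[2, 4:8] = 1
    catalog = _call_one(positions, g)
    assert len(catalog) == 2      # a double CO contributes two crossovers
    assert set(catalog.df["cls"]) == {"g"}
    assert set(catalog.df["chromatids"]) == {"2+3"}


def test_measure_tract_conventions():
    """Deviating markers 10,000/11,500 with flanks 9,000/12,500."""
    event = dict(tract_start=10_000.0, tract_end=11_501.0,
                 start=9_000, end=12_500)
    assert sm.measure_tract(event, "minimal") == 1_500
    assert sm.measure_tract(event, "midpoint") == 2_500
    assert sm.measure_tract(event, "maximal") == 3_500
    with pytest.raises(ValueError):
        sm.measure_tract(event, "bogus")
    with pytest.raises(ValueError):
        sm.measure_tract(dict(event, tract_start=float("nan")), "minimal")


def test_single_marker_tract_has_floor():
    event = dict(tract_start=10_000.0, tract_end=10_001.0,
                 start=9_000, end=11_000)
    assert sm.measure_tract(event, "minimal") == 1.0


def test_missing_spore_never_nucleates_event():
    positions = np.arange(1, 13) * 1000
    g = np.tile([[1], [1], [2], [2]], (1, 12)).astype(np.int8)
    g[0, 4:8] = 0                 # missing stretch, no deviation
    catalog = _call_one(positions, g)
    assert len(catalog) == 0


def test_noise_free_recall_is_complete(clean_sim):
    """Every detectable true event is recovered near its true position."""
    tetrads, truth, _ = clean_sim
    catalog = sm.call_events(tetrads, params=CallerParams(min_tract_markers=1))
    cd = catalog.df
    for _, r in truth.detectable(tetrads.markers).iterrows():
        sub = cd[(cd.tetrad == r.tetrad) & (cd.chrom == r.chrom)]
        assert len(sub) and (np.abs(sub["pos"] - r.pos) < 10_000).any(), (
            f"missed {r.kind} at {r.tetrad}:{r.chrom}:{r.pos:.0f}"
        )


def test_recovered_positions_and_chromatids_for_first_cos(clean_sim):
    """The first crossover of each chromosome comes back at the right
    place on the right chromatid pair.

    Only the first exchange is compared by label: truth records original
    strand indices, while genotypes expose molecule (spore) identities,
    and every upstream crossover re-routes molecules across strands.
    """
    tetrads, truth, _ = clean_sim
    catalog = sm.call_events(tetrads, params=CallerParams(min_tract_markers=1))
    cd = catalog.df[catalog.df["kind"] == "CO"]
    td = truth.df
    checked = 0
    for (tet, chrom), grp in td[td.kind == "CO"].groupby(["tetrad", "chrom"]):
        grp = grp.sort_values("pos")
        r = grp.iloc[0]
        if len(grp) > 1 and grp.iloc[1]["pos"] - r["pos"] < 30_000:
            continue               # entangled with the next exchange
        lo = r.tract_start if np.isfinite(r.tract_start) else r.pos
        hi = r.tract_end if np.isfinite(r.tract_end) else r.pos
        sub = cd[(cd.tetrad == tet) & (cd.chrom == chrom)]
        hit = sub[(sub.pos > lo - 5_000) & (sub.pos < hi + 5_000)]
        if len(hit) != 1:
            continue
        assert hit.iloc[0]["chromatids"] == r.chromatids
        assert abs(hit.iloc[0]["pos"] - r.pos) < 5_000
        checked += 1
    assert checked > 80


def test_caller_matches_minimal_event_oracle():
    """On small instances the caller's event count is the brute-force
    minimum number of events explaining the genotypes."""
    rng = np.random.default_rng(77)
    positions = np.arange(1, 19) * 1000
    n_checked = 0
    for _ in range(40):
        k = rng.integers(0, 3)
        events = []
        for _ in range(k):
            if rng.random() < 0.6:
                i, j = [(0, 2), (0, 3), (1, 2), (1, 3)][rng.integers(4)]
                x = rng.uniform(2_500, 15_500)
                events.append(("CO", i, j, x, x))
            else:
                c = rng.integers(4)
                t0 = rng.uniform(2_500, 12_000)
                events.append(("NCO", int(c), t0, t0 + rng.uniform(1_500, 3_500)))
        g = genotype_from_events(positions, events)
        oracle = minimal_event_count(positions, g)
        if oracle is None:
            continue
        catalog = _call_one(positions, g, merge_window=1)
        assert len(catalog) == oracle, f"events={events}"
        n_checked += 1
    assert n_checked >= 30


def test_spore_order_invariance(clean_sim):
    tetrads, _, _ = clean_sim
    sub = TetradSet(
        tetrads.markers, tetrads.tetrad_names[:4],
        {c: g[:4] for c, g in tetrads.genotypes.items()},
    )
    perm = [2, 0, 3, 1]
    shuffled = TetradSet(
        sub.markers, sub.tetrad_names,
        {c: g[:, perm] for c, g in sub.genotypes.items()},
    )
    p = CallerParams(min_tract_markers=1)
    a = sm.call_events(sub, params=p).df
    b = sm.call_events(shuffled, params=p).df
    assert len(a) == len(b)
    assert a["kind"].value_counts().to_dict() == b["kind"].value_counts().to_dict()
    assert sorted(a["pos"]) == sorted(b["pos"])


def test_reduced_marker_density_never_adds_events(clean_sim):
    tetrads, _, _ = clean_sim
    full = sm.call_events(tetrads, params=CallerParams())
    thinned_markers = {c: p[::3] for c, p in tetrads.markers.positions.items()}
    thinned = TetradSet(
        MarkerMap(thinned_markers), tetrads.tetrad_names,
        {c: g[:, :, ::3] for c, g in tetrads.genotypes.items()},
    )
    sparse = sm.call_events(thinned, params=CallerParams())
    assert len(sparse) <= len(full)


def test_recurrent_double_crossover_filtering(small_layout):
    params = sm.SimParams(seed=31, missing_rate=0.0, error_rate=0.0)
    tetrads, _ = sm.simulate_tetrads(small_layout, params, 12)
    tetrads = sm.inject_artifacts(
        tetrads, recurrent_dco_loci=[("I", 250_000.0)],
        recurrence_fraction=1.0, rng=np.random.default_rng(1),
    )
    catalog = sm.call_events(tetrads, params=CallerParams(min_tract_markers=1))
    flagged, filtered = sm.flag_recurrent_double_crossovers(catalog)
    assert len(flagged) == 1
    assert flagged.iloc[0]["chrom"] == "I"
    assert abs(flagged.iloc[0]["pos"] - 250_000) < 10_000
    # injected everywhere; a coincident meiotic CO can obscure the
    # signature in a tetrad or two, but recurrence stays above threshold
    assert flagged.iloc[0]["fraction"] >= 0.8
    near = filtered.df[(filtered.df.chrom == "I") &
                       ((filtered.df.pos - 250_000).abs() < 5_000)]
    assert len(near) == 0


def test_single_double_crossover_is_retained():
    positions = np.arange(1, 13) * 1000
    g = np.tile([[1], [1], [2], [2]], (1, 12)).astype(np.int8)
    g[1, 4:8] = 2
    g[2, 4:8] = 1
    tetrads = tetrad_from_matrix(positions, g)
    catalog = sm.call_events(tetrads, params=CallerParams(min_tract_markers=1))
    flagged, filtered = sm.flag_recurrent_double_crossovers(catalog)
    # one tetrad of one cannot establish recurrence below the threshold
    assert len(filtered) == len(catalog)


def test_flag_recurrent_on_empty_catalog():
    from sporemap.core import EventCatalog
    flagged, filtered = sm.flag_recurrent_double_crossovers(EventCatalog.empty())
    assert len(flagged) == 0 and len(filtered) == 0


def test_summaries_single_event_and_gcco_fraction(clean_sim):
    positions = np.arange(1, 11) * 1000
    g = np.tile([[1], [1], [2], [2]], (1, 10)).astype(np.int8)
    g[1, 5:] = 2
    g[2, 5:] = 1
    one = sm.call_events(tetrad_from_matrix(positions, g),
                         params=CallerParams(min_tract_markers=1))
    s = sm.summarize_events(one)
    assert s["co_per_meiosis_median"] == 1 and s["gcco_fraction"] == 0.0

    tetrads, truth, params = clean_sim
    catalog = sm.call_events(tetrads, params=CallerParams(min_tract_markers=1))
    s = sm.summarize_events(catalog)
    # the configured tract-carrying probability, minus marker-resolution
    # loss for tracts spanning no marker (~3%), within sampling noise
    assert s["gcco_fraction"] == pytest.approx(params.gcco_prob, abs=0.06)


def test_phase_conservation_is_reported(clean_sim):
    tetrads, _, _ = clean_sim
    catalog = sm.call_events(tetrads, params=CallerParams(min_tract_markers=1))
    viol = catalog.provenance["phase_violations"]
    assert viol <= 0.001 * tetrads.markers.n_markers * tetrads.n_tetrads


def test_masked_events_are_dropped(clean_sim, analyzed_layout):
    tetrads, _, _ = clean_sim
    mask = sm.build_mask(analyzed_layout, [("A", 0, 820_000)])  # whole chr A
    catalog = sm.call_events(tetrads, mask=mask)
    assert not (catalog.df["chrom"] == "A").any()


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60)
@given(st.integers(0, 2_000), st.integers(1, 3_000), st.integers(1, 2_000),
       st.integers(1, 2_000))
def test_tract_conventions_are_ordered(f0, gap_l, dev, gap_r):
    """minimal <= midpoint <= maximal for any marker geometry."""
    d0 = f0 + gap_l
    d1 = d0 + dev
    f1 = d1 + gap_r
    event = dict(tract_start=float(d0), tract_end=float(d1) + 1.0,
                 start=f0, end=f1)
    minimal = sm.measure_tract(event, "minimal")
    midpoint = sm.measure_tract(event, "midpoint")
    maximal = sm.measure_tract(event, "maximal")
    assert minimal <= midpoint <= maximal
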