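"""Recombination event calling from four-spore genotypes.

A consistent tetrad is 2:2 at every heterozygous marker outside
recombination events.  A crossover (CO) exchanges the distal segments of two
non-sister chromatids and appears as a reciprocal switch of two spores'
genotype sequences; when the exchange carries a heteroduplex conversion
tract (GCco) the two reciprocal switch points are offset and the markers
between them segregate 3:1.  A noncrossover (NCO) is a conversion tract on a
single chromatid with unchanged flanking phase.  Events are classified into
the single-tetrad taxonomy of :data:`sporemap.core.EVENT_CLASSES`.

The caller works per (tetrad, chromosome):

1. each spore's genotype sequence is decomposed into *units*: net switches
   and sandwich runs (a run flanked by two runs of the same value = a
   candidate conversion tract);
2. units closer than ``merge_window`` are clustered into one event;
3. each cluster is classified by comparing the flanking 2:2 phases and the
   interior pattern, preferring the explanation with fewest chromatid
   exchanges;
4. events intersecting the mask are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EventCatalog, MarkerMap, TetradSet, events_frame
from .genome import MaskSet


@dataclass(frozen=True)
class CallerParams:
    """Event-caller knobs.

    merge_window
        Breakpoint clusters closer than this (bp) in one tetrad/chromosome
        are treated as a single event.
    min_tract_markers
        Minimum markers in a sandwich run for it to nucleate a conversion
        tract; single-marker tracts are indistinguishable from genotyping
        error, hence the default of 2.  Set to 1 for maximal sensitivity on
        noise-free data.
    max_tract_span
        Longest sandwich run (bp) still interpreted as one conversion
        tract; a longer same-spore excursion is two independent switches
        (e.g. two crossovers sharing a chromatid).  Also the reach of the
        reciprocal-switch pairing that reunites a crossover whose offset
        switch points fall into different breakpoint clusters.
    """

    merge_window: int = 5_000
    min_tract_markers: int = 2
    max_tract_span: int = 15_000


@dataclass
class _Unit:
    """A per-spore breakpoint unit (switch or candidate tract)."""

    spore: int              # 0-based
    kind: str               # "switch" | "tract"
    left_idx: int           # last marker index before the unit
    right_idx: int          # first marker index after the unit
    first_idx: int          # first deviating marker (tract) / == right (switch)
    last_idx: int           # last deviating marker (tract) / == left (switch)
    v_from: int
    v_to: int               # tract: the converted value


def _spore_units(
    obs_idx: np.ndarray,
    vals: np.ndarray,
    pos: np.ndarray,
    min_tract_markers: int,
    max_tract_span: float,
) -> list[_Unit]:
    """Decompose one spore's observed genotype sequence into units.

    Sandwich runs shorter than ``min_tract_markers`` are healed (treated as
    genotyping noise): they produce no unit and do not interrupt the
    background value.  Sandwich runs spanning more than ``max_tract_span``
    bp stay two independent switches.
    """
    if len(vals) == 0:
        return []
    # run-length encode
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(vals)]])
    runs = [(int(s), int(e), int(vals[s])) for s, e in zip(starts, ends)]

    # heal short sandwich runs (noise), repeatedly until stable
    healed = True
    while healed and len(runs) >= 3:
        healed = False
        for i in range(1, len(runs) - 1):
            s, e, v = runs[i]
            if (e - s) < min_tract_markers and runs[i - 1][2] == runs[i + 1][2]:
                runs = runs[: i - 1] + [(runs[i - 1][0], runs[i + 1][1], runs[i - 1][2])] + runs[i + 2:]
                healed = True
                break

    # candidate tracts: internal sandwich runs short enough to be a
    # conversion; a genotype sequence like 1,2,1,2 is ambiguous (tract then
    # switch vs switch then tract), so candidates are selected greedily by
    # increasing bp span — conversion tracts are short, exchanged crossover
    # segments long — as an independent (non-adjacent) set
    def span(i: int) -> float:
        s, e, _ = runs[i]
        return float(pos[obs_idx[e - 1]] - pos[obs_idx[s]])

    cands = [i for i in range(1, len(runs) - 1)
             if runs[i - 1][2] == runs[i + 1][2] and span(i) <= max_tract_span]
    selected: set[int] = set()
    for i in sorted(cands, key=span):
        if i - 1 not in selected and i + 1 not in selected:
            selected.add(i)

    units: list[_Unit] = []
    spore = -1  # filled by caller
    for i in sorted(selected):
        s, e, v = runs[i]
        units.append(_Unit(
            spore=spore, kind="tract",
            left_idx=int(obs_idx[runs[i - 1][1] - 1]),
            right_idx=int(obs_idx[runs[i + 1][0]]),
            first_idx=int(obs_idx[s]), last_idx=int(obs_idx[e - 1]),
            v_from=runs[i - 1][2], v_to=v,
        ))
    # net switches between remaining (background) runs
    bg = [r for i, r in enumerate(runs) if i not in selected]
    for a, b in zip(bg[:-1], bg[1:]):
        if a[2] != b[2]:
            units.append(_Unit(
                spore=spore, kind="switch",
                left_idx=int(obs_idx[a[1] - 1]), right_idx=int(obs_idx[b[0]]),
                first_idx=int(obs_idx[b[0]]), last_idx=int(obs_idx[a[1] - 1]),
                v_from=a[2], v_to=b[2],
            ))
    units.sort(key=lambda u: (u.left_idx, u.right_idx))
    return units


def _cluster_units(
    units: list[_Unit], pos: np.ndarray, merge_window: int,
    max_tract_span: float = 0.0,
) -> list[list[_Unit]]:
    units = sorted(units, key=lambda u: (pos[u.left_idx], pos[u.right_idx]))
    clusters: list[list[_Unit]] = []
    right = -math.inf
    for u in units:
        if clusters and pos[u.left_idx] - right <= merge_window:
            clusters[-1].append(u)
        else:
            clusters.append([u])
        right = max(right, pos[u.right_idx])

    def net(cluster: list[_Unit]) -> dict[int, int]:
        """Net direction (+1: 1->2, -1: 2->1) per spore with odd switches."""
        out: dict[int, int] = {}
        for u in cluster:
            if u.kind == "switch":
                out[u.spore] = out.get(u.spore, 0) + (1 if u.v_from == 1 else -1)
        return {s: d for s, d in out.items() if d != 0}

    # repair pass: a crossover with a long heteroduplex tract leaves its two
    # reciprocal switches in different clusters; merge adjacent clusters with
    # complementary unbalanced switch parity within max_tract_span
    if max_tract_span > 0:
        merged = True
        while merged and len(clusters) > 1:
            merged = False
            for k in range(len(clusters) - 1):
                a, b = clusters[k], clusters[k + 1]
                gap = pos[min(u.left_idx for u in b)] - pos[max(u.right_idx for u in a)]
                na, nb = net(a), net(b)
                if (gap <= max_tract_span and len(na) % 2 == 1 and len(nb) % 2 == 1
                        and sum(na.values()) + sum(nb.values()) == 0):
                    clusters = clusters[:k] + [a + b] + clusters[k + 2:]
                    merged = True
                    break
    return clusters


def _find_flank_phase(
    g: np.ndarray, idx: int, direction: int
) -> tuple[tuple[int, ...] | None, int | None]:
    """Nearest complete 2:2 marker at or beyond ``idx`` in ``direction``."""
    m = g.shape[1]
    i = idx
    while 0 <= i < m:
        col = g[:, i]
        if (col != 0).all() and (col == 1).sum() == 2:
            return tuple(int(x) for x in col), i
        i += direction
    return None, None


def _pair_four_strand(switches: list[_Unit]) -> list[tuple[_Unit, _Unit]]:
    """Pair reciprocal switches of a four-strand double crossover.

    Spores switching 1->2 are matched to spores switching 2->1 by proximity
    of their switch gaps.
    """
    ups = [u for u in switches if u.v_from == 1]
    downs = [u for u in switches if u.v_from == 2]
    pairs: list[tuple[_Unit, _Unit]] = []
    downs = list(downs)
    for u in ups:
        if not downs:
            break
        j = int(np.argmin([abs(d.left_idx - u.left_idx) for d in downs]))
        pairs.append((u, downs.pop(j)))
    return pairs


def _tract_fields(pos, first_idx, last_idx, left_idx, right_idx) -> dict:
    d0, d1 = int(pos[first_idx]), int(pos[last_idx])
    f0, f1 = int(pos[left_idx]), int(pos[right_idx])
    length = (d1 + f1) / 2.0 - (d0 + f0) / 2.0  # midpoint convention
    return dict(
        tract_start=float(d0), tract_end=float(d1) + 1.0,
        tract_len=float(max(length, 1.0)),
        _tract_marks=(first_idx, last_idx, left_idx, right_idx),
    )


def _classify_cluster(
    cluster: list[_Unit], g: np.ndarray, pos: np.ndarray
) -> list[dict]:
    """Classify one breakpoint cluster into event rows (possibly several)."""
    switches = [u for u in cluster if u.kind == "switch"]
    tracts = [u for u in cluster if u.kind == "tract"]
    left_bound = min(u.left_idx for u in cluster)
    right_bound = max(u.right_idx for u in cluster)
    phase_before, bi = _find_flank_phase(g, left_bound, -1)
    phase_after, ai = _find_flank_phase(g, right_bound, +1)
    if phase_before is None and phase_after is None:
        return []

    rows: list[dict] = []
    base = dict(
        start=int(pos[left_bound]), end=int(pos[right_bound]),
        pos=(int(pos[left_bound]) + int(pos[right_bound])) // 2,
        tract_start=np.nan, tract_end=np.nan, tract_len=np.nan,
        n_markers=int(right_bound - left_bound - 1),
    )

    net_spores = sorted({u.spore for u in switches
                         if sum(1 for s in switches if s.spore == u.spore) % 2 == 1})

    def interior_patterns() -> list[tuple[int, ...]]:
        pats = []
        for m in range(left_bound + 1, right_bound):
            col = g[:, m]
            if (col != 0).all():
                pats.append(tuple(int(x) for x in col))
        return pats

    def is_phase_segment(t: _Unit) -> bool:
        """True when a sandwich run is 2:2 inside (an exchanged segment of a
        second crossover sharing the chromatid, not a conversion tract)."""
        cols = g[:, t.first_idx:t.last_idx + 1]
        complete = (cols != 0).all(axis=0)
        if not complete.any():
            return False
        n1 = (cols == 1).sum(axis=0)
        return float((n1[complete] == 2).mean()) >= 0.5

    if len(net_spores) == 2:
        i, j = net_spores
        si = [u for u in switches if u.spore == i]
        sj = [u for u in switches if u.spore == j]
        ui, uj = si[0], sj[0]
        chromatids = f"{i + 1}+{j + 1}"
        same_gap = ui.left_idx == uj.left_idx and ui.right_idx == uj.right_idx
        row = dict(base, kind="CO", chromatids=chromatids)
        if same_gap and not tracts:
            row["cls"] = "a"
            row["start"], row["end"] = int(pos[ui.left_idx]), int(pos[ui.right_idx])
            row["pos"] = (row["start"] + row["end"]) // 2
        elif not tracts:
            # offset reciprocal switches: 3:1 heteroduplex tract between them
            first, second = (ui, uj) if ui.right_idx <= uj.right_idx else (uj, ui)
            if first.right_idx > second.left_idx:
                # gaps interleave without a resolvable 3:1 region
                row["cls"] = "a"
            else:
                row["cls"] = "b"
                row.update(_tract_fields(
                    pos, first.right_idx, second.left_idx,
                    first.left_idx, second.right_idx,
                ))
            row["chromatids"] = chromatids
        else:
            phase_segs = [t for t in tracts if is_phase_segment(t)]
            if len(phase_segs) == 1 and len(tracts) == 1:
                # two crossovers sharing the sandwiched chromatid: the
                # interior is 2:2 of a different phase, not a conversion
                t = phase_segs[0]
                near_i = abs(ui.left_idx - t.left_idx) <= abs(uj.left_idx - t.left_idx)
                first_partner, second_partner = (i, j) if near_i else (j, i)
                for partner, l_idx, r_idx in (
                    (first_partner, t.left_idx, t.first_idx),
                    (second_partner, t.last_idx, t.right_idx),
                ):
                    a, b = sorted((t.spore, partner))
                    start, end = int(pos[l_idx]), int(pos[r_idx])
                    rows.append(dict(
                        base, kind="CO", cls="a", chromatids=f"{a + 1}+{b + 1}",
                        start=start, end=end, pos=(start + end) // 2,
                    ))
                return rows
            involved = {i, j}
            t_spores = {t.spore for t in tracts}
            if not same_gap:
                row["cls"] = "f" if (t_spores - involved) else "e"
            elif t_spores <= involved:
                row["cls"] = "c" if len(tracts) == 1 else "e"
            elif not (t_spores & involved):
                row["cls"] = "d" if len(tracts) == 1 else "e"
            else:
                row["cls"] = "f"
            t = tracts[0]
            row.update(_tract_fields(pos, t.first_idx, t.last_idx,
                                     t.left_idx, t.right_idx))
        rows.append(row)
    elif len(net_spores) == 4:
        for a, b in _pair_four_strand(
            [u for u in switches if u.spore in net_spores]
        ):
            i, j = sorted((a.spore, b.spore))
            row = dict(base, kind="CO", chromatids=f"{i + 1}+{j + 1}")
            if a.left_idx == b.left_idx and a.right_idx == b.right_idx:
                row["cls"] = "a"
                row["start"], row["end"] = int(pos[a.left_idx]), int(pos[a.right_idx])
                row["pos"] = (row["start"] + row["end"]) // 2
            else:
                first, second = (a, b) if a.right_idx <= b.right_idx else (b, a)
                row["cls"] = "b"
                row.update(_tract_fields(
                    pos, first.right_idx, second.left_idx,
                    first.left_idx, second.right_idx,
                ))
            rows.append(row)
    elif len(net_spores) == 0 and (tracts or switches):
        pats = interior_patterns()
        has_40 = any(p.count(1) in (0, 4) for p in pats)
        # reciprocal tract pair = double CO on that chromatid pair
        recip: tuple[_Unit, _Unit] | None = None
        for x in range(len(tracts)):
            for y in range(x + 1, len(tracts)):
                a, b = tracts[x], tracts[y]
                if a.v_to == b.v_from and a.v_from == b.v_to and \
                        a.first_idx <= b.last_idx and b.first_idx <= a.last_idx:
                    recip = (a, b)
        if has_40 and not recip:
            t = tracts[0] if tracts else None
            row = dict(base, kind="NCO", cls="k",
                       chromatids="+".join(str(t.spore + 1) for t in tracts) or "")
            if t is not None:
                lo = min(t.first_idx for t in tracts)
                hi = max(t.last_idx for t in tracts)
                fl = min(t.left_idx for t in tracts)
                fr = max(t.right_idx for t in tracts)
                row.update(_tract_fields(pos, lo, hi, fl, fr))
            rows.append(row)
        elif recip is not None:
            a, b = recip
            i, j = sorted((a.spore, b.spore))
            extra = [t for t in tracts if t not in recip]
            cls = "g" if not extra else ("h" if len(extra) == 1 else "i")
            row = dict(base, kind="CO", cls=cls, chromatids=f"{i + 1}+{j + 1}")
            lo = min(a.first_idx, b.first_idx)
            hi = max(a.last_idx, b.last_idx)
            if cls != "g":
                t = extra[0]
                row.update(_tract_fields(pos, t.first_idx, t.last_idx,
                                         t.left_idx, t.right_idx))
            row["start"] = int(pos[min(a.left_idx, b.left_idx)])
            row["end"] = int(pos[max(a.right_idx, b.right_idx)])
            row["pos"] = (row["start"] + row["end"]) // 2
            rows.append(row)
            # a double CO contributes two crossovers
            rows.append(dict(row, _dup_of_double=True))
        else:
            for t in tracts:
                row = dict(base, kind="NCO", cls="j", chromatids=str(t.spore + 1))
                row.update(_tract_fields(pos, t.first_idx, t.last_idx,
                                         t.left_idx, t.right_idx))
                row["start"], row["end"] = int(pos[t.left_idx]), int(pos[t.right_idx])
                row["pos"] = (row["start"] + row["end"]) // 2
                rows.append(row)
    else:
        # odd number of net switches: unresolved flank (chromosome end or
        # conflicting noise) - emit a complex CO involving the net spores
        if phase_before is None or phase_after is None:
            return []
        row = dict(base, kind="CO", cls="e",
                   chromatids="+".join(str(s + 1) for s in net_spores))
        rows.append(row)
    return rows


def call_events(
    tetrads: TetradSet,
    markers: MarkerMap | None = None,
    mask: MaskSet | None = None,
    params: CallerParams | None = None,
) -> EventCatalog:
    """Call and classify recombination events for every tetrad.

    Markers inside masked intervals and chromosomes flagged aneuploid (or
    excluded by the mask) are removed before calling; called events whose
    bounding interval still intersects the mask are dropped.  Phase
    conservation (2:2 outside events) is checked and violations counted in
    the catalog provenance.
    """
    params = params or CallerParams()
    markers = markers or tetrads.markers
    rows: list[dict] = []
    phase_violations = 0
    for chrom in tetrads.chromosomes:
        if chrom in tetrads.aneuploid_flags:
            continue
        if mask is not None and chrom in mask.excluded_chromosomes:
            continue
        pos_all = markers[chrom]
        if mask is not None and mask.intervals:
            keep = np.ones(len(pos_all), dtype=bool)
            for c, s, e in mask.intervals:
                if c == chrom:
                    keep &= ~((pos_all >= s) & (pos_all < e))
        else:
            keep = np.ones(len(pos_all), dtype=bool)
        pos = pos_all[keep]
        if len(pos) == 0:
            continue
        for t_idx, tname in enumerate(tetrads.tetrad_names):
            g = tetrads.genotypes[chrom][t_idx][:, keep]
            units: list[_Unit] = []
            for s in range(4):
                obs = np.flatnonzero(g[s] != 0)
                for u in _spore_units(obs, g[s][obs], pos,
                                      params.min_tract_markers,
                                      params.max_tract_span):
                    u.spore = s
                    units.append(u)
            event_spans: list[tuple[int, int]] = []
            for cluster in _cluster_units(units, pos, params.merge_window,
                                          params.max_tract_span):
                for row in _classify_cluster(cluster, g, pos):
                    row.pop("_tract_marks", None)
                    dup = row.pop("_dup_of_double", False)
                    row.update(tetrad=tname, chrom=chrom)
                    if mask is not None and mask.overlaps(
                        chrom, row["start"], row["end"]
                    ):
                        continue
                    if not dup:
                        event_spans.append((row["start"], row["end"]))
                    rows.append(row)
            # phase conservation outside events
            complete = (g != 0).all(axis=0)
            n1 = (g == 1).sum(axis=0)
            bad = complete & (n1 != 2)
            if bad.any():
                in_event = np.zeros(len(pos), dtype=bool)
                for s, e in event_spans:
                    in_event |= (pos >= s) & (pos <= e)
                phase_violations += int((bad & ~in_event).sum())

    df = events_frame(rows)
    provenance = dict(
        caller=dict(merge_window=params.merge_window,
                    min_tract_markers=params.min_tract_markers),
        n_tetrads=tetrads.n_tetrads,
        phase_violations=phase_violations,
        mask_intervals=len(mask.intervals) if mask else 0,
    )
    return EventCatalog(df, provenance)


def measure_tract(event: pd.Series | dict, convention: str = "midpoint") -> float:
    """Conversion-tract length (bp) under a stated convention.

    minimal
        distance from the first to the last deviating marker (1 bp floor);
    midpoint (default)
        distance between the midpoints of the two flanking
        agreeing/deviating marker gaps;
    maximal
        distance between the flanking agreeing markers.

    Requires ``tract_start``/``tract_end`` (deviating-marker extent) and
    ``start``/``end`` (flanking agreeing markers) on the event.
    """
    d0 = float(event["tract_start"])
    d1 = float(event["tract_end"]) - 1.0
    if not np.isfinite(d0):
        raise ValueError("event has no conversion tract")
    f0 = float(event["start"])
    f1 = float(event["end"])
    if convention == "minimal":
        return max(d1 - d0, 1.0)
    if convention == "midpoint":
        return (d1 + f1) / 2.0 - (d0 + f0) / 2.0
    if convention == "maximal":
        return f1 - f0
    raise ValueError(f"unknown convention {convention!r}")


def flag_recurrent_double_crossovers(
    catalog: EventCatalog,
    recurrence_fraction: float = 0.8,
    radius: int = 5_000,
    min_tetrads: int = 10,
) -> tuple[pd.DataFrame, EventCatalog]:
    """Filter double-CO loci recurring across tetrads (parental mitotic COs).

    A locus shows a double-CO signature in a tetrad when that tetrad has
    two or more crossovers within ``radius`` of the locus midpoint on one
    chromosome (four-strand doubles and same-pair doubles), or a single
    complex/double-class crossover (classes e-i) there — a coincident
    meiotic crossover merges with the inherited double into one complex
    call.  Loci whose signature recurs in at least ``recurrence_fraction``
    of tetrads are flagged; their events are removed from the returned
    catalog and listed in the side table.  Below ``min_tetrads`` tetrads
    recurrence is not meaningful and nothing is filtered.
    """
    df = catalog.df
    n_tetrads = int(catalog.provenance.get("n_tetrads") or df["tetrad"].nunique())
    empty = pd.DataFrame(columns=["chrom", "pos", "n_tetrads", "fraction"])
    if len(df) == 0 or n_tetrads < min_tetrads:
        return empty, catalog

    co = df[df["kind"] == "CO"]
    # per (tetrad, chrom): loci with a double-CO signature
    sig: list[tuple[str, float, str]] = []  # (chrom, locus position, tetrad)
    for (tet, chrom), grp in co.groupby(["tetrad", "chrom"]):
        p = np.sort(grp["pos"].to_numpy(dtype=float))
        for a, b in zip(p[:-1], p[1:]):
            if b - a <= radius:
                sig.append((chrom, (a + b) / 2.0, tet))
        for _, row in grp[grp["cls"].isin(list("efghi"))].iterrows():
            sig.append((chrom, float(row["pos"]), tet))
    if not sig:
        return empty, catalog

    flagged_rows = []
    drop_index: set[int] = set()
    sig_df = pd.DataFrame(sig, columns=["chrom", "pos", "tetrad"])
    for chrom, grp in sig_df.groupby("chrom"):
        p = grp.sort_values("pos")
        clusters: list[list[int]] = []
        last = -math.inf
        for idx, row in p.iterrows():
            if row["pos"] - last <= radius and clusters:
                clusters[-1].append(idx)
            else:
                clusters.append([idx])
            last = row["pos"]
        for cl in clusters:
            sub = grp.loc[cl]
            frac = sub["tetrad"].nunique() / n_tetrads
            if frac >= recurrence_fraction:
                center = float(sub["pos"].mean())
                flagged_rows.append(dict(
                    chrom=chrom, pos=center,
                    n_tetrads=int(sub["tetrad"].nunique()), fraction=frac,
                ))
                hit = df[(df["chrom"] == chrom) & (df["kind"] == "CO") &
                         ((df["pos"] - center).abs() <= 2 * radius)]
                drop_index.update(hit.index)

    flagged = pd.DataFrame(flagged_rows,
                           columns=["chrom", "pos", "n_tetrads", "fraction"])
    filtered = EventCatalog(
        df.drop(index=sorted(drop_index)).reset_index(drop=True),
        dict(catalog.provenance, recurrent_loci_removed=len(flagged)),
    )
    return flagged, filtered


def summarize_events(catalog: EventCatalog) -> dict:
    """Per-meiosis counts, per-class counts and the GCco fraction."""
    from .core import TRACT_CO_CLASSES

    df = catalog.df
    n_tetrads = int(catalog.provenance.get("n_tetrads") or
                    (df["tetrad"].nunique() if len(df) else 0))
    co = df[df["kind"] == "CO"]
    nco = df[df["kind"] == "NCO"]

    def per_meiosis(sub: pd.DataFrame) -> np.ndarray:
        counts = sub.groupby("tetrad").size()
        if n_tetrads and len(counts) < n_tetrads:
            counts = counts.reindex(
                counts.index.tolist() +
                [f"__absent{i}" for i in range(n_tetrads - len(counts))],
                fill_value=0,
            )
        return counts.to_numpy()

    co_counts = per_meiosis(co)
    nco_counts = per_meiosis(nco)
    gcco = float((co["cls"].isin(TRACT_CO_CLASSES)).mean()) if len(co) else float("nan")
    return dict(
        n_tetrads=n_tetrads,
        n_co=int(len(co)),
        n_nco=int(len(nco)),
        co_per_meiosis_median=float(np.median(co_counts)) if len(co_counts) else 0.0,
        co_per_meiosis_mean=float(np.mean(co_counts)) if len(co_counts) else 0.0,
        nco_per_meiosis_median=float(np.median(nco_counts)) if len(nco_counts) else 0.0,
        nco_per_meiosis_mean=float(np.mean(nco_counts)) if len(nco_counts) else 0.0,
        gcco_fraction=gcco,
        class_counts=df["cls"].value_counts().to_dict() if len(df) else {},
    )
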