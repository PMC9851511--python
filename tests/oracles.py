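"""Independent brute-force oracles used by the tests.

These deliberately avoid the production caller's machinery: the
minimal-event enumerator explains an observed 4 x M genotype matrix by
forward-generating candidate event sets and returns the smallest number of
events that reproduces the observation exactly.
"""

from itertools import combinations, product

import numpy as np

BASE = np.array([1, 1, 2, 2], dtype=np.int8)
PAIRS = [(0, 2), (0, 3), (1, 2), (1, 3)]


def genotype_from_events(positions, events):
    """Forward model: genotypes implied by an event list.

    Events are ("CO", i, j, t0, t1) with recipient strand i cut at t0 and
    donor j at t1 (conversion toward j's parent in [t0, t1)), or
    ("NCO", c, t0, t1) flipping chromatid c over [t0, t1).  Re-implements
    segment path-following independently with per-marker simulation.
    """
    positions = np.asarray(positions, dtype=float)
    g = np.tile(BASE[:, None], (1, len(positions)))
    cos = [e for e in events if e[0] == "CO"]
    # walk each chromatid through the crossover cut graph
    cuts = [[] for _ in range(4)]
    for eid, (_, i, j, t0, t1) in enumerate(cos):
        cuts[i].append((t0, eid, 0))
        cuts[j].append((t1, eid, 1))
    for s in range(4):
        cuts[s].sort()
    out = np.empty_like(g)
    for s in range(4):
        cur, y = s, 0.0
        while True:
            nxt = next((c for c in cuts[cur] if c[0] > y), None)
            if nxt is None:
                out[s, positions >= y] = BASE[cur]
                break
            x, eid, side = nxt
            out[s, (positions >= y) & (positions < x)] = BASE[cur]
            _, i, j, t0, t1 = cos[eid]
            if side == 0:
                out[s, (positions >= t0) & (positions < t1)] = BASE[j]
                cur, y = j, t1
            else:
                cur, y = i, t1
    for e in events:
        if e[0] == "NCO":
            _, c, t0, t1 = e
            sel = (positions >= t0) & (positions < t1)
            out[c, sel] = 3 - out[c, sel]
    return out


def minimal_event_count(positions, observed, max_events=3):
    """Smallest number of events whose forward model matches ``observed``.

    Candidate cut points are restricted to inter-marker gaps where some
    spore's genotype changes (all other cuts are observationally
    equivalent).  Enumeration covers crossovers (all ordered strand pairs,
    all cut-gap pairs) and single-chromatid conversion tracts.
    """
    positions = np.asarray(positions, dtype=float)
    observed = np.asarray(observed, dtype=np.int8)
    if np.array_equal(observed, np.tile(BASE[:, None], (1, len(positions)))):
        return 0
    switch_gaps = set()
    for s in range(4):
        for m in np.flatnonzero(np.diff(observed[s]) != 0):
            switch_gaps.add((positions[m] + positions[m + 1]) / 2.0)
    gaps = sorted(switch_gaps) + [positions[-1] + 1.0]

    candidates = []
    for i, j in PAIRS:
        for a, b in ((i, j), (j, i)):
            for t0 in gaps:
                for t1 in gaps:
                    if t1 >= t0:
                        candidates.append(("CO", a, b, t0, t1))
    for c in range(4):
        for x0 in range(len(gaps)):
            for x1 in range(x0 + 1, len(gaps)):
                candidates.append(("NCO", c, gaps[x0], gaps[x1]))

    for k in range(1, max_events + 1):
        for combo in combinations(candidates, k):
            if np.array_equal(genotype_from_events(positions, list(combo)),
                              observed):
                return k
    return None
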