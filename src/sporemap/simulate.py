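"""Synthetic tetrad generator with known ground truth.

Crossovers are placed along each bivalent as a mixture of an interfering
pathway (stationary gamma renewal process: inter-event gaps ~ gamma(shape,
scale), shape > 1 giving positive interference) and a non-interfering
"sprinkled" pathway (uniform, Poisson-distributed count).  Each crossover is
assigned to one of the four non-sister chromatid pairs with equal probability
(no chromatid interference) and carries a detectable gene-conversion tract
with probability ``gcco_prob``; noncrossovers are independent single-chromatid
conversion tracts.  Spore genotypes follow chromatid ancestry, with optional
symmetric genotyping error and missingness.

The defaults emulate the hybrid yeast cross this pipeline was designed for:
~10 Mb genome, markers every ~159 bp (median), ~21 COs and ~7 NCOs per
meiosis, gamma shape 1.23, ~7.7% sprinkled COs, ~2 kb conversion tracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import NON_SISTER_PAIRS, MarkerMap, TetradSet
from .genome import GenomeLayout, merge_intervals

# gamma(shape=2) has median 1.67835 * scale; used to convert a configured
# median tract length into the scale of the tract-length law
_GAMMA2_MEDIAN = float(stats.gamma.ppf(0.5, a=2.0))

#: number of mean gap lengths simulated before the origin so that the renewal
#: process is effectively stationary when it enters the chromosome
_BURN_IN_GAPS = 12.0


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.  Rates are per meiosis unless stated otherwise.

    co_shape, co_scale
        Gamma shape (dimensionless) and scale (kb) of the interfering
        inter-crossover gap law.  When ``co_per_meiosis`` is set the scale is
        rescaled internally so the renewal intensity matches the requested
        genome-wide expectation; ``co_scale`` then only fixes the shape/scale
        family used for drawing.
    co_per_meiosis
        Expected total crossovers per meiosis across the layout (interfering
        + sprinkled).  ``None`` uses ``co_scale`` directly as the gap scale.
    p_sprinkle
        Proportion of crossovers from the non-interfering (type II) pathway.
    nco_rate
        Expected noncrossovers per Mb per meiosis.
    gcco_prob
        Probability that a crossover carries a detectable conversion tract.
    tract_median_co, tract_median_nco
        Median conversion-tract lengths (kb); tract lengths are drawn from a
        gamma(shape=2) law rescaled to the configured median (a right-skewed
        strictly-positive stand-in; the true law is not identified).
    marker_spacing_median
        Median distance between consecutive markers (bp); spacings are
        exponential (Poisson marker process).
    missing_rate, error_rate
        Per-genotype missingness and symmetric allele-flip probabilities.
    """

    co_shape: float = 1.23
    co_scale: float = 145.9
    co_per_meiosis: float | None = 21.0
    p_sprinkle: float = 0.077
    nco_rate: float = 1.2
    gcco_prob: float = 0.73
    tract_median_co: float = 2.0
    tract_median_nco: float = 1.8
    marker_spacing_median: float = 159.0
    missing_rate: float = 0.01
    error_rate: float = 0.001
    loh_intervals: tuple[tuple[str, int, int], ...] = ()
    aneuploid_chromosomes: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.co_shape > 0 and self.co_scale > 0):
            raise ValueError("gamma shape and scale must be positive")
        for name in ("p_sprinkle", "gcco_prob", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nco_rate < 0:
            raise ValueError("nco_rate must be >= 0")
        if self.co_per_meiosis is not None and self.co_per_meiosis < 0:
            raise ValueError("co_per_meiosis must be >= 0")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


@dataclass
class TruthCatalog:
    """Ground-truth events injected by the simulator (one row per event).

    Columns: tetrad, chrom, kind (CO/NCO), pos (exchange point, bp),
    chromatids ("i+j" for COs, "c" for NCOs), tract_start, tract_end
    (NaN when the event carries no conversion tract).
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def detectable(self, markers: MarkerMap) -> pd.DataFrame:
        """Subset of events a caller can possibly see.

        A CO is detectable when at least one marker lies on each side of
        its exchange region.  An NCO needs a marker inside its tract plus
        flanking markers on both sides: a tract truncated by a chromosome
        end is indistinguishable from a terminal segment of foreign
        ancestry and carries no callable signature.
        """
        keep = []
        for _, row in self.df.iterrows():
            pos = markers[row["chrom"]]
            if row["kind"] == "CO":
                lo = row["tract_start"] if np.isfinite(row["tract_start"]) else row["pos"]
                hi = row["tract_end"] if np.isfinite(row["tract_end"]) else row["pos"]
                keep.append(bool(np.any(pos < lo) and np.any(pos >= hi)))
            else:
                inside = (pos >= row["tract_start"]) & (pos < row["tract_end"])
                flanked = np.any(pos < row["tract_start"]) and \
                    np.any(pos >= row["tract_end"])
                keep.append(bool(np.any(inside) and flanked))
        return self.df[np.array(keep, dtype=bool)] if keep else self.df


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and positive, got {value}")


def _stationary_renewal(
    length: float, shape: float, mean_gap: float, rng: np.random.Generator
) -> np.ndarray:
    """Event positions in [0, length) of a stationary gamma renewal process.

    Stationarity is achieved by starting the process ``_BURN_IN_GAPS`` mean
    gaps before the origin, which makes the distribution of the first event
    indistinguishable from the equilibrium (length-biased) delay law.
    """
    scale = mean_gap / shape
    start = -_BURN_IN_GAPS * mean_gap
    span = length - start
    positions: list[float] = []
    t = start
    n_guess = max(8, int(span / mean_gap * 1.5) + 8)
    while t < length:
        gaps = rng.gamma(shape, scale, size=n_guess)
        cum = t + np.cumsum(gaps)
        inside = cum[(cum >= 0) & (cum < length)]
        positions.append(inside)
        t = cum[-1]
    out = np.concatenate([np.atleast_1d(p) for p in positions]) if positions else np.array([])
    return np.sort(out)


def place_crossovers(
    chrom_length: float,
    expected_co: float,
    shape: float,
    scale: float,
    p_sprinkle: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Crossover positions (bp) on one bivalent under the two-pathway model.

    A fraction ``1 - p_sprinkle`` of events comes from a stationary gamma
    renewal process whose intensity is rescaled so the expected interfering
    count is ``(1 - p_sprinkle) * expected_co``; the remainder are sprinkled
    uniformly with a Poisson count.  With ``expected_co=None`` the gap law is
    gamma(``shape``, ``scale`` kb) taken literally (no rescaling) and the
    sprinkled expectation is derived from the renewal intensity.
    """
    _check_positive("chrom_length", chrom_length)
    _check_positive("shape", shape)
    if not (0.0 <= p_sprinkle <= 1.0):
        raise ValueError("p_sprinkle must be in [0, 1]")
    if expected_co is None:
        _check_positive("scale", scale)
        if p_sprinkle >= 1.0:
            raise ValueError("expected_co is required when p_sprinkle == 1")
        mean_gap = shape * scale * 1000.0  # kb -> bp
        exp_interfering = (chrom_length / mean_gap)
        exp_sprinkle = exp_interfering * p_sprinkle / (1.0 - p_sprinkle)
    else:
        if not np.isfinite(expected_co) or expected_co < 0:
            raise ValueError("expected_co must be finite and >= 0")
        exp_interfering = (1.0 - p_sprinkle) * expected_co
        exp_sprinkle = p_sprinkle * expected_co
        if exp_interfering <= 0:
            mean_gap = None
        else:
            mean_gap = chrom_length / exp_interfering

    parts = []
    if mean_gap is not None and exp_interfering > 0:
        parts.append(_stationary_renewal(chrom_length, shape, mean_gap, rng))
    n_sprinkle = rng.poisson(exp_sprinkle) if exp_sprinkle > 0 else 0
    if n_sprinkle:
        parts.append(rng.uniform(0.0, chrom_length, size=n_sprinkle))
    if not parts:
        return np.array([], dtype=float)
    return np.sort(np.concatenate(parts))


def simulate_co_count_matrix(
    chrom_length: float,
    n_meioses: int,
    expected_co: float,
    shape: float,
    p_sprinkle: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Vectorized batch of ``place_crossovers`` draws (one array per meiosis).

    Used by the two-pathway fitter where many thousands of meioses are
    simulated per candidate parameter point.
    """
    exp_int = (1.0 - p_sprinkle) * expected_co
    out: list[np.ndarray] = [np.array([], dtype=float) for _ in range(n_meioses)]
    if exp_int > 0:
        mean_gap = chrom_length / exp_int
        scale = mean_gap / shape
        start = -_BURN_IN_GAPS * mean_gap
        span = chrom_length - start
        k = max(4, int(span / mean_gap + 6 * math.sqrt(span / mean_gap) + 8))
        gaps = rng.gamma(shape, scale, size=(n_meioses, k))
        cum = start + np.cumsum(gaps, axis=1)
        # extend rows that did not reach the chromosome end
        while np.any(cum[:, -1] < chrom_length):
            extra = rng.gamma(shape, scale, size=(n_meioses, k))
            cum = np.concatenate([cum, cum[:, -1:] + np.cumsum(extra, axis=1)], axis=1)
        inside = (cum >= 0) & (cum < chrom_length)
        for i in range(n_meioses):
            out[i] = cum[i, inside[i]]
    if p_sprinkle > 0 and expected_co > 0:
        counts = rng.poisson(p_sprinkle * expected_co, size=n_meioses)
        for i, c in enumerate(counts):
            if c:
                out[i] = np.sort(np.concatenate([out[i], rng.uniform(0, chrom_length, c)]))
    return out


def _tract_length(median_kb: float, rng: np.random.Generator) -> float:
    """Tract length in bp from gamma(shape=2) scaled to the given median."""
    scale_bp = median_kb * 1000.0 / _GAMMA2_MEDIAN
    return float(rng.gamma(2.0, scale_bp))


def make_marker_map(
    layout: GenomeLayout, spacing_median: float, rng: np.random.Generator
) -> MarkerMap:
    """Poisson marker positions with the requested median spacing."""
    mean_spacing = spacing_median / math.log(2.0)
    positions: dict[str, np.ndarray] = {}
    for chrom in layout.chromosomes:
        n_guess = int(chrom.length / mean_spacing * 1.3) + 10
        gaps = rng.exponential(mean_spacing, size=n_guess)
        pos = np.cumsum(gaps)
        while pos[-1] < chrom.length:
            more = np.cumsum(rng.exponential(mean_spacing, size=n_guess))
            pos = np.concatenate([pos, pos[-1] + more])
        pos = pos[pos < chrom.length].astype(np.int64)
        pos = np.unique(pos)
        positions[chrom.name] = pos
    return MarkerMap(positions)


def _ancestry_from_events(
    pos: np.ndarray, events: list[tuple[int, int, float, float]]
) -> np.ndarray:
    """Chromatid ancestry by segment path-following through crossovers.

    ``events`` are crossovers ``(i, j, t0, t1)`` on 0-based strands: the
    recipient strand ``i`` is cut at ``t0``, the donor strand ``j`` at
    ``t1 >= t0``, flanks rejoined crosswise with the segment ``[t0, t1)``
    copied from the donor (the heteroduplex conversion tract, 3:1 toward
    the donor's parent).  Each final chromatid is a path over original
    strand segments; crossovers are placed on the intact four-strand
    bivalent, so events sharing a strand compose correctly (two-strand
    doubles restore phase, three-strand doubles leave one double-switched
    chromatid, four-strand doubles invert the phase of all four).  Callers
    must keep the ``[t0, t1]`` cut intervals of distinct events disjoint;
    2:2 segregation outside conversion tracts is then guaranteed.
    """
    base = (1, 1, 2, 2)
    cuts: list[list[tuple[float, int, int]]] = [[], [], [], []]
    for eid, (i, j, t0, t1) in enumerate(events):
        cuts[i].append((t0, eid, 0))   # broken (recipient) strand
        cuts[j].append((t1, eid, 1))   # donor strand
    for s in range(4):
        cuts[s].sort()
    anc = np.empty((4, len(pos)), dtype=np.int8)
    for s in range(4):
        cur, y = s, 0.0
        while True:
            nxt = next((c for c in cuts[cur] if c[0] > y), None)
            if nxt is None:
                anc[s, pos >= y] = base[cur]
                break
            c, eid, side = nxt
            anc[s, (pos >= y) & (pos < c)] = base[cur]
            i, j, t0, t1 = events[eid]
            if side == 0:
                # conversion patch [t0, t1) copied from the donor strand,
                # then continue on the donor past its cut
                anc[s, (pos >= t0) & (pos < t1)] = base[j]
                cur, y = j, t1
            else:
                cur, y = i, t1
    return anc


def simulate_tetrads(
    layout: GenomeLayout,
    params: SimParams,
    n_tetrads: int,
) -> tuple[TetradSet, TruthCatalog]:
    """Simulate a full tetrad set plus its ground-truth event catalog.

    Every injected event is recorded in the truth catalog, including events
    spanning zero markers (undetectable by any caller).  LOH intervals and
    aneuploid chromosomes listed in ``params`` are injected after the clean
    meioses are generated (see :func:`inject_artifacts`).
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    for name in params.aneuploid_chromosomes:
        if name not in layout:
            raise ValueError(f"aneuploid chromosome {name!r} not in layout")
    rng = np.random.default_rng(params.seed)
    markers = make_marker_map(layout, params.marker_spacing_median, rng)

    total = layout.total_length
    tetrad_names = [f"T{i + 1:03d}" for i in range(n_tetrads)]
    genotypes = {
        c.name: np.zeros((n_tetrads, 4, len(markers[c.name])), dtype=np.int8)
        for c in layout.chromosomes
    }
    truth_rows: list[dict] = []

    for t_idx, tname in enumerate(tetrad_names):
        for chrom in layout.chromosomes:
            pos = markers[chrom.name]
            expected = (
                None
                if params.co_per_meiosis is None
                else params.co_per_meiosis * chrom.length / total
            )
            co_pos = place_crossovers(
                chrom.length, expected, params.co_shape, params.co_scale,
                params.p_sprinkle, rng,
            )
            co_events: list[tuple[int, int, float, float]] = []
            for k, x in enumerate(co_pos):
                # cut intervals of adjacent crossovers must stay disjoint:
                # clamp tracts at the midpoints to neighboring exchanges
                lo = 0.0 if k == 0 else (co_pos[k - 1] + x) / 2.0
                hi = float(chrom.length) if k == len(co_pos) - 1 \
                    else (x + co_pos[k + 1]) / 2.0
                i, j = NON_SISTER_PAIRS[rng.integers(4)]
                if rng.random() < 0.5:
                    i, j = j, i
                if rng.random() < params.gcco_prob:
                    ell = _tract_length(params.tract_median_co, rng)
                    u = rng.random()
                    t0 = max(lo, x - u * ell)
                    t1 = min(hi, t0 + ell)
                    t1 = max(t1, x)
                    t0 = min(t0, x)
                else:
                    t0 = t1 = x
                co_events.append((i - 1, j - 1, t0, t1))
                truth_rows.append(dict(
                    tetrad=tname, chrom=chrom.name, kind="CO", pos=float(x),
                    chromatids=f"{min(i, j)}+{max(i, j)}",
                    tract_start=t0 if t1 > t0 else np.nan,
                    tract_end=t1 if t1 > t0 else np.nan,
                ))
            anc = _ancestry_from_events(pos, co_events)
            n_nco = rng.poisson(params.nco_rate * chrom.length / 1e6)
            for _ in range(n_nco):
                c = int(rng.integers(4))
                ell = _tract_length(params.tract_median_nco, rng)
                x = rng.uniform(0, chrom.length)
                t0 = max(0.0, x - rng.random() * ell)
                t1 = min(float(chrom.length), t0 + ell)
                inside = (pos >= t0) & (pos < t1)
                anc[c, inside] = 3 - anc[c, inside]
                truth_rows.append(dict(
                    tetrad=tname, chrom=chrom.name, kind="NCO", pos=float(x),
                    chromatids=str(c + 1), tract_start=t0, tract_end=t1,
                ))
            genotypes[chrom.name][t_idx] = anc

    tetrads = TetradSet(markers, tetrad_names, genotypes)
    truth = TruthCatalog(pd.DataFrame(
        truth_rows,
        columns=["tetrad", "chrom", "kind", "pos", "chromatids",
                 "tract_start", "tract_end"],
    ))

    if params.loh_intervals or params.aneuploid_chromosomes:
        tetrads = inject_artifacts(
            tetrads,
            loh_intervals=list(params.loh_intervals),
            aneuploid_chromosomes=set(params.aneuploid_chromosomes),
            rng=rng,
        )

    # genotype noise last, so artifacts are noisy too
    if params.error_rate > 0 or params.missing_rate > 0:
        for chrom in tetrads.chromosomes:
            g = tetrads.genotypes[chrom]
            if params.error_rate > 0:
                flip = rng.random(g.shape) < params.error_rate
                g[flip] = 3 - g[flip]
            if params.missing_rate > 0:
                miss = rng.random(g.shape) < params.missing_rate
                g[miss] = 0
    return tetrads, truth


def inject_artifacts(
    tetrads: TetradSet,
    loh_intervals: list[tuple[str, int, int]] | None = None,
    aneuploid_chromosomes: set[str] | None = None,
    recurrent_dco_loci: list[tuple[str, float]] | None = None,
    recurrence_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> TetradSet:
    """Overlay parental-hybrid artifacts on a simulated tetrad set.

    LOH intervals become 4:0/0:4 (one fixed parental allele per merged
    interval) in every tetrad; aneuploid chromosomes are flagged and given a
    chromosome-wide complex (non-2:2) segregation pattern; recurrent
    double-CO loci receive a four-strand double-crossover signature in a
    ``recurrence_fraction`` of tetrads, emulating mitotic crossovers in the
    parental diploid.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    out = tetrads.copy()
    for chrom, start, end in merge_intervals(loh_intervals or []):
        if chrom not in out.markers.positions:
            raise ValueError(f"LOH interval on unknown chromosome {chrom!r}")
        pos = out.markers[chrom]
        inside = (pos >= start) & (pos < end)
        allele = int(rng.integers(1, 3))
        out.genotypes[chrom][:, :, inside] = allele
    for chrom in aneuploid_chromosomes or set():
        if chrom not in out.markers.positions:
            raise ValueError(f"aneuploid chromosome {chrom!r} not in tetrad set")
        out.aneuploid_flags.add(chrom)
        g = out.genotypes[chrom]
        n_t, _, n_m = g.shape
        # an extra chromosome copy perturbs segregation at most markers:
        # flip one random spore at ~60% of markers, per tetrad
        for t in range(n_t):
            hit = rng.random(n_m) < 0.6
            spore = rng.integers(0, 4, size=n_m)
            idx = np.where(hit)[0]
            vals = g[t, spore[idx], idx]
            g[t, spore[idx], idx] = np.where(vals != 0, 3 - vals, vals)
    for chrom, x in recurrent_dco_loci or []:
        pos = out.markers[chrom]
        distal = pos >= x
        for t in range(out.n_tetrads):
            if rng.random() >= recurrence_fraction:
                continue
            # four-strand double CO: every chromatid toggles at the locus
            g = out.genotypes[chrom][t]
            seg = g[:, distal]
            g[:, distal] = np.where(seg != 0, 3 - seg, seg)
    return out
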