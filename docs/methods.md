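# Methods

`sporemap` reconstructs a meiotic recombination landscape from tetrad
genotypes: four haploid spores per meiosis, each genotyped at tens of
thousands of heterozygous markers coded by parental origin. This note
records the models, the algorithms, the defaults and the choices made where
the design was genuinely open.

## The data model

A hybrid diploid is heterozygous at every marker, so in a clean tetrad every
marker segregates 2:2. Recombination perturbs this locally:

* a **crossover (CO)** exchanges the distal segments of two non-sister
  chromatids — two spores switch parental origin at the same point;
* a crossover usually carries a **gene-conversion tract (GCco)**: the two
  reciprocal switch points are offset by the heteroduplex repair tract, and
  markers between them segregate 3:1;
* a **noncrossover (NCO)** is a conversion tract on a single chromatid with
  the flanking phase unchanged (an isolated 3:1 run);
* **loss of heterozygosity (LOH)** in the parental hybrid makes whole
  regions 4:0/0:4 in every tetrad, and an aneuploid chromosome deviates
  from 2:2 with a complex chromosome-wide pattern — both must be masked
  before events are called.

Spores are indexed 1–4 with sister pairs fixed as {1,2} and {3,4}; the four
non-sister pairs are equally likely to exchange (no chromatid
interference). Internally all coordinates are 0-based half-open; 1-based
inclusive coordinates appear only in TSV files, and BED files are standard
0-based half-open.

## Synthetic tetrads (the closed loop)

Every downstream stage is validated against the generator in
`simulate.py`, whose defaults are the study conditions this pipeline was
built around:

| parameter | default | meaning |
|---|---|---|
| genome | 8 chromosomes, 10.2 Mb (A = 1.12 Mb) | full layout; B and D (2.35 Mb) are the aneuploid pair |
| analyzed layout | 6 chromosomes, 5.7 Mb | post-masking territory; lengths rounded to 20 kb so the 5 kb and 20 kb tilings are exact |
| `marker_spacing_median` | 159 bp | markers are a Poisson process (exponential gaps) |
| `co_per_meiosis` | 21 | expected COs per meiosis, apportioned by chromosome length |
| `co_shape`, `co_scale` | 1.23, 145.9 kb | gamma gap law of the interfering pathway |
| `p_sprinkle` | 0.077 | non-interfering (type II) CO fraction, placed uniformly with Poisson counts |
| `nco_rate` | 1.2 / Mb | NCOs per Mb per meiosis |
| `gcco_prob` | 0.73 | probability a CO carries a conversion tract |
| `tract_median_co`, `tract_median_nco` | 2.0, 1.8 kb | median tract lengths |
| `missing_rate`, `error_rate` | 0.01, 0.001 | independent missingness; symmetric allele flips |

Interfering COs are a **stationary gamma renewal process**: the chain is
started 12 mean gaps before the origin, which makes the first event's law
indistinguishable from the equilibrium (length-biased) delay and the
interior gap distribution exactly gamma. When an expected count is given,
the scale is rescaled so the renewal intensity matches
`(1 − p_sprinkle) · expected / length`.

Chromatid genotypes follow **segment path-following through the crossover
cut graph**: every crossover cuts its recipient strand at `t0` and its
donor strand at `t1 ≥ t0`; flanks are rejoined crosswise with `[t0, t1)`
copied from the donor (the 3:1 conversion tract). Crossovers are placed on
the intact four-strand bivalent, so events sharing a chromatid compose
correctly — a two-strand double restores phase, a three-strand double
leaves one double-switched chromatid, a four-strand double inverts the
phase of all four spores. Naive sequential "swap the distal contents"
updating silently annihilates three-strand doubles (the exchanged segments
already carry the same parent), and per-chromatid "toggle the parental
source" updating breaks 2:2 phase; both were rejected for the cut-graph
walk, which provably preserves 2:2 outside tracts (the strand segments at
any position are a partition). Tract cut intervals of adjacent crossovers
are clamped at the midpoints between exchange points so the walk stays
balanced; this truncates a tract only when two crossovers fall within a
couple of kilobases of each other.

Tract lengths are gamma with shape 2 rescaled to the configured median — a
right-skewed, strictly positive stand-in; the true law is not identified by
the data this emulates, so the law is a single function
(`_tract_length`) that can be swapped.

What the generator does **not** emulate: read-level noise (coverage,
mapping artifacts), non-uniform marker density around divergence hotspots,
crossover hotspot fine structure (placement is homogeneous within a
chromosome), mitotic LOH formation mechanisms, and disomic spore genotypes
(aneuploidy is emulated as chromosome-wide complex segregation, not as an
extra sequenced copy). Passing closed-loop tests therefore validates the
algorithms, not the upstream genotyping.

## Segregation screening and masking

`classify_segregation` tabulates the per-marker class (2:2, 3:1, 1:3, 4:0,
0:4, incomplete) per tetrad and the modal class across tetrads. LOH
detection scans 50 kb windows and flags maximal runs in which at most 5% of
markers behave heterozygously (the window size is standard; the 5% cutoff
is this package's explicit, tunable default). Aneuploidy is flagged when
more than 20% of a chromosome's markers show complex (3:1/1:3) segregation
chromosome-wide — a trisomy perturbs markers everywhere, LOH perturbs
contiguous blocks toward 4:0, which is how the two are separated. A spore
is suspect when fewer than 95% of fully-genotyped markers are
2:2-consistent with its three siblings; suspect tetrads are reported, never
auto-removed. `build_mask` merges LOH intervals, whole excluded
chromosomes and extra intervals (e.g. translocation breakpoints);
`analyzed_length` is the total minus the mask, counted once.

## Event calling

Per tetrad and chromosome, after removing masked markers:

1. **Unit decomposition.** Each spore's genotype sequence is run-length
   encoded. Sandwich runs (a run flanked by two runs of the same value)
   shorter than `min_tract_markers` (default 2) are healed as genotyping
   noise; longer ones up to `max_tract_span` (default 15 kb) become
   candidate conversion tracts; everything else becomes switches. A
   sequence like 1,2,1,2 is ambiguous (tract-then-switch vs
   switch-then-tract), so candidate tracts are chosen greedily by
   increasing bp span as a non-adjacent set — conversion tracts are short,
   exchanged crossover segments long.
2. **Clustering.** Units closer than `merge_window` (default 5 kb, chosen
   to match the hotspot window scale) form one breakpoint cluster. A
   repair pass reunites adjacent clusters with complementary unbalanced
   switch parity within `max_tract_span` — a crossover with a long
   heteroduplex tract otherwise leaves its two reciprocal switches in
   different clusters.
3. **Classification.** Flanking 2:2 phases are read off the nearest
   complete 2:2 markers on each side. Two net-switched spores = a CO
   (class a when the reciprocal switches share one inter-marker gap,
   class b when offset with a 3:1 region between); four = a four-strand
   double (two CO rows); zero with a reciprocal tract pair = a same-pair
   double CO (classes g–i, two CO rows); zero with single-chromatid 3:1
   tracts = NCOs (class j); 4:0 interior = class k. A sandwiched segment
   whose interior is 2:2 of a different phase is two crossovers sharing a
   chromatid, not a conversion, and is split accordingly. Ties go to the
   explanation with fewest chromatid exchanges. The taxonomy letters b–f
   are operationalized as: b contiguous tract on an involved chromatid, c
   detached tract on an involved chromatid, d tract on an uninvolved
   chromatid, e complex, f tracts on both involved and uninvolved
   chromatids.
4. **Masking and audit.** Events whose bounding interval intersects the
   mask are dropped; every complete marker outside called events is
   checked to be 2:2 and violations are counted into the catalog
   provenance.

The CO position is the midpoint of the bounding informative-marker
interval (rounded down). Tract lengths are reported under three
conventions: *minimal* (first to last deviating marker, 1 bp floor),
*midpoint* (between the midpoints of the two flanking gaps; the default),
*maximal* (between the flanking agreeing markers).

Recurrent double-CO loci (mitotic crossovers in the parental hybrid)
are flagged by clustering double-CO signatures — two CO rows within 5 kb,
or one complex/double-class (e–i) row — and removing loci whose signature
recurs in ≥ 80% of tetrads (≥ 10 tetrads required).

Chromatid labels are molecule labels: a called pair equals the generator's
strand pair only for the first exchange on a chromosome, because every
upstream crossover re-routes molecules across strands.

## Landscape statistics

Windows tile each chromosome from 0; the trailing partial window is kept;
windows more than 50% masked leave both the scan set and the null set, so
observed and null window counts stay equal. The hotspot/coldspot null
re-places all observed crossovers into the scan windows with equal
probabilities (multinomial), records each permutation's extreme window
count, and takes the `ceil(fdr·n_perm)`-th most extreme (the 2,000th of
10⁵ at 2%) as the threshold; significance is strict. An exact-enumeration
check (4 events in 2 windows) pins the order statistics, and the per-scan
false-positive rate is verified to track the FDR on uniform data.

At the full study scale (4,049 events, 5.7 Mb), the exact binomial tails
place both thresholds on a knife edge: with 1,140 five-kb windows
P(max ≥ 14) = 2.4% and with 285 twenty-kb windows P(min ≤ 2) = 2.2%, so
this implementation stably returns 14 and 2. Thresholds of 13 and 3 would
require ≥ ~1,165 and ≤ ~283 windows respectively — mutually inconsistent
with any single analyzed length, i.e. that pair can only arise from two
scans with different effective window sets. The acceptance suite asserts
the published pair and is left failing with this analysis on record.

E₀ (non-exchange) chromosomes are meioses with zero called COs on a
chromosome; rates are reported per meiosis and per Mb in both mean and
median variants (the two differ and the choice is not standardized;
`co_density` additionally gives the pooled events-per-Mb figure).
Chromosome regressions are ordinary least squares of mean CO count on
chromosome size, observed and size-corrected (count scaled by
full/analyzed length); the rate–size correlation uses 50 cM per CO per
meiosis, the standard tetrad map-length conversion. Tract statistics
compare GCco and NCO tract lengths with a two-sided Mann–Whitney U test.

## Interference

*Gamma fit.* Adjacent-CO distances are pooled over tetrads and
chromosomes (kilobases) and fitted by gamma maximum likelihood with the
location fixed at zero; shape 1 means no interference. Raw, uncensored
gaps are fitted deliberately — finite chromosomes censor long gaps, which
biases the shape, but this matches the procedure the fit is meant to
reproduce and the bias is shared by the values it is compared against.
The KS test against the no-interference reference uses a gamma of shape 1
with the scale taken from the full fit, parameters treated as fixed; the
asymptotic p-value is therefore mildly anti-conservative, also by design.

*Coefficient of coincidence.* Chromosomes are tiled with fixed intervals
(default 25 kb). For each interval pair at distance d: observed = fraction
of meioses with a CO in both; expected = product of the marginals; CoC(d)
is the ratio of summed observed to summed expected over pairs, which
weights pairs by informativeness and skips uninformative ones.
`interference = 1 − CoC` exactly. The relative mode rescales chromosomes
to unit length with bin size 1/(5 × mean relative inter-CO distance).

*Two-pathway (gamma-sprinkling) fit.* A mixture of an interfering gamma
renewal (shape ν) and a fraction p of uniformly sprinkled crossovers is
fitted by simulation: each candidate (ν, p) simulates `n_sims` meioses per
chromosome with per-chromosome expected counts matched to the data, and is
scored by (i) the two-sample KS distance between pooled gap distributions,
(ii) 3 × the short-gap CDF mismatch at 10 and 25 kb — sprinkled crossovers
leave a positive gap density near zero that a renewal lacks, and the
sup-norm alone dilutes that signature — and (iii) 0.3 × the per-chromosome
count dispersion-index mismatch (a full count-histogram distance at a few
hundred meioses is dominated by sampling noise). Scores are averaged over
three fixed random streams; positions closer than the calling resolution
(the caller's merge window, from catalog provenance) are collapsed
identically on both sides. Optimization is a coarse (ν, p) grid followed
by coordinate hill climbing with step halving; the grid exists because the
two parameters trade off almost exactly at weak interference and a climb
from a fixed start stalls on the ridge. Degenerate corners are flagged:
at ν = 1 the renewal is itself Poisson and p drops out of the likelihood;
at p = 1 ν does.

**Identifiability caveat.** At interference as weak as this data's
(ν ≈ 1.2–1.3), the sprinkled fraction is not statistically identifiable
from one 192-tetrad experiment: across the (ν, p) ridge the short-gap
fractions differ by ≲ 0.002 while their sampling SE at ~2,900 gaps is
~0.002, so any estimator's p scatters over several percentage points
(observed: 0–20% across data seeds). Recovery is accurate at stronger
interference — the test suite verifies ν = 2, p = 0.20 recovered within
±0.05 — but at ν ≈ 1.2 the fitted p should be read as "small", not as a
two-digit number.

## Hotspot conservation

A source hotspot is anchored by its five closest genes (midpoint distance,
ties to the smaller gene start); if at least two of their target-species
orthologs lie within 10 kb of each other on one target chromosome, the
block spanning those anchors is the projection ("more than two" in one
description vs "at least two" in another is resolved as ≥ 2). A
projection is conserved when a target hotspot lies within 5 kb,
edge-to-edge (0 when overlapping; whether the rule is edge-to-edge or
midpoint-to-midpoint is not specified anywhere, so the stricter reading is
the default and `max_sep` is a parameter).

## Problem sizes and budgets

The test suite simulates 24 noise-free tetrads over the 5.7 Mb analyzed
layout for closed-loop checks (~690 detectable events), uses 10⁴–4×10⁴
permutations for threshold order statistics, and 192 tetrads for the
two-pathway recovery checks; the full suite runs in about a minute. The
acceptance script uses the full 10⁵ permutations for both thresholds,
5,000 gaps for the gamma refit, and a full 192-tetrad
simulate → call → fit round for the two-pathway target (~30 s total).

## Known limitations

* The caller cannot resolve two crossovers closer than `merge_window`
  unless they involve disjoint chromatid pairs, and a crossover pair
  sharing a chromatid within `max_tract_span` is intrinsically ambiguous
  with a CO-plus-tract — parsimony picks the single event unless the
  sandwiched segment is 2:2 of a different phase.
* Conversion tracts truncated by a chromosome end have no callable
  signature and are excluded from the detectable set.
* Permutation thresholds sit on integer knife edges at study scale; see
  the landscape section.
* The two-pathway decomposition is honest but weakly identified at weak
  interference; see the caveat above.
* Aneuploidy emulation is segregation-level only; coverage-based
  aneuploidy detection from reads is out of scope.
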