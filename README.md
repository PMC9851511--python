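# sporemap

Meiotic recombination landscape analysis from yeast tetrads.

A hybrid diploid yeast sporulated into four-spore tetrads exposes all four
chromatids of one meiosis: genotyping each spore at the parents'
heterozygous markers reveals every crossover (CO, a reciprocal switch of
two spores' parental origin), every detectable noncrossover (NCO, a 3:1
gene-conversion tract with unchanged flanking phase), and the artifacts
that must be masked first (loss-of-heterozygosity tracts segregating
4:0/0:4, aneuploid chromosomes with complex segregation). `sporemap` is
for geneticists running such tetrad experiments — built around a
*Lachancea waltii* cross (10.2 Mb over chromosomes A–H, markers every
~159 bp, ~21 COs per meiosis) but parameterized for any tetrad-forming
fungus. It provides:

* **a ground-truth tetrad simulator** — interfering COs as a stationary
  gamma renewal process (inter-CO gaps ~ Γ(γ, θ); γ = 1 no interference,
  γ > 1 positive interference) mixed with a sprinkled non-interfering
  fraction *p*, conversion tracts, LOH, aneuploidy and genotype noise, so
  every stage has a closed-loop test;
* **segregation screening** — per-marker 2:2/3:1/4:0 classes, LOH and
  aneuploidy detection, tetrad consistency checks, mask construction;
* **a transparent event caller** — CO/NCO detection and classification
  into the single-tetrad taxonomy (classes a–k), tract measurement under
  minimal/midpoint/maximal conventions, and filtering of recurrent
  double-CO loci inherited from mitotic crossovers in the parental hybrid;
* **landscape statistics** — windowed CO density; hotspot/coldspot calling
  against an equal-probability permutation null (the threshold is the
  ⌈FDR·n⌉-th most extreme per-permutation window count); E₀ (non-exchange)
  chromosome frequencies; rates and genome-wide extrapolations;
  chromosome-size regressions; tract-length statistics;
* **crossover interference** — inter-CO distance pooling, gamma MLE with a
  KS test against the shape-1 (no-interference) reference, coefficient of
  coincidence CoC(d) = observed double-CO frequency / expected under
  independence, tetrad-label randomization controls, and a two-pathway
  (gamma-sprinkling) decomposition fitted by simulation;
* **hotspot conservation** — ortholog-anchored synteny projection
  (five closest genes, 10 kb block rule, 5 kb conservation rule).

## Worked example

```python
import sporemap as sm

layout = sm.analyzed_layout()                  # 6 chromosomes, 5.7 Mb
params = sm.SimParams(seed=7)                  # study-condition defaults
tetrads, truth = sm.simulate_tetrads(layout, params, 48)
catalog = sm.call_events(tetrads)

s = sm.summarize_events(catalog)
rates = sm.event_rates(catalog, layout.total_length, 48,
                       genome_total=sm.waltii_layout().total_length)
fit = sm.fit_gamma(sm.inter_crossover_distances(catalog))
e0 = sm.e0_statistics(catalog, layout.names, 48)
```

prints, via the obvious f-strings:

```
called 999 COs and 291 NCOs in 48 tetrads
median per meiosis: 21 CO, 6 NCO; GCco fraction 0.67
CO rate 3.65/Mb -> 37.2 genome-wide
gamma fit: shape 1.40, scale 141 kb (n=710); KS vs shape-1: p=3.5e-21
meioses with >=1 E0 chromosome: 8.3%
```

Reading this: 48 simulated meioses yielded ~21 crossovers each (median),
two thirds of crossovers carried a detectable conversion tract, and the
crossover rate extrapolates to ~37 per meiosis over the full 10.2 Mb
genome. The gamma shape fitted to inter-crossover distances is above 1
and the Kolmogorov–Smirnov test rejects the shape-1 reference decisively:
crossovers interfere. One meiosis in twelve had at least one chromosome
segregate without any crossover (E₀).

The same pipeline runs from the shell on TSV/BED files:

```bash
sporemap simulate --seed 7 --n-tetrads 48 --outdir sim
sporemap segregate sim/genotypes.tsv --outdir seg
sporemap call-events sim/genotypes.tsv --mask seg/mask.bed --outdir ev
sporemap landscape ev/events.tsv --mask seg/mask.bed --outdir land
sporemap interference ev/events.tsv --outdir itf
```

Real data enters through the same formats: a genotype TSV (chromosome,
1-based position, then `<tetrad>_<a..d>` spore columns coded 1/2/NA), an
optional biallelic VCF, or a ReCombine-style event TSV with a configurable
column mapping (`sporemap.io.read_event_table`).

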