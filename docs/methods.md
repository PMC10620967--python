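# Methods

This note records the statistical model, the synthetic-data generator, the
numerical choices and the known limitations of `cytotype`, at the level of
detail a user needs to judge what a passing test suite does and does not
demonstrate.

## Flow-cytometric genome-size estimation

Each analysis is one plant co-stained with an internal standard
(2C = 3.38 pg by default). Channel values are an arbitrary linear scale;
only the ratio of peak means is meaningful, and the genome-size formula
`GS = F_sample/F_standard × GS_standard` is scale-free. Histograms use
equal-width half-open bins over `[0, max)`; 256 bins by default.

Peak detection runs on a 5-bin moving average of the counts so Poisson
noise cannot split a broad peak into two apexes; an apex must have smoothed
prominence above 5 % of the maximum count and be ≥ 4 bins from a higher
apex. Windows extend from the apex until the smoothed histogram drops below
10 % of the apex count (at most 25 bins each way); overlapping windows are
cut at the intervening count minimum; windows with fewer than 50 raw events
are discarded. The decaying debris shoulder has no interior local maximum
and is excluded by construction. Within a window, the mean uses all raw
events and the CV uses the population SD (divide by n). Because the window
clips the peak at roughly ±2.1 within-peak SDs, the estimated CV
underestimates the generating CV by ~9 %; the peak mean is unaffected
(symmetric truncation). The quality filter is strict: an analysis is kept
iff *both* the sample and the standard peak CV are < 2.5 %. Applying the
threshold to both peaks is the conservative reading of a protocol that
records CVs "for all fluorescent peaks".

The standard peak is identified as the detected peak closest to the
configured reference channel (200 by default). When only one peak is found
the sample is taken to co-locate with the standard, the genome size equals
the standard's, and a warning is attached — a genuine sample at the
standard's genome size is indistinguishable from a failed analysis without
a second stain.

## Synthetic studies

The generator emulates the sampling design the analysis assumes:

* **Cytotypes.** Eight groups (2x … 7x, monoploid number x = 7) with the
  published component means and SDs (2.587/0.036 … 8.643/0.100 pg). Each
  individual's true genome size is drawn from Normal(μ_c, σ_c) of its
  cytotype: the tabulated SDs are treated as *between-individual* spread,
  while the peak CVs are *within-analysis* dispersion. Default prevalences
  (6xC 0.49, 6xB and 4xA 0.12, 7x 0.10, the rest ≤ 0.05) are this package's
  choice, qualitatively mirroring a landscape dominated by the heaviest
  hexaploid; the source field data report no group frequencies.
* **Populations.** 133 populations × 15 individuals by default. A
  configurable fraction (0.38) of populations receives a mixed composition
  row (dominant group weight 0.6, one or two companions sharing 0.4); the
  rest are pure. A population's habitat (natural vs anthropogenic) is
  Bernoulli with probability taken from a per-cytotype table keyed by the
  row's dominant group — hexaploids road-associated, diploids and
  pentaploids natural-only.
* **Events.** 3500 particles per analysis: the standard peak at channel
  200, the sample peak at `200 × GS/3.38`, Gaussian with relative SD CV/100
  (1.5 % by default), a binomial `debris_fraction` (0.10) drawn from an
  exponential truncated at the lower peak and scaled to a third of it — a
  left-shoulder background. 15 % of analyses get both CVs inflated to
  3–6 % so the quality filter has realistic work; this approximates the
  study-scale attrition.
* **Anchors.** 39 chromosome-counted individuals. Quotas are near-equal
  per group (minor cytotypes deliberately oversampled relative to
  frequency, as calibration campaigns do), and within a group anchors sit
  at evenly spaced quantile ranks of the central ±2 SD genome-size range —
  margins included, because group boundaries are later read off the extreme
  anchored individuals. Anchors avoid analyses flagged for QC injection.
  Every anchor's 2n is exactly 7 × ploidy; the generator produces no
  aneuploids.
* **Reproducibility.** One master seed is split per population and
  individual via `numpy.random.SeedSequence`, so a fixed seed yields
  byte-identical studies and any subset is reproducible.

What the generator does **not** emulate: spectral spillover, doublets,
cell-cycle (G2) peaks, multi-channel acquisition, instrument drift, or
heavy-tailed measurement error. Passing tests therefore demonstrate the
statistical machinery under clean Gaussian conditions, not robustness to
every artefact of real cytometers.

## Mixture fitting

`fit_gmm` is plain 1D EM with k components. Initialisation: the first
start places means at k evenly spaced sample quantiles with uniform weights
and per-component SD = pooled SD / k (a full pooled-SD start flattens the
first E-step and loses the quantile structure); the remaining starts (10 by
default) come from seeded 1D k-means++ — quantiles track the probability
mass, k-means the support, covering both balanced and strongly skewed group
frequencies. Restarts use the two-phase short-run strategy: every start
runs at most 500 iterations and only the best by log-likelihood continues
to convergence (absolute log-likelihood change < 1e-8, hard cap 10⁶
iterations). Component SDs are floored at 1e-4 pg; a run whose component
collapses below the floor or empties is discarded. Fitting operates on a
sorted copy of the data, which makes the result exactly invariant to input
permutations. Components are stored sorted by mean; max-posterior ties in
classification go to the lower-mean component.

Model comparison: a component is *redundant* iff its weight is below 0.02
and its 1st–99th percentile interval lies entirely inside another
component's; `select_model` retains the largest candidate k with no
redundant components and reports log-likelihood, AIC and BIC per candidate
as diagnostics. Both the weight floor and the percentile pair are
configurable.

## Delimitation

Percentiles of fitted components use the closed form μ + z_p σ. Provisional
group intervals are the 1st–99th percentile intervals; for each *adjacent*
pair of different ploidy whose intervals overlap, the anchor rule replaces
the facing edges (highest/lowest counted genome size of the respective
ploidy); homoploid neighbours keep percentile edges; the outermost edges
are unbounded by default (a switch restores percentile tails). All
intervals are half-open `[low, high)`. An individual in exactly one
interval is assigned; in zero or several, unassigned — ambiguity is never
resolved by posterior probability, keeping the rule purely interval-based
and conservative. Anchored individuals assigned against their counted
ploidy are reported as conflicts, never dropped.

Component-to-ploidy mapping classifies anchors by max posterior. The
strict mode (default of the library function) requires unanimous anchor
ploidies per component; the pipeline uses the lenient mode, where votes are
weighted by posterior responsibility and the heaviest ploidy wins, because
an anchor whose genome size strays across the posterior boundary of two
overlapping components occurs regularly under the generative model and
would otherwise abort unattended runs. Exact ties and uncovered components
are always errors. Chromosome counts that are not multiples of 7 are
rejected as putative aneuploids.

## Population structure

`groups_present` of a population excludes unassigned individuals (their
count is reported separately), so "mixed" is strictly about delimited
groups; group-mixed and ploidy-mixed fractions are both reported since two
homoploid groups make a population group-mixed but not ploidy-mixed.
Intersection counts order combinations by frequency, ties lexicographic.
The habitat association table counts, per group, the natural and
anthropogenic populations containing it and attaches a two-sided
permutation p-value (habitat labels shuffled across populations, 10⁴
permutations by default, seeded). The counts are the descriptive result and
the p-values diagnostics only — the underlying field study reports no
formal habitat test. For calibration checks the test offers a
randomized-tie-breaking p-value, which is exactly Uniform(0, 1) under the
null at the price of one extra random draw; the default estimator is the
conservative `(c+1)/(B+1)` form.

## Problem sizes and tolerances used in the tests

Mixture-recovery checks fit n = 1200 genome sizes (150 per group at equal
weights). The tolerance for recovered component means is 3 Monte-Carlo SEs,
where the SEs are the replicate SDs of the fitted means over 30 independent
simulate+fit runs (0.0025–0.0318 pg per component); overlap between
neighbouring components makes these up to 2.3× larger than the naive
σ/√(n·w). Model-selection behaviour is measured over 20 seeded replicates.
Event-level checks use 3500 particles per analysis; full-pipeline checks
run 40–133 populations. The grid-search oracle for EM uses k = 2 at n = 50
with a dense parameter grid.

## Known limitations

* **Homoploid ambiguity floor.** With the published 6xA/6xB/6xC overlaps,
  the shared percentile stretches contain roughly 4–5 % of individuals at
  equal weights; under the unassigned-on-ambiguity rule these can never be
  recovered, so end-to-end label recovery plateaus near 90–93 % even with a
  perfect fit. The unassigned rate, not misassignment, dominates the error.
* **k-selection on clean data.** On data simulated exactly from eight
  Gaussian components, the best k = 9 fit usually gives its extra component
  weight 0.02–0.05 and a protruding interval, so the redundancy rule does
  not flag it and the larger k is retained in most seeds. A "very small,
  entirely overlapped" extra component — the behaviour that motivates
  preferring k = 8 on real data — is a property of real, heavier-tailed
  post-QC measurements rather than of the clean generative model.
* **Fit fragility on skewed small samples.** With ≲ 500 QC-passed samples
  and 3 %-prevalence groups, k = 8 EM can merge minor components or split
  the dominant one (the good and pathological optima can tie in likelihood
  to within 0.1); delimitation then refuses with a component-coverage or
  mapping error. This is a data-size effect; at the default study scale
  (~1700 QC-passed) it is rare but not absent.
* **Mixed-fraction overestimation.** Misassigned singletons create spurious
  group combinations, so the recovered mixed-population fraction
  systematically exceeds the generated one (e.g. ~0.54 group-mixed
  recovered for 0.38 generated); the ploidy-mixed fraction is much closer.
* **Sample–standard collision.** A sample whose genome size is near the
  standard's produces coincident peaks; the pipeline flags it and returns
  the standard's value rather than guessing.
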