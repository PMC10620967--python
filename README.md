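# cytotype

Flow-cytometric genome-size estimation and cytotype delimitation for
mixed-ploidy plant complexes.

Polyploid species complexes — the weeping alkali grass aggregate is the
motivating case — often hide several cytotypes: groups of individuals that
share a ploidy level and/or a characteristic 2C genome size. Field surveys
infer them by DNA flow cytometry (FCM): each plant is chopped and co-stained
with an internal standard of known DNA content, the fluorescence histogram is
evaluated into peak means and coefficients of variation (CV), and the
sample/standard ratio converts to picograms. Over hundreds of plants the
genome sizes form a multimodal distribution whose modes are candidate
cytotypes; chromosome counts on a calibration subset pin each mode to a
ploidy level. `cytotype` implements that whole chain, plus a synthetic-data
generator that emulates the field campaign, so every stage is testable
against ground truth.

## The model

Genome size of a sample co-stained with an internal standard of known
2C-value (here *Bellis perennis*, 2C = 3.38 pg):

```
GS = (F_sample / F_standard) × GS_standard        [pg, 2C]
```

with `F` the mean fluorescence of the respective histogram peak. Analyses
are kept only if every retained peak has CV = 100·SD/mean strictly below
2.5 %.

QC-passed genome sizes `x_i` are modelled as a k-component univariate
Gaussian mixture fitted by EM,

```
f(x) = Σ_j w_j · N(x; μ_j, σ_j²),   Σ_j w_j = 1,
```

with candidate k compared by a redundancy rule: a component that is very
small (w < 0.02) and whose 1st–99th percentile interval lies entirely inside
another component's interval adds no interpretable group; the largest k
without such components is retained.

Components become delimited genome-size groups using chromosome-counted
anchor individuals (ploidy = 2n/x, monoploid number x = 7):

1. between overlapping groups of different ploidy, the boundary is set by the
   anchored individuals — the lower group reaches up to the highest counted
   genome size of its ploidy, the upper group down to the lowest counted one;
2. between overlapping groups of the same ploidy each group keeps its own
   1st/99th Normal-percentile edge, so the shared stretch stays ambiguous.

Individuals whose genome size falls in exactly one group interval are
assigned to it; all others are left unassigned. Population summaries then
report pure vs mixed populations, group-combination counts (upset-style) and
natural vs anthropogenic habitat contingencies with a permutation diagnostic.

## Worked example

Simulate a study at the default scenario — 133 populations × 15 plants,
eight cytotypes between 2.587 pg (2x) and 8.643 pg (7x), 3500 particles per
analysis, 39 chromosome-counted anchors — and run the full pipeline:

```python
from cytotype import default_scenario, simulate_study, run_pipeline, RunConfig

study = simulate_study(default_scenario(seed=2))
population_of = dict(zip(study.truth["sample_id"], study.truth["population_id"]))
result = run_pipeline(study.events, study.chromosome_counts, study.populations,
                      population_of, RunConfig(k_candidates=(8,), seed=2))
print(result.report)
```

The run prints (abridged):

```
n_measured: 1995        n_qc_passed: 1707       k_chosen: 8
groups: ['2x', '4xA', '4xB', '5x', '6xA', '6xB', '6xC', '7x']
n_unassigned: 142       mixed_fraction_ploidy: 0.376
```

1995 analyses were evaluated, 1707 passed the 2.5 % CV filter (the generator
injects ~15 % deliberately degraded analyses), and the k = 8 mixture fit
recovered all eight generating components — e.g. the fitted 2x mean is
2.590 pg against the generating 2.587 pg, and 6xC (the dominant roadside
hexaploid) gets weight 0.52:

```
component  mean    sd  weight label        low   high   low_rule   high_rule
        0 2.590 0.035   0.046    2x       -inf  2.670  unbounded  percentile
        2 5.935 0.129   0.028   4xB      5.633  6.217 percentile      anchor
        6 8.198 0.134   0.521   6xC      7.885  8.456 percentile      anchor
```

The 4xB group's upper edge (6.217 pg) is an anchored tetraploid's genome
size — criterion 1 at the overlapping 4xB/5x boundary — while its lower edge
is the percentile rule. 142 individuals (8 %) fall in ambiguous or empty
stretches and stay unassigned. 37.6 % of populations are mixed-ploidy, and
the habitat table shows the qualitative field pattern the scenario encodes:
6xC sits in 62 anthropogenic vs 30 natural populations (permutation
p = 0.0002), whereas pentaploids are natural-only.

The same chain is available from the shell, stage by stage or end to end:

```
cytotype run-all --seed 2 --k 8 --out out/
cytotype simulate --seed 2 --out sim/
cytotype evaluate --events sim/events.csv --out measurements.csv
```

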