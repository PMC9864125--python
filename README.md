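# canmp

Microplastic quantification and dietary-intake risk analysis for canned-fish
market surveys.

Visual microscopy of digested fish tissue overcounts microplastics (MPs):
only a fraction of counted particles are confirmed as synthetic polymer by
µ-Raman spectroscopy, and some particles are laboratory background. `canmp`
takes a survey of per-can particle counts — brands nested in producers,
replicate cans per brand, a fixed-mass digested subsample per can — and
produces corrected concentrations, particle-composition summaries, annual
human-intake estimates with Monte Carlo uncertainty, and the inferential
stage (normality checks, one-way ANOVA across survey factors, weight–
abundance correlation). It is written for food-safety and exposure-assessment
researchers working with particle-count contamination surveys.

## The model

For brand *b* with replicate cans *r* = 1…n (subsample mass *m* grams,
count *c*):

```
raw_b        = mean_r( c_br / m × 100 )                 [MPs / 100 g]
corrected_b  = raw_b × (n_verified / n_analyzed)        [verification scaling]
grand        = mean_b(raw_b) × rate − blank             [scale, then subtract]
```

where `rate = n_verified / n_analyzed` is the spectroscopic verification
rate (64/79 ≈ 81% in the packaged reference survey) and `blank` is the
procedural-blank background (2 particles over 3 control dishes ≈ 0.67
items/dish). The order matters: blank subtraction is applied once, to the
overall mean, *after* verification scaling, and never to individual brands.

Annual intake for a consumption scenario (weekly rate *C* g/person/week,
exposure frequency *F* days/year) is

```
intake = (C / 7) × MPs × F        [items / person / year]
```

with `MPs` the corrected concentration in items per gram. Two rates are
carried: canned-fish consumption (MICF estimates, C = 0.54 g/week) and
overall fish consumption (MIF estimates, C = 16.84 g/week), each at
F ∈ {52, 156, 260}. Uncertainty is propagated by Monte Carlo under a
zero-truncated normal assumption (10,000 iterations by default), reporting
the mean and 5th/95th percentiles.

## Worked example

Generate a synthetic survey (7 producers × 5 brands × 3 cans), estimate
the correction constants from its own analyzed particles and blank dishes,
and fit:

```python
from canmp import CannedFishSurvey, simulate

cfg = simulate.GeneratorConfig(seed=7)
tables = simulate.generate_survey(cfg)
blanks = simulate.generate_blanks(cfg)
res = CannedFishSurvey.from_tables(
    tables, blank_counts=list(blanks["particle_count"])
).fit()
print(res.summary())
```

```
Canned-fish microplastic survey
===============================================
brands: 35    cans: 105
verification rate: 0.7938 (79%)
blank rate: 1.00 items/dish (mode: standard)

grand raw mean:        11.77 MPs/100 g
grand corrected mean:   8.34 ± 1.00 MPs/100 g
```

79% of this survey's analyzed particles were (synthetically) confirmed as
plastic, so the raw grand mean of 11.77 MPs/100 g shrinks to 8.34 after
scaling and background subtraction. Downstream analyses hang off the
results object:

```python
mc = res.monte_carlo()[3]          # fish consumption, once a week
print(mc.point_items_per_year, mc.mc_mean, mc.mc_p5, mc.mc_p95)
# 10.44  11.64  2.04  22.98       (items/person/year)
print(res.anova("producer").pvalue)
# ~0.0  (the generator injects a producer effect by default)
```

The same stages are available as a CLI:

```sh
canmp simulate --seed 7 --out-dir survey/
canmp correct --observations survey/observations.csv --out conc.csv
canmp compose --particles survey/particles.csv
canmp intake --concentrations conc.csv
canmp stats --observations survey/observations.csv --products survey/products.csv
```

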