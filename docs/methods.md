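# Methods

This note documents the statistical procedures `canmp` implements, the
conventions behind them, and what the synthetic-data tests do and do not
demonstrate.

## Count correction

Visual counts of MP-like particles are corrected in two steps, in a fixed
order:

1. **Verification scaling.** A random subsample (~30%) of counted
   particles is analyzed spectroscopically; the fraction confirmed as
   synthetic polymer is the verification rate. Counts and concentrations
   are multiplied by this rate. The rate is carried as the exact ratio
   (64/79 = 0.810127 in the reference survey), never the display-rounded
   81%: pre-rounding would compound error across every brand.
2. **Blank subtraction.** The procedural-blank background (items per
   control dish) is subtracted once, from the overall mean concentration,
   after scaling. Per-brand values receive no blank subtraction.

Scale-then-subtract and subtract-then-scale differ (on the reference data:
4.14 vs 4.26 MPs/100 g); the implementation scales first, which is the
order the reference survey used. Corrected values are floored at zero.

Two blank modes exist. The `standard` mode subtracts the per-dish rate
directly from the per-100 g mean, mirroring the reference survey's
arithmetic even though one dish corresponds to a 50 g subsample. A
`unit_consistent` mode converts the per-dish rate to per-100 g (×2 at
50 g) before subtracting; it is off by default because the standard mode
is what reproduces the published numbers.

### Two routes to the overall mean

The overall concentration can be pooled two ways, and they disagree
slightly whenever brands differ:

* **brand-mean route** (`corrections.grand_mean`) — unweighted mean of
  per-brand raw means, then scale and subtract. This is the pipeline
  default for survey data; on the reference raw means it gives
  5.929 × 0.8101 − 0.667 = 4.14 MPs/100 g.
* **pooled-count route** (`corrections.overall_mean_from_counts`) — the
  verification rate applied to the total counted particles over all cans
  (293 particles / 99 cans in the reference survey), expressed per 100 g,
  background subtracted. With the display-rounded constants (0.81, 0.67)
  this gives 4.12 MPs/100 g, which is the published overall value. The
  table reproduction therefore uses this route for the grand corrected
  cell; the discrepancy between the two printed grand numbers (5.93 raw is
  a brand mean, 4.12 corrected is a can mean) is inherent to the source
  table, not to this implementation.

### Presentation rounding

Internally the pipeline keeps full precision and rounds only at the
report layer (half-up, two decimals — `decimal`-based, since Python's
built-in `round` is half-even). The published intake columns were
demonstrably computed from corrected concentrations *after* rounding them
to two decimals (e.g. 6.254857 × 13.50 = 84.44 as printed, where the
unrounded 13.5021 would give 84.46), so the reproduction path feeds
display-rounded concentrations into the intake step. Library calls on user
data do not round.

Printed standard errors in the reference table are consistent with
scaling replicate-level errors by the verification rate, which is what
`correct_brand` does; the output metadata flags this choice.

## Intake estimation

`intake = (weekly_rate / 7) × concentration × exposure_days`. The weekly
consumption rates are divided by 7 because the exposure frequencies are in
days per year; this convention reproduces every published intake cell to
two decimals. Intake is linear in concentration, consumption rate and
exposure days (so the 260-day column is exactly five times the 52-day
column), and the unit is items per person per year.

## Monte Carlo uncertainty

Uncertainty in the intake is propagated by sampling Normal(m, s) where
`m` is the intake at the overall corrected concentration and `s` the
standard deviation of per-brand intakes (brand-level SE × √n_brands),
per scenario, pooled over brands. Sampling is zero-truncated by default —
negative intakes are unphysical under the normality assumption — via
`scipy.stats.truncnorm`; an untruncated variant mirrors a literal normal
assumption. Note that truncation at zero raises the mean above the point
estimate when the coefficient of variation is large; the reported
empirical mean is the mean of the truncated distribution, verified in
tests against its closed form. 10,000 iterations by default; the seed is
fixed in `MonteCarloConfig` and echoed in outputs so reports are
reproducible.

## Composition

Shape, color and size-class shares are percentages over particles with a
defined value; polymer shares are computed over spectroscopically
confirmed particles only (rejected and unanalyzed particles have no
defined polymer). Natural polymers (cellulose, chitin) are flagged
non-plastic but retained in polymer summaries, matching how spectroscopy
tables report them.

Size classes follow the debris scheme nanoplastic < 1 µm ≤ microplastic
≤ 5 mm < mesoplastic ≤ 20 mm < macroplastic ≤ 100 mm < megaplastic.
Classes are upper-inclusive — exactly 5 mm is microplastic — a convention
chosen because the scheme's prose ("5 mm–1 µm") does not state openness;
it is encoded in one place (`SIZE_CLASSES`) if a user needs the other
convention.

`reconstruct_counts` inverts printed two-decimal percentages to integer
counts by searching for the smallest consistent denominator; on the
reference polymer table this recovers 11 fibers and 53 fragments (64
verified particles), and the combined shares reproduce the printed totals
exactly (21.88% polyolefin = 14/64). Matching uses half-up rounding,
because printed values like 21.875 appear as 21.88.

## Inferential stage

Per-can abundances are counts and right-skewed, so analyses run on
log(x+1) by default (admitting zero counts; plain log is available via
`transform=False` plus a user transform for strictly positive data).
Normality is checked with Shapiro–Wilk and the Lilliefors variant of
Kolmogorov–Smirnov (the plain KS test is miscalibrated when the normal
parameters are estimated from the data). One-way ANOVA runs across
producer, package type, oil type, water usage and species; groups with a
single observation are dropped with a warning. Pearson correlation
relates product weight to abundance.

**Clustering caveat.** Replicate cans of a brand share that brand's
contamination level. For factors that vary only between brands (all five
above), per-can ANOVA is therefore anticonservative when brands are
heterogeneous: in null simulations with the generator's default
brand-intensity spread, per-can rejection ran near 40% at α = 0.05, while
brand-level aggregation restored ≈5%. The survey surface exposes
`level="can"` (the default, n = 99 in the reference design) and
`level="brand"` (n = 33); calibrated inference about brand-level factors
should use the brand level. The package's calibration tests run the null
check at brand level and the power check at the per-can default.

## Synthetic-data generator

The generator emulates the survey design: per-brand Poisson intensities
drawn uniformly from 1–17 MPs/100 g (spanning the reference survey's raw
means of 1.00–16.67), multiplied by a per-producer log-normal effect
(default SD 0.5 on the log scale, a typical ±65% producer multiplier —
comparable to the producer differences the reference survey detected);
per-can counts Poisson at the 50 g subsample scale with additive Poisson
background at 0.67 items per dish. Particles carry shape (57.3%
fragments), color (34.8% blue, 27.3% black, 11.9% white, 10.6%
transparent, remainder pooled as "other" since the source ranking leaves
15.4% unitemized), log-normal sizes truncated to the printed per-shape
ranges, and a latent true-MP label (P = 64/79, independent of shape by
default). A random 30% is marked analyzed; true MPs among them become
verified with a shape-conditional polymer drawn from the reconstructed
composition counts.

What the generator does *not* emulate: digestion losses, spectral
match-score uncertainty, shape-dependent verification probability (an
option exists in principle but the default is independence), per-color
blank matching, and any correlation between packaging and contamination.
Passing recovery tests therefore demonstrate that the pipeline's
arithmetic and estimators are consistent under the stated model, not that
the model captures every feature of real surveys.

## Problem sizes and tolerances in tests

The published-table reproduction is deterministic and exact to ±0.01 per
cell. Monte Carlo convergence is asserted within 3 Monte Carlo standard
errors at 10,000 iterations against the closed-form truncated-normal
mean. ANOVA type-I calibration uses 2,000 null simulations of 5 groups × 6
observations with log-normal-plus-one noise (so the log(x+1) transform
recovers exact normality), asserting 0.05 ± 0.02. End-to-end recovery uses
a 385-brand synthetic survey (≥5,000 particles), asserting the raw grand
mean within 2 SE and composition shares within ±2 percentage points.
Power and null-calibration link tests use 200 seeded surveys each at the
default design size.
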