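# Methods

## Generating model

Each replication draws a latent ability vector θ ~ N(0, 1) of length N
and produces three continuous score vectors: two independent human
ratings H = θ + ε and H₂ = θ + ε′ with ε, ε′ ~ N(0, σ_H²), and an AI
rating A* = θ + b + ε^(A) with ε^(A) ~ N(0, σ_A²).  The second human
rater exists only to anchor the human–human QWK used by the gap rule;
it passes through no distortion.  The strict-null cell (b = 0,
σ_A = σ_H, no distortion flags) therefore makes the AI exchangeable
with a human rater, which is what justifies reading its exceedance
rates as Type I (liberality) rates.

σ_H defaults to 0.50 so that the "mid" AI error level equals the human
level; σ_A ∈ {0.40, 0.50, 0.95} for low/mid/high.  All of these are
fields of `DistortionParams` and can be overridden.

### Distortion mechanisms and their order

Distortions apply to the continuous AI scores only, in a fixed order:
compression, then imbalance, then fairness.  Compression and the
fairness offset are affine, so for flag subsets excluding imbalance
the pipeline equals the closed form (1 − λ_c)(θ + b + ε^(A)) + δ·G,
which the test suite verifies directly.  The imbalance reshaping is
rank-dependent (empirical quantiles), so its position in the order
matters and is fixed by convention.

* **Compression** multiplies by (1 − λ_c), λ_c = 0.40, shrinking scores
  toward the scale centre while preserving ranks.
* **Imbalance** shifts scores strictly below the empirical 0.40
  quantile by −0.30 and strictly above the 0.90 quantile by +0.30, and
  switches the discretization cut-points from (−0.8, −0.2, 0.2, 0.8)
  to (−1.2, −0.4, 0.4, 1.2).  The tail-shift magnitudes are package
  defaults (configurable); ±0.30 keeps the reshaping comparable in
  size to one bias step.  The wider cut-points apply to the human
  vectors as well, so all raters share one category map; see
  "Limitations" for the consequences.
* **Fairness** adds δ·G_i, δ = 0.30, to the AI score of a random
  equal-probability subgroup.  The subgroup indicator is drawn in every
  replication regardless of the flag so that toggling flags never
  shifts the random stream.

### Discretization

Categories 0–4 are assigned as the number of cut-points strictly below
the score; a value exactly on a cut-point falls in the lower category.
This is a measure-zero event under the continuous model and the
convention exists purely for bit-reproducibility.  Discretization is
monotone by construction.

## Agreement metrics

All five metrics operate on the discretized pair over the full declared
category set (default 0..4), so chance-expected terms stay stable when
categories go unobserved under imbalance.

* **ICC(A,1)** defaults to the two-way McGraw–Wong absolute-agreement
  form, (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)) with k = 2,
  which charges both random disagreement and a systematic level
  difference between the rating sources.  A one-way variant
  ((MSB − MSW)/(MSB + MSW), rater effect collapsed into the residual)
  is available via `form="oneway"`; the two coincide when the sources
  share a mean and differ under additive bias, where the two-way form
  is the standard absolute-agreement estimator and is the package
  default.
* **Krippendorff's α** is built from the 2-rater coincidence matrix;
  each unit contributes both ordered value pairs, and expected
  disagreement draws pairs without replacement from the pooled
  marginals.  The default squared distance is the squared
  category-index difference; the classic cumulative-frequency ordinal
  metric is available via `distance="ordinal_cumulative"`.  With the
  default distance, α behaves like a finite-sample-corrected ICC and
  the two track each other closely under the null, which is the regime
  the default threshold analysis assumes.
* **QWK** uses w_ij = (i − j)² on category indices and the product of
  the observed marginals for the expected table.
* **Bland–Altman** reports d̄, s_d (n − 1 denominator) and d̄ ± 1.96·s_d.
* **Tolerance agreement** is the exact proportion within k points
  (k = 1 and 2 stored).

Degenerate samples (all ratings one constant, collapsing a
denominator) return NaN rather than raising; the engine excludes NaN
flags from both the numerator and denominator of exceedance and
reports the exclusion count per condition.

## Threshold policy

Default adequacy cut-offs: ICC ≥ 0.70, α ≥ 0.80, QWK ≥ 0.70 with the
additional requirement |QWK_HA − QWK_HH| ≤ 0.10, tolerance(±1) ≥ 0.70.
All comparisons are inclusive.  The α and QWK defaults sit at the
midpoints of the sensitivity grids (α: 0.70–0.90, QWK: 0.60–0.80,
ICC: 0.60–0.80 in 0.05 steps); an alternative "textual" profile with
the conventional guideline values α ≥ 0.67 and QWK ≥ 0.60 ships as
`ThresholdPolicy.textual()`.  The grid-centred defaults are the ones
under which the package's null and operating exceedance rates are
internally consistent (a mean α near 0.74 with a single-digit
exceedance rate is only possible against a 0.80 cut-off, not 0.67).
Every threshold is a config field.

## Monte Carlo machinery

* **Seeding.** A master seed spawns one `SeedSequence([seed, index])`
  substream per condition; conditions are independent, individually
  re-runnable, and bitwise reproducible.  Substream independence and
  reproducibility are tested.
* **Aggregation.** Exceedance proportions carry Wilson 95% intervals
  (recentred point, symmetric half-width, clipped to [0, 1] and snapped
  exactly to the boundary at p̂ ∈ {0, 1}) and MCSE = √(p(1−p)/reps).
* **Storage.** Replication-level metric values persist to Parquet (CSV
  by suffix) with a JSON manifest (seed, reps, policy, params,
  version) sufficient to reproduce the run; threshold-sensitivity
  analysis re-thresholds the store without re-simulation.
* **Problem sizes.** The test suite runs reproduction cells at 1,500
  replications with tolerances max(0.02, 3·MCSE) at that count, and
  the design-wide logistic sign check at 500 replications per cell;
  `scripts/acceptance.py` uses the full 5,000.  These sizes keep the
  Monte Carlo error comfortably inside the stated tolerances.

## Logistic exceedance models

Single-metric models regress a metric's per-replication flag on sample
size (factor, reference 100), an any-bias indicator (|b| > 0 — the
design is symmetric in ±b, so a signed coding is uninformative), AI
variance level (factor, reference low) and the three distortion flags.
The composite model stacks the ICC, α and QWK flags and adds metric
main effects (reference ICC) plus metric × factor interactions.
Coefficients are maximum likelihood (statsmodels GLM/binomial) with
Wald standard errors and ±1.96·SE intervals; p-values are Holm
step-down adjusted within the table.  Factor levels absent from a
store slice drop out of the design matrix; a degenerate response or a
binary term perfectly aligned with the response raises an error naming
the term.

## Audit module

The audit consumes a long-format score table (unit, rater, human/ai
kind, optional familiarity group, score on a declared 0–70 scale).
The human reference is the per-unit mean of human scores.  Indicators:
bias = mean(AI − ref); variance ratio = SD(AI − ref) over the pooled
SD of teacher − ref residuals; slope and R² of AI on ref (slope < 1
indicates compression); per-group mean deviations d_g = AI − teacher_g.
A unit-level percentile bootstrap (B = 2,000 default) yields 95% CIs,
Pr(slope < 1) as the compression probability, and the probability that
|d_g| follows a declared strict ordering (default direct < indirect <
unfamiliar) as the fairness probability.  Resamples collapsing to a
single distinct unit are redrawn (capped and logged).  The bootstrap
uses a unit-indexed array fast path proven equal, in tests, to
materialising the resampled table.

Condition matching standardises the point bias by the pooled teacher
SD, converts to latent units via σ_H, and snaps to the nearest design
bias level; the variance ratio maps to low/mid/high at boundaries
0.75/1.10 (chosen so that sub-unit ratios around 0.85 read "mid" and
ratios above 1.1 read "high"); compression and fairness flags fire at
bootstrap probabilities ≥ 0.6 and ≥ 0.95.  The imbalance flag is never
inferred — no audit statistic formalises prevalence shift — and an
undefined variance ratio raises rather than guessing.  Percentile
intervals (not BCa) are the default as the simplest distribution-free
choice at these sample sizes.

### Fixture generator

`make_fixture` emulates the motivating audit layout: six essays, three
teachers (one per familiarity group) scoring true + group offset +
noise, and two AI systems scoring intercept + slope·true + noise, all
clipped to the 0–70 scale.  Defaults place the AI systems below the
human reference with slopes 0.50/0.67 — the compressed, negatively
biased regime the audit is designed to flag.  What the fixture does
*not* emulate: rubric-specific score granularity (scores are
continuous), rater drift over essays, or correlated teacher errors;
passing audit tests therefore demonstrate estimator and bootstrap
correctness, not robustness to those real-data features.

## Numerical conventions

* Undefined metric values are NaN, never exceptions, so batch runs
  cannot abort mid-design; exclusion counts are logged and reported.
* Wilson z defaults to 1.96 (the conventional printed value, not the
  exact 97.5% quantile 1.95996…); tests against statsmodels pass the
  exact quantile.
* Holm adjustment delegates to statsmodels' `multipletests` and is
  verified against a brute-force smallest-rejection-level oracle.
* Ratings exactly on a cut-point discretize downward (see above).

## Known limitations

* **Percentile-bootstrap undercoverage.**  At the six-unit audit
  layout, 95% percentile intervals cover the generating bias/slope in
  roughly 82–87% of fixture draws — the well-known small-n behaviour
  of percentile intervals, not an estimator defect (coverage recovers
  to ≥ 90% by ~24 units, which the tests check).  Audit CIs on
  six-essay tables should be read as approximate.
* **Imbalance and fairness effects on exceedance are
  mechanism-sensitive.**  Under this package's mechanisms, the
  imbalance flag *raises* ICC/QWK exceedance on net (the shared wider
  cut-points concentrate all raters mid-scale, which helps agreement
  more than the ±0.30 tail reshaping hurts it), and the AI-only
  fairness offset *lowers* it slightly (it adds one-sided
  disagreement).  Analyses that treat these signs as universal should
  note they flip under nearby mechanism variants (e.g. AI-only
  cut-point shifts, or subgroup offsets entering a shared component).
* The latent trait is normal and raters are drift-free; severity
  drift, halo effects and non-normal ability distributions are out of
  scope.
* Krippendorff's α here is the complete-data, two-ratings-per-unit
  case; missing data and >2 raters are not supported.
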