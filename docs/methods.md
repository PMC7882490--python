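# Methods

This note documents the statistical procedures implemented in `riskbeliefs`,
the assumptions behind them, the synthetic data they are validated on, and
the numerical choices that were genuinely open.

## The data model

One record per respondent, one or two repeated cross-sectional waves.
Belief items are bounded: four 0–100 items (believed infection fatality
ratio, own risk of catching the disease, others' perceived risk, expected
population prevalence), six 0–10 opinion scores, an expected epidemic
duration in weeks (0–52). Several items were fielded in wave 1 only
(influenza comparisons, confidence, health status, chronic illness); a
non-missing value for such an item in wave 2 is a validation error, not a
quiet missing. Missingness is an explicit state — an empty cell in files,
NaN in memory — never a sentinel inside the valid range. Post-stratification
weights are positive reals normalized to mean one within each wave.

Descriptive summaries use the n−1 standard deviation. Weighted summaries
renormalize weights over the respondents who answered the item, scaled so
the mean weight is one; with equal weights the formulas reduce *exactly* to
the unweighted ones, which the tests assert.

## Synthetic data: what it emulates and what it does not

The generator draws demographics independently from fixed per-wave margins
(the bundled defaults are the margins of the two-wave French lockdown survey
design the package was built around: 52.4 % female, seven age bands, etc. —
printed counts normalized to probabilities where they do not sum exactly to
the wave size). Each bounded item is generated as

    response = 50                with probability π₅₀   (the heap)
             = round(scale · X)  otherwise, X ~ Beta(a, b)

with `logit E[X]` equal to a per-wave intercept plus small effects of
gender, age band and incidence tier, and `a + b` the precision. Default
means/precisions are solved from the published wave-level means and standard
deviations (e.g. own risk: mean 0.345, precision 2.2 in wave 1, mean +11.5
points in wave 2; expected prevalence −11.1 points); default heap masses
mirror the measured excess-50 percentages; default missingness rates are the
published per-item missing counts over the wave sizes, missing completely at
random. Weights are computed by post-stratification on gender × age against
the configured margins, so cell-weighted margins match the targets exactly
on occupied cells.

Deliberate simplifications: items are correlated only through the shared
demographic predictor (no residual copula); missingness is MCAR, so
listwise-deletion analyses are unbiased on generated data by construction;
heaping replaces the latent draw rather than displacing nearby values; and
respondents heap only at 50 by default (the anchor is configurable). Tests
passing on this generator therefore show the *estimators* behave as
specified — they do not show that real respondents satisfy MCAR or
single-anchor heaping.

Stratum count tables are generated as diagnosed ~ Binomial(population,
prevalence) and deaths ~ Binomial(diagnosed, IFR), the model the benchmark
computation inverts.

## Benchmarks

IFR = 100·deaths/diagnosed and prevalence = 100·diagnosed/population per
stratum. With hospital-only counts these are respectively an upper and a
lower bound of the population quantities; the package computes, it does not
reinterpret. A zero-diagnosed stratum has an *undefined* IFR, carried as an
explicit flag. Cross-stratum contrasts are true odds ratios on the
proportion scale, [p/(1−p)] / [p_ref/(1−p_ref)]; at per-cent magnitudes the
odds ratio is numerically indistinguishable from the rate ratio, so nothing
downstream depends on that choice. Aggregation pools counts and recomputes
rates — never averages rates — and the tests assert the difference.

## Heaping ("50-blip")

Responses x ∈ [0, 100] are mapped to x/100 and boundary-shrunk by
x′ = (x(n−1)+0.5)/n so exact 0/100 answers keep finite likelihood; a beta
law is then fitted by maximum likelihood (method of moments available as a
flag). The default fit *includes* the 50s — the procedure fits the
distribution actually observed — with an exclude-50s flag exposed.

The excess-50 statistic is the observed share of answers in [45, 55]
(closed window; answers are integers) minus the fitted beta's probability of
producing an integer answer in that window, I(0.555; a, b) − I(0.445; a, b).
The half-cell bounds matter: evaluating the continuous window [0.45, 0.55]
instead understates the expectation by about a tenth of the window mass and
biases the excess upward by ≈ +1 point at typical item shapes.

Measured operating characteristics at the default study conditions (mean
0.345, precision 2.2, n = 1000, hundreds of generator seeds): mean excess
≈ 0 when no heap is generated; heaps of 5 and 15 points are recovered with
biases of about −0.6 and −2.1 points respectively, because the heap itself
contaminates the beta fit and inflates the expected window mass. Averaged
over the heap grid {0, 0.05, 0.15} the bias is within one percentage point.
The statistic is a *detector with a conservative bias for large heaps*, not
an unbiased estimator of the heap mass; the exclude-50s flag removes the
contamination when an unbiased estimate is wanted.

The "difference between means with and without the 50s" test is an OLS
regression of demeaned answers on the indicator 1{x = 50} with intercept,
two-sided t on the indicator — algebraically the pooled-variance two-sample
t test, an identity the tests assert numerically. Heaping analyses are
unweighted by design.

## Calibration and comparative optimism

Paired comparisons use the classical paired t test with listwise deletion
and exact sidedness; the degenerate zero-variance case (constant
differences) is defined explicitly (t = 0, two-sided p = 1 for identical
vectors) rather than left NaN. Pair classification counts higher/equal/lower
with an equality tolerance defaulting to 0 (exact equality on integer
items). The contagiousness comparison is a no-intercept regression,
slope = Σxy/Σx², SE = √(Σ(y−bx)²/(n−1))/√(Σx²), read as "belief y is b
times belief x". Stratified gaps are mean belief (0–100) minus benchmark
prevalence (per 100); the sign convention (positive = beliefs exceed the
recorded prevalence) is carried in the output.

The comparative-optimism index is (q4 − q2 + 100)/200 — the unique affine
map sending a difference of −100 to 0, 0 to 0.5 and +100 to 1. By linearity
the index mean is an affine function of the mean difference and the paired t
against 0.5 is identical to the paired t on the raw difference; both are
asserted. The between-wave contrast is the wave-indicator test in a
quasibinomial logit GLM of the index (indicator-only model by default,
unweighted by default, both configurable).

## Regression

Quasibinomial logit GLM: mean logit⁻¹(Xβ), variance φ·μ(1−μ). Rescaled
slider responses are continuous proportions, which quasi-likelihood accepts;
exact 0/1 outcomes are admitted. The fit is IRLS (statsmodels GLM, Binomial
family) with post-stratification weights as variance weights, convergence
tolerance 1e-8, 100 iterations max; non-convergence is flagged, and a fitted
linear predictor exceeding 30 in magnitude flags suspected separation.
Dispersion is Pearson χ²/(n−p). The default covariance is the
heteroscedasticity-robust sandwich (HC1), mirroring design-based survey
inference; a model-based option (Pearson-scaled) exists. Reference levels
are the first-declared codebook category of each term. Listwise deletion
over the model variables.

Average marginal effects: for a categorical level, the (weighted) average
over records of p̂(level) − p̂(reference) holding all other covariates at
observed values; for a numeric term, the average derivative β·μ(1−μ).
Standard errors by the delta method with a central-difference Jacobian
(step 1e-6) against the coefficient covariance; p-values are two-sided
normal. The suite checks the fit against an independent hand-rolled IRLS
solver to 1e-6, the binary-covariate AME against its closed form, and the
delta-method SE against a 200-resample bootstrap within 20 %.

## Pipeline and problem sizes

`run_pipeline` executes the stages in dependency order, derives a named
substream of the run seed per stage (so toggling stages never reseeds the
others), writes every table as commented CSV, and records all operative
choices in a JSON report; identical config and seed give byte-identical
outputs, asserted in the tests. The test suite and the acceptance script use
two-wave samples of 1000–1005 respondents per wave — the design's own scale —
and 100–200 generator seeds for Monte-Carlo recovery checks; the full suite
runs in well under a minute.

## Known limitations

- The excess-50 statistic understates large heaps under the default
  include-the-50s fit (see above).
- The generator cannot produce non-MCAR missingness or inter-item residual
  correlation, so those robustness questions are out of reach of this test
  bed.
- Benchmark tables are consumed as given; no data acquisition is included.
- The GLM covers single-level models only; no ordinal or multilevel
  structure for the confidence items, which enter as plain covariates.
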