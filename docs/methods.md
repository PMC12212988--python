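# Methods

## The model and the two hypotheses

Adult fertility outcomes are treated as a smooth function of two
environment summaries: the developmental environment `e0` (experienced in
the first year of life) and the magnitude of the development/adulthood
mismatch `|Δe| = |e1 − e0|`.  A second-order expansion of that function
gives the quadratic regression

y₁ = γ + γ₀·e0 + γd·|Δe| + γ₀₀·e0² + γdd·|Δe|² + γ₀d·e0·|Δe| + u,

which is flexible enough to represent diminishing returns and asymmetric
curvature while remaining linear in parameters.  The adult environment `e1`
is deliberately not a regressor: it is generated by `e0 + Δe = e1` and so
carries no independent information once `e0` and `|Δe|` are in the model.

The developmental-constraints (DC) hypothesis predicts a positive marginal
effect of the developmental environment, ∂y₁/∂e0 = γ₀ + 2γ₀₀·e0 + γ₀d·|Δe| > 0;
the adaptive-response (AR) hypothesis predicts a negative marginal effect
of mismatch, ∂y₁/∂|Δe| = γd + 2γdd·|Δe| + γ₀d·e0 < 0.  Both derivatives are
evaluated by default at the sample means of `e0` and `|Δe|`, with
delta-method standard errors from the cluster-robust coefficient
covariance and two-sided p-values from a t distribution with G − 1 degrees
of freedom (G = number of females).  A result is "consistent with theory"
when the estimate has the predicted sign *and* clears the chosen α
(default 0.05); the two conditions are reported separately so one-sided
reasoning stays explicit.

## Risk sets, windows and exclusions

Each outcome conditions its denominator on eligibility:

* conception — female-months in which the female was cycling on the first
  day of the month (months beginning in pregnancy or postpartum amenorrhea
  are out of the risk set);
* live birth — completed pregnancies (in-progress pregnancies are censored
  and dropped);
* infant survival — live births, outcome 1 iff the infant reached 70 weeks
  (the average weaning age).  Infants younger than 70 weeks at the end of
  data collection are censored; records where the mother died before her
  infant are excluded because early maternal loss dominates infant fate.

All time windows are half-open `[start, end)` on calendar dates, and the
"first year of life" is `[birth, birth + 12 calendar months)`.  Rainfall
windows sum daily depths and divide by the number of window months (12),
never by days/30, so leap spans change nothing; a day missing from the
gauge series is a coverage error unless missing days are explicitly
configured to count as zero.  Rank windows are gap-tolerant means of
available months: the developmental rank is the mother's mean rank over
{birth month − 1, birth month, birth month + 1}, and adult rank windows
follow the outcome (3-month window around the cycling month; pregnancy
months; the 12 months before the infant's death/70-week anchor).  Records
with unobtainable environments or covariates are dropped — never imputed —
and every drop carries a machine-readable reason code (censored-pregnancy,
censored-infant, maternal-death, missing-development-environment,
missing-adult-environment, missing-covariate).

Covariates are age at the outcome anchor (years, with a squared term) and
mean daily group size over the outcome-appropriate span.  Parity and
prior-infant status are deliberately excluded from conception models: they
are plausibly downstream of the environments under test, and conditioning
on them could mask the effects of interest.

## Estimation and inference

The binary outcomes are fitted by least squares (a linear probability
model), so coefficients and marginal effects live directly on the
probability scale; a logistic variant of the generator exists for
misspecification experiments.  Fixed effects (social group, or female
identity for the within-individual AR comparison) are absorbed by the
within transformation; an explicit dummy encoding is also implemented and
agrees with demeaning to 1e-8, which the tests check.  Under the individual
fixed effect the development-only terms `e0` and `e0²` are absorbed and
flagged not-estimable — DC is simply untestable within females, because
each female has one developmental environment — while the interaction
`e0·|Δe|` survives and keeps the AR derivative estimable.

The covariance estimator is the one-way cluster-robust (CR1) sandwich with
clusters = females and the small-sample factor G/(G−1)·(N−1)/(N−K), K
counting slope and absorbed fixed-effect parameters.  Rank-deficient
columns are eliminated by pivoted QR and reported by name.  Numerical
guards: a bread matrix with condition number above 1e12 raises instead of
silently inverting; a zero-variance nonzero estimate raises a degenerate
variance error; an exactly-zero estimate with zero variance reports p = 1.

## Effect translation and percentile contrasts

Marginal effects are translated into percentile contrasts: predicted
outcomes at the 10th vs 90th empirical percentile of one variable, holding
everything else at sample means.  The relative difference is the
good-minus-adverse gap as a percentage of the mean outcome, and the
absolute difference rescales it to percentage points
(absolute = relative × baseline / 100; e.g. 13.18% of a 73.74% baseline is
9.72 points).  Because the exact construction of an "X% more likely to
fail" statement is ambiguous, the contrast object also reports the gap
relative to the mean *failure* rate; both numbers are emitted rather than
choosing silently.

## The asymmetry test

Whether rises and falls in the environment act symmetrically is tested by
refitting with sign-split mismatch terms Δ⁺ = max(Δ, 0) and Δ⁻ = max(−Δ, 0),
each entering linearly and squared (the interaction keeps `|Δe|`), followed
by a joint 2-df cluster-robust Wald test that the positive and negative
coefficients coincide pairwise.  This construction is the package's own
reconstruction of an under-specified procedure and is recorded in the
result object.  Simulation shows the joint Wald statistic holds its size at
around 200 clusters but over-rejects with few clusters (≈0.10 at 40
females) — the familiar few-cluster inflation of multi-restriction
cluster-robust Wald tests — so the size property is verified at 200
females and the caveat applies to small samples.

## Multiple testing

One full run produces 18 derivative tests (three outcomes × two
environments × [DC under group FE + AR under both FE specs]); that family
is adjusted with sharpened two-stage FDR q-values.  Stage one runs a
step-up pass at q′ = q/(1+q); the number of stage-one rejections estimates
the count of true nulls m̂₀ = m − r₁; stage two re-runs the step-up at
q′·m/m̂₀.  A test's q-value is the smallest level on the grid
{0.001, 0.002, …} at which the two-stage procedure rejects it (1 if never),
matching the 3-decimal precision q-values are conventionally reported at.
Sharpening means a q-value can undercut its p-value when many tests in the
family look non-null.  The family membership is explicit in configuration
rather than hard-coded.

## The synthetic generator

`simulate_panel` draws `e0` once per female — Uniform(0, 1) for rank-like
environments (the proportional-rank scale), log-normal with mean 28.8
mm/month and log-sd 0.45 for rainfall-like environments (a right-skewed
positive shape matching the observed mean; the shape itself is a modelling
choice) — and `e1` per observation through a Gaussian copula with target
Pearson correlation ρ (default 0.71, the observed rank e0/e1 correlation;
for the uniform marginal the latent correlation is adjusted to
2·sin(πρ/6) so the Pearson target is hit on the rank scale).  Outcomes add
female and group random intercepts and Gaussian noise to the quadratic
surface and pass through one of three links: Bernoulli with a clipped
linear probability (default for fertility-like panels; a warning fires if
more than 20% of latent values leave [0, 1]), Bernoulli-logistic, or a
continuous Gaussian outcome for power and recovery studies where the
generative model is exactly the fitted regression.  Coefficients apply to
empirically z-scored environment columns by default ("0.5 per sd of e0"),
with a raw-scale mode for recovery checks.  Default panel dimensions mirror
the conception analysis: 295 females with 20–36 observations each, mean
outcome 0.137.

What the generator does *not* emulate: mechanistic demography (group
fissions, matriline overthrows, rank trajectories), seasonal autocorrelation
between a female's successive adult windows, age-dependent environment
effects, and selective disappearance.  Passing tests therefore demonstrate
the statistical machinery — estimator correctness, test calibration,
sensitivity in known-effect regimes — not the substantive ecology of any
real population.

`simulate_raw_records` additionally generates the four raw input tables
(daily seasonal rainfall, bounded-random-walk monthly ranks with ~2%
missing months, a monthly reproductive state machine, group census) so the
panel-builder path can be exercised end to end; it plants no environment
effect on fertility, making it a null world in which any significant
derivative test is a false positive.

## Simulation studies and problem sizes

The shipped study regimes, chosen once:

* sensitivity — 300 females × 10 observations, coefficient ±0.5 per sd on
  the tested variable, all other environment coefficients zero, Gaussian
  noise sd 0.5, female/group intercept sds 0.1/0.05; 200 replicates; DC is
  tested under the group fixed effect, AR under the individual fixed
  effect; a replicate counts as a detection when the two-sided p < 0.05
  *and* the sign matches the prediction.  Both tests detect in ≈100% of
  replicates in this regime.
* size — the binary null preset (intercept 0.3, environment coefficients
  zero) at 150 females × 8–12 observations, 1000 replicates, rejection by
  two-sided p < 0.05 alone.  Both tests land near the nominal 0.05.
* recovery — 200 females × 10 observations (n = 2000) with known raw-scale
  coefficients and Gaussian noise sd 0.3; estimates fall within 3
  cluster-robust SEs of truth in ≥95% of replicates.

Replicate r of a study reseeds the generator with base seed + r, so studies
are reproducible bit for bit; identical configuration and seed give
byte-identical panels and, downstream, byte-identical result CSVs.

## Known limitations

* The linear probability model can predict outside [0, 1]; marginal effects
  at the sample means are well-behaved in the regimes studied, but extreme
  evaluation points inherit LPM artifacts.
* CR1 with t(G−1) is one defensible small-sample convention among several;
  with very few clusters (tens of females) both the derivative tests and
  especially the 2-df asymmetry Wald over-reject.
* Gap-tolerant rank windows assume missingness is unrelated to rank, and
  calendar-month boundaries are used for pregnancy-duration rank means.
* The sharpened q-value grid resolves to 0.001; q-values are exact with
  respect to that grid, not continuous.
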