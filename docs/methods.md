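# Methods

This note documents the statistical models behind `synthtte`, the defaults
they ship with, the numerical choices made where the design was open, and
what the synthetic-data generator does and does not emulate.

## Synthetic IPD reconstruction (`sipd`)

**Baselines.** Each arm's baseline covariates (age in years, BMI in kg/m²,
weight in kg, HbA1c in %) are drawn from a multivariate normal defined by
the reported means, SDs, and (optional) correlation matrix. The sample is
then *exactly re-colored*: centered, whitened by the Cholesky factor of
the sample covariance, re-colored by the Cholesky factor of the target
covariance, and shifted to the target means. This makes the sample
moments match the targets exactly for any arm size n > d (d = number of
covariates), which matters because a naive draw at n ≈ 10–20 has sampling
error ~1/√n ≈ 0.25 in each correlation — far outside the 0.05 fidelity
tolerance. Biological plausibility bounds (BMI > 18 kg/m², HbA1c > 4.0 %,
age ≥ 18 y) are then enforced by a clip-and-re-color loop (≤ 25
iterations); because the bounds typically sit ≳ 3 SD from the mean, clip
events are rare and the final moments stay well inside tolerance. A
target mean more than 3 SD below a bound raises a feasibility error.

**Trajectories.** Visit-wise outcomes are built from a latent AR(1)
process (adjacent-visit correlation ρ = 0.7 by default, configurable)
standardized per visit, scaled by the per-visit SD implied by the
reported standard error (SD = SE·√n), and added to the reported visit
mean. Visit-level sample means and SEs are therefore exact; serial
correlation is positive by construction. ρ = 0.7 reflects the strong
tracking of within-patient weight change across adjacent visits seen in
obesity pharmacotherapy trials; no published value constrains it.

**Responders.** The round-half-even of n·rate patients with the largest
final losses are flagged at each threshold, so counts are exact integers
and ladders nest across thresholds by construction (a ≥ 10 % responder is
always a ≥ 5 % responder). Published responder rates are event counts
over n, so the fidelity tolerance of 0.3 pp is met exactly when rates are
expressible as k/n — the fixture generator emits such rates.

**Adverse events and dropout.** Event times follow piecewise-constant
hazards solved in closed form against target cumulative incidence:
λₖ = (Hₖ − Hₖ₋₁)/Δₖ with H = −log(1 − F). Dropout keeps the fraction
exact — a uniformly random subset of size round(n·rate) is truncated at
times drawn from the calibrated hazard conditioned on occurrence before
end of follow-up.

**Seeding.** One master seed; each (arm, purpose) pair gets an
independent stream derived by hashing, so arms are reproducible in
isolation and distinct seeds give distinct cohorts.

**Fidelity tolerances** (defaults, all configurable): means 0.1 units
absolute, SDs 10 % relative, responder rates 0.3 pp, pairwise
correlations 0.05, mean-trajectory R² > 0.95. "Means within 0.1" is
interpreted as absolute percentage points, the reading consistent with
how endpoint fidelity is conventionally reported.

## Dose-response (`doseresp`)

Efficacy uses the Emax model E(d) = Emax·dʰ/(ED50ʰ + dʰ), fit by weighted
nonlinear least squares (weights ∝ arm n) with the Hill coefficient fixed
at 1 by default; `hill_mode="estimated"` frees it, and AIC in `fit_stats`
supports the comparison. ED50 is parameterized on the log scale for
stability. Wald CIs use the Gauss-Newton covariance with t critical
values at the residual degrees of freedom. The lack-of-fit statistic is a
pure-error F-test against the saturated dose-means model and is defined
only when dose levels are replicated (NaN otherwise). ED-quantiles use
the closed form EDₚ = ED50·(p/(100−p))^{1/h}; with h = 1, ED80 = 4·ED50
and ED90 = 9·ED50 exactly.

Tolerability endpoints are modelled as
logit P(AE|d) = logit(p₀) + Emax_tol·d/(ED50_tol + d), fit by penalized
binomial likelihood with weakly-informative penalties
Emax_tol ~ N(0, 2.5), log ED50_tol ~ N(log 10, 1), and a diffuse N(0, 10²)
on the baseline log-odds. The deterministic penalized fit is the default
so results are exactly reproducible; passing a seed adds draws from the
Laplace (normal) approximation at the mode for interval summaries. MCMC
convergence diagnostics (R-hat, ESS) are reported as `None` in this mode.
Degenerate arm proportions (0 or 1) get the continuity correction
(x + ½)/(n + 1) before logit transformation; a strict mode raises
instead.

The benefit-risk frontier evaluates all three fitted curves on a common
dose grid (default 0–60 mg in 0.1 mg steps). Gate crossings
(discontinuation ≤ 20 %, GI-AE ≤ 75 % by default) are found by Brent
root-finding on the fitted curves; the therapeutic window runs from the
dose achieving 80 % of Emax (configurable fraction) to the tightest
crossing, flagged when no gate is crossed on the grid. Which efficacy
parameterization feeds the lower bound (the pooled ED50 or a
transportability-reweighted one) is a user choice via the `EmaxFit`
passed in.

## Evidence synthesis (`synthesis`)

Indirect contrasts of placebo-anchored effects use Δ = ETD_a − ETD_b,
SE = √(se_a² + se_b²) (independent trials), normal-theory CI/z/p,
P(superiority) = Φ(|Δ|/SE), and Φ((m − Δ)/SE) for a non-inferiority
margin m with lower-is-better outcomes. Active-active SEs always use the
independent-sum rule; published tables sometimes imply other conventions,
and standardizing on one rule keeps contrasts mutually consistent.
Cohen's d divides by a user-supplied pooled SD.

SUCRA_k = 100·Σ_{j<K} cumP_k(j)/(K−1); a treatment certain to hold rank r
scores 100·(K−r)/(K−1), and the mean across treatments is 50 % for any
rank matrix arising from a distribution over rankings.

DerSimonian-Laird heterogeneity uses inverse-variance weights:
Q = Σw(y−ȳ)², C = Σw − Σw²/Σw, τ² = max(0, (Q−df)/C),
I² = max(0, (Q−df)/Q). On the logit scale the within-arm variance is
1/(n·p·(1−p)). τ² CIs use the Q-profile method (inverting the
generalized Q against χ² quantiles); the Biggerstaff-Tweedie alternative
is surfaced in the API but not implemented, as it needs the τ̂² sampling
distribution and no authoritative parameterization was available. I² CIs
translate the τ² bounds through the typical within-study variance.

MAP predictive intervals are the maximum-a-posteriori plug-in of the
pooled logit mean and τ² into a normal predictive:
mean ± z·√(se² + τ²) on the logit scale, inverse-logit back to
proportions, which produces the characteristic asymmetry (longer upper
arm below p = 0.5). At τ² = 0 the interval reduces to the pooled CI.

Transport weights re-calibrate a source cohort to a target population:
w_i ∝ exp(−½·d_M(x_i, target)²) under the target covariance, normalized
to mean 1 within each arm. E-values use RR + √(RR(RR−1)), inverting
protective ratios first.

## Kinetics (`kinetics`)

The plateau model W(t) = W∞(1−e^{−kt}) is fit by nonlinear least squares
on loss magnitudes with log-parameterized k; it is scale-equivariant in
W∞. Time-to-threshold inverts it in closed form. Velocity is the finite
difference of visit means per adjacent interval; a plateau is declared at
the first interval with |velocity| < 0.05 pp/week (a simple changepoint
surrogate — a Bayesian changepoint model is out of scope for lack of any
constraining values). Time-to-response uses the product-limit estimator
via lifelines with dropout as right-censoring; the default event time is
the first *scheduled* visit at/after crossing, with linear interpolation
behind a flag (published fractional medians such as 9.2 weeks imply
interpolation was used at the source). The reported median is the first
time survival drops to ≤ 0.5. Log-rank tests use the lifelines
multivariate statistic; pairwise Bonferroni adjustment reports
α/C(k,2) — 0.05/6 ≈ 0.0083 for four groups. Competing risks use the
Aalen-Johansen estimator restricted to two event types.

Published plateau parameters are not always self-consistent (a printed
rate constant and a printed time-to-threshold can disagree with the
closed form); the package therefore treats the model form as the
contract and asserts only internally consistent quantities.

## Trial simulation (`trialsim`)

Power uses the z-approximation: 1−β = Φ(|Δ|/SE − z_{1−α/2}) with
SE = sd·√(2/n); at the n ≥ 500 scale of confirmatory obesity trials the
z-vs-t difference is < 0.001. Non-inferiority shifts by the margin at
one-sided level α/2; equivalence uses TOST. ANCOVA covariate adjustment
is represented as a variance deflation √(1−ρ²) on sd. Where a published
SE at one n is available, `sd_from_se` back-solves the implied sd rather
than assuming one.

Group-sequential boundaries use error spending with the Lan-DeMets
O'Brien-Fleming-type function f(t) = 2(1 − Φ(z_{1−α'/2}/√t)) per side
(α' = α/2), chosen because it reproduces the two-look (0.5, 1.0)
boundaries 2.96/1.97 that anchor the design contract (classic OBF would
give 2.80/1.98). Boundaries are solved look-by-look by propagating the
continuation density of the canonical sequential z-process
(Cov(Z_i,Z_j) = √(t_i/t_j)) on a 4001-point grid over ±8 with trapezoid
convolution and Brent root-finding; the partial grid cell at each cut is
handled by interpolation. Expected sample size is the definitional
Σ n_k·P(stop at k). Sample-size re-estimation solves the normal power
equation at the interim estimate (sd implied by the interim SE at the
planned size), floored at the planned n and capped at the inflation
limit (default 2×).

Retention is exponential with weekly hazard −ln(1−annual)/52, anchoring
retention(52 weeks) = 1 − annual exactly; extra components (early
termination, protocol deviation) add on the hazard scale.

Virtual head-to-head simulation draws per-patient normal outcomes,
applies a Welch z-test per replicate (two-sided superiority or one-sided
non-inferiority), and reports the empirical rejection rate with its
binomial Monte-Carlo SE. Dropout removes patients completely at random
before analysis.

## Validation (`validation`)

Leave-trial-out holds out one arm at a time (whole-trial holdout behind a
flag), refits the supplied model callback, and regresses **observed on
predicted**: slope < 1 means under-prediction of magnitudes and 1/slope
is the recommended inflation for prediction-based sample-size
calculations. Failing folds are flagged and excluded rather than
aborting. PPC reports the fraction of observations inside per-observation
5th–95th predictive bands against a nominal 0.90. SBC records the rank
of each prior draw among its posterior draws and tests uniformity with a
KS test on midpoint-corrected ranks (r + ½)/(L + 1), pass level p > 0.15
by default.

## The synthetic-data generator and what passing tests show

`aggdata.generate_fixture` emulates the *structure* of a multi-trial
development program: placebo plus ascending active doses (1–60 mg),
arm sizes 10–2,500, 3–12 visits, saturating mean-loss trajectories
(generative Emax 22 pp, ED50 3 mg, plateau rate 0.06/week, placebo drift
−2 pp), monotone responder ladders at 5/10/15 pp expressed as exact
count fractions, GI-AE and discontinuation rates rising in dose from
realistic backgrounds, and well-conditioned random baseline correlation
matrices. It does **not** emulate: reporting errors and rounding
inconsistencies of real publications, non-monotone printed trajectories,
missing-not-at-random dropout, between-visit outcome distributions that
are non-normal, or covariate distributions with skew (weight and BMI are
mildly right-skewed in reality). Fidelity tests passing on fixtures
therefore demonstrate that the reconstruction machinery hits its
tolerances when the aggregates are internally consistent; they do not
certify behaviour on contradictory source tables, which the validators
are designed to flag rather than repair.

## Problem sizes used in the shipped checks

Fidelity is exercised over 20 generator seeds × 6 arms (arm sizes up to
2,500); Monte-Carlo calibration uses 2,000 replicates per design point on
a 12-point (effect, sd, n) grid; SBC uses 50 master seeds × 100 runs ×
100 draws on a conjugate normal toy; parameter-recovery uses 200 noisy
Emax replicates. These sizes give binomial/Monte-Carlo error comfortably
inside the asserted tolerances while keeping the default suite quick to
run.

## Known limitations

* Gaussian copula only for baselines; no skewed or heavy-tailed marginals.
* The tolerability "posterior" is a Laplace approximation around the
  penalized mode, not MCMC; tail quantiles of strongly skewed posteriors
  will differ.
* No network-meta-analysis likelihood: contrasts are pairwise
  placebo-anchored, and loop-inconsistency diagnostics are out of scope.
* No futility (beta-spending) boundaries or multi-arm multi-stage
  designs.
* Dropout reasons and pattern-mixture sensitivity analyses are not
  modelled.
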