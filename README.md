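# synthtte — synthetic target-trial emulation from aggregate trial data

`synthtte` is a toolkit for biostatisticians planning confirmatory trials
of anti-obesity and glycemic pharmacotherapy (amylin-pathway agents,
GLP-1 combinations) from *published, arm-level* evidence only. When no
individual patient data (IPD) are available, it:

1. **reconstructs synthetic IPD** from arm-level aggregates (baseline
   means/SDs/correlations, visit-wise outcome summaries, responder
   ladders, adverse-event and discontinuation proportions), under
   biological plausibility constraints, and verifies fidelity against the
   source summaries;
2. **fits dose-response models** — efficacy Emax
   `E(d) = Emax·dʰ/(ED50ʰ + dʰ)` and tolerability logit-Emax
   `logit P(AE|d) = logit(p₀) + Emax_tol·d/(ED50_tol + d)` — with
   ED-quantiles `EDₚ = ED50·(p/(100−p))^{1/h}` and benefit-risk frontiers
   gated at discontinuation ≤ 20 % and GI-AE ≤ 75 %;
3. **synthesizes evidence across trials**: placebo-anchored indirect
   contrasts, SUCRA rankings, DerSimonian-Laird heterogeneity (τ², I²) on
   the logit scale with proper within-arm variance 1/(n·p·(1−p)), and
   meta-analytic-predictive (MAP) intervals for future-trial outcomes;
4. **models longitudinal kinetics**: exponential-plateau trajectories
   `W(t) = W∞(1−e^{−kt})`, velocity profiles, Kaplan-Meier time-to-response,
   log-rank tests, competing risks, number needed to harm;
5. **simulates trial designs**: closed-form and Monte-Carlo power for
   superiority/non-inferiority/equivalence, Lan-DeMets error-spending
   group-sequential boundaries, sample-size re-estimation, completion
   curves, and replicate-based virtual head-to-head comparisons;
6. **validates predictions**: leave-trial-out calibration (slope,
   intercept, RMSE, inflation factor 1/slope), posterior predictive
   checks, and simulation-based calibration.

## Worked example

```python
import numpy as np
from synthtte import *
from synthtte.doseresp import emax_curve

# 1) reconstruct a synthetic cohort for one published arm and verify it
table = generate_fixture(FixtureConfig(n_trials=2, arms_per_trial=3,
                                       n_range=(50, 500), seed=42))
arm = table.arms[1]
cohort = generate_cohort(arm, seed=42)
report = validate_fidelity(cohort, arm)
print("fidelity rows:", len(report.rows), "all passed:", report.passed)

# 2) efficacy dose-response and ED-quantiles
d = np.array([1.25, 5, 20, 60])          # mg
fit = fit_emax(d, emax_curve(d, 24.66, 2.22))
print("Emax %.2f  ED50 %.2f  ED80 %.2f mg  ED90 %.2f mg"
      % (fit.emax, fit.ed50, ed_quantile(fit, 80), ed_quantile(fit, 90)))

# 3) placebo-anchored indirect comparison of two trials
a = EffectEstimate("combo_obesity", -17.3, 0.33, n=2108)
b = EffectEstimate("semaglutide", -11.9, 0.86, n=302)
r = indirect_contrast(a, b)
print("contrast %.1f pp  95%% CI (%.1f, %.1f)  p=%.2g"
      % (r.difference, *r.ci95, r.p_value))

# 4) two-look group-sequential efficacy boundaries
g = gsd_boundaries(alpha=0.05, info_fractions=(0.5, 1.0))
print("GSD boundaries:", [round(z, 2) for z in g.z_boundaries])
```

which prints:

```
fidelity rows: 24 all passed: True
Emax 24.66  ED50 2.22  ED80 8.88 mg  ED90 19.98 mg
contrast -5.4 pp  95% CI (-7.2, -3.6)  p=4.6e-09
GSD boundaries: [2.96, 1.97]
```

The fidelity report confirms the 437-patient synthetic cohort matches its
source aggregates on every checked quantity (baseline means within 0.1
units, SDs within 10 % relative, pairwise correlations within 0.05,
visit means within 0.1 pp, responder rates within 0.3 pp). The Emax fit
recovers the dose-response from arm-level means: a dose of 8.88 mg
achieves 80 % of the maximal effect and 19.98 mg achieves 90 % (under a
hyperbolic model these are exactly 4× and 9× the ED50). The indirect
contrast says the combination arm outperforms semaglutide monotherapy by
5.4 percentage points of weight loss with CI excluding zero, and the
O'Brien-Fleming-type boundaries require z ≥ 2.96 at the halfway interim
but only z ≥ 1.97 at the final analysis.

## Command line

```sh
synthtte data fixture --seed 1 --out table.csv   # synthetic aggregate table
synthtte data validate table.csv                 # schema + invariant checks
synthtte sipd --in table.csv --seed 1 --report fidelity.json
synthtte run --config run.yaml                   # full pipeline + manifest
```

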