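# jointcox

Joint models versus Cox regression when the predictor is longitudinal and
noisy: a simulation laboratory, from-scratch estimators, and a
coverage/bias evaluation harness for biostatisticians studying
time-to-event outcomes with time-dependent predictors.

## The problem

In follow-up studies — the motivating case is transition to psychosis in
ultra-high-risk patients assessed monthly — the outcome is a time to
event and a key predictor is measured repeatedly with error.  The
conventional analyses put the observed values straight into Cox
regression:

* **baseline-value Cox** uses only the day-0 measurement;
* **LOCF Cox** treats the predictor as time-dependent, carrying the last
  observation forward across the counting-process risk sets.

Both see `y(t) = m(t) + ε` instead of the latent value `m(t)`, so their
estimates of the predictor effect are attenuated.  The **shared
random-effects joint model** fixes this by modelling the two components
together:

    y_i(t) = m_i(t) + ε_i(t),   m_i(t) = β₀ + β₁ t + b₀ᵢ + b₁ᵢ t,
    (b₀, b₁) ~ N(0, D),  ε ~ N(0, σ²)

    h_i(t) = h₀(t) · exp( γ uᵢ + α m_i(t) )

with `h₀` Weibull or piecewise-constant, and the random effects
integrated out of the likelihood by pseudo-adaptive Gauss–Hermite
quadrature.  The package provides a data generator whose daily hazard is
log-linear in the latent trajectory (`h_i(t) = exp(λ₀ + λ₁ m_i(t) + τ uᵢ)`
on days 0–364), the three estimator families implemented from scratch,
and a study runner that measures 95%-CI coverage and the percentage of
estimates below the truth across replicate grids.  A period-record
pipeline applies every estimator to transition-to-psychosis-style cohort
tables (family history as group, HAMD depression score as the
time-dependent predictor).

## Worked example

One simulated replicate of the canonical scenario (monotone visits,
measurement-error variance 16, true `λ₁ = −0.03`, `τ = 0`):

```python
import jointcox as jc
from jointcox.joint import JointSpec

ds = jc.simulate_dataset(jc.get_scenario(1, seed=42), 0)

cox_b = jc.fit_cox(jc.build_baseline_table(ds))
cox_t = jc.fit_cox(jc.build_locf_table(ds))
joint = jc.fit_joint(ds, JointSpec(baseline="weibull"))
```

prints (via `examples/cox_attenuation.py` and
`examples/joint_model_fit.py`):

```
 baseline-value Cox: lambda1 = -0.0282 (se 0.0155, 95% CI -0.0585 to +0.0022)
           LOCF Cox: lambda1 = -0.0434 (se 0.0113, 95% CI -0.0656 to -0.0212)
   weibull baseline: alpha   = -0.0412 (se 0.0125, CI -0.0657 to -0.0167)
```

All three target the same effect (truth −0.030).  On this replicate the
baseline-value CI brushes zero; across 100 replicates the study runner
quantifies the systematic picture — the Cox estimates center above the
truth (attenuation), while the joint model is approximately unbiased with
near-nominal coverage:

```python
summary, replicates = jc.run_study([1], ("cox_baseline", "cox_locf",
                                         "joint_weibull"), replicates=100,
                                   seed=1)
```

The `examples/` directory has one short script per capability
(simulation, Cox attenuation, joint fitting, the coverage study, the
cohort-table pipeline), and the same workflow is scriptable from a shell
via the thin `jointcox simulate | fit | evaluate` CLI.

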