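"""Fit the shared-random-effects joint model to one simulated replicate.

The joint model links the hazard to the latent current value m(t) of the
longitudinal process and integrates over each subject's random intercept
and slope by pseudo-adaptive Gauss-Hermite quadrature, removing the
measurement-error attenuation that biases the Cox analyses.
"""

import jointcox as jc
from jointcox.joint import JointSpec

ds = jc.simulate_dataset(jc.get_scenario(1, seed=42), 0)

for baseline in ("weibull", "piecewise_constant"):
    fit = jc.fit_joint(ds, JointSpec(baseline=baseline))
    lo, hi = fit.ci_alpha()
    print(f"{baseline:>18s} baseline: "
          f"alpha = {fit.alpha:+.4f} (se {fit.se_alpha:.4f}, "
          f"CI {lo:+.4f} to {hi:+.4f}), gamma = {fit.gamma:+.3f}, "
          f"loglik = {fit.loglik:.1f}, "
          f"{'converged' if fit.converged else 'NOT converged'}")

fit = jc.fit_joint(ds, JointSpec())
p = fit.params
print(f"\nlongitudinal submodel: beta = ({p.beta[0]:.2f}, {p.beta[1]:.4f}) "
      f"[truth (40, 0.02)], sigma2 = {p.sigma2:.1f} [truth 16]")
print(f"random-effects variances: Var(b0) = {p.D[0, 0]:.1f} [32], "
      f"Var(b1) = {p.D[1, 1]:.4f} [0.002]")
print("\nalpha estimates the effect of the latent predictor value on the "
      "log hazard (truth -0.03); compare with the attenuated Cox estimates "
      "from cox_attenuation.py on the same replicate.")
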