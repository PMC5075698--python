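"""Joint model: likelihood oracles, quadrature behaviour, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import jointcox as jc
from jointcox.joint import (
    JointParams,
    JointSpec,
    PiecewiseBaseline,
    WeibullBaseline,
    _initial_params,
    _Problem,
    conditional_survival_loglik,
    fit_joint,
    subject_marginal_loglik,
    total_marginal_loglik,
)
from jointcox.lmm import fit_lmm

D_FORM_A = np.array([[32.0, 0.06], [0.06, 0.002]])


def _params(alpha=-0.03, gamma=0.0, baseline=None, sigma2=16.0):
    return JointParams(
        beta=np.array([40.0, 0.02]), sigma2=sigma2, D=D_FORM_A.copy(),
        alpha=alpha, gamma=gamma,
        baseline=baseline or WeibullBaseline(shape=1.0, log_scale=-6.0),
    )


class TestConditionalSurvival:
    def test_exponential_collapse(self):
        # alpha=0 and Weibull shape 1: plain exponential with rate
        # exp(log_scale + gamma*u)
        p = _params(alpha=0.0, gamma=-0.5,
                    baseline=WeibullBaseline(shape=1.0, log_scale=-5.0))
        for T, delta, u in [(120.0, 1, 0), (300.0, 0, 1)]:
            rate = np.exp(-5.0 - 0.5 * u)
            expected = delta * np.log(rate) - rate * T
            got = conditional_survival_loglik(p, T, delta, u, (0.0, 0.0))
            assert got == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("baseline", [
        PiecewiseBaseline(knots=np.array([]), log_hazards=np.array([-5.5])),
        PiecewiseBaseline(knots=np.array([60.0, 200.0]),
                          log_hazards=np.array([-5.0, -5.8, -6.4])),
        WeibullBaseline(shape=1.4, log_scale=-8.0),
    ])
    def test_matches_adaptive_quadrature(self, baseline):
        p = _params(alpha=-0.03, gamma=0.3, baseline=baseline)
        b = (2.0, 0.01)
        T, u = 250.0, 1

        def hazard(s):
            if isinstance(baseline, WeibullBaseline):
                h0 = np.exp(baseline.log_scale) * baseline.shape * s ** (
                    baseline.shape - 1)
            else:
                h0 = np.exp(baseline.log_hazards[int(baseline.interval_of(s))])
            m = p.beta[0] + p.beta[1] * s + b[0] + b[1] * s
            return h0 * np.exp(p.gamma * u + p.alpha * m)

        cum = 0.0
        edges = [0.0, 60.0, 200.0, T] if not isinstance(
            baseline, WeibullBaseline) else [0.0, T]
        for a, c in zip(edges[:-1], edges[1:]):
            cum += integrate.quad(hazard, a, c, epsabs=1e-13, epsrel=1e-12)[0]
        expected = np.log(hazard(T)) - cum
        got = conditional_survival_loglik(p, T, 1, u, b)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_cumulative_hazard_matches_daily_generator_sum(self):
        # the continuous integral vs the simulator's day-by-day hazard sum
        sc = jc.SimScenario()
        p = _params(baseline=PiecewiseBaseline(
            knots=np.array([]), log_hazards=np.array([-4.8])))
        T = 120.0
        cum_cont = -conditional_survival_loglik(p, T, 0, 0, (0.0, 0.0))
        cum_daily = sum(jc.daily_hazard(sc, 0.0, 0.0, 0, t) for t in range(120))
        assert cum_cont == pytest.approx(cum_daily, rel=0.01)


class TestMarginalLikelihood:
    def test_vectorized_total_equals_per_subject_sum(self, small_dataset):
        long_df = small_dataset.to_longitudinal_frame()
        surv_df = small_dataset.to_survival_frame()
        lmm = fit_lmm(long_df)
        p = _params()
        spec = JointSpec()
        total = total_marginal_loglik(long_df, surv_df, p, spec, lmm=lmm)
        surv = surv_df.sort_values("subject_id").reset_index(drop=True)
        acc = 0.0
        for i, rec in surv.iterrows():
            g = long_df[long_df.subject_id == rec.subject_id]
            acc += subject_marginal_loglik(
                p, g.day.to_numpy(), g.value.to_numpy(),
                rec.time, int(rec.status), int(rec.group), spec,
                center=(lmm.eb_modes_[i], lmm.eb_covs_[i]))
        assert total == pytest.approx(acc, abs=1e-7)

    def test_factorizes_at_zero_association(self, small_dataset):
        # with alpha=0 the joint likelihood is the LMM marginal likelihood
        # plus a fixed-covariate survival likelihood, exactly
        long_df = small_dataset.to_longitudinal_frame()
        surv_df = small_dataset.to_survival_frame()
        lmm = fit_lmm(long_df)
        base = WeibullBaseline(shape=1.2, log_scale=-7.0)
        p = JointParams(beta=lmm.beta, sigma2=lmm.sigma2_hat, D=lmm.D_hat,
                        alpha=0.0, gamma=0.4, baseline=base)
        joint_ll = total_marginal_loglik(long_df, surv_df, p, JointSpec(),
                                         lmm=lmm)
        surv_ll = 0.0
        for rec in surv_df.itertuples(index=False):
            logh0 = base.log_scale + np.log(base.shape) \
                + (base.shape - 1) * np.log(rec.time)
            H0 = np.exp(base.log_scale) * rec.time ** base.shape
            surv_ll += rec.status * (logh0 + p.gamma * rec.group) \
                - H0 * np.exp(p.gamma * rec.group)
        assert joint_ll == pytest.approx(lmm.loglik + surv_ll, abs=1e-6)

    @pytest.mark.parametrize("gh_hi,tol", [(15, 1e-3), (25, 1e-4)])
    def test_quadrature_convergence(self, small_dataset, gh_hi, tol):
        # the pseudo-adaptive rule centers nodes on the longitudinal
        # posterior, so convergence is assessed at parameters consistent
        # with that centering (as during an actual fit)
        long_df = small_dataset.to_longitudinal_frame()
        surv_df = small_dataset.to_survival_frame()
        lmm = fit_lmm(long_df)
        p = JointParams(beta=lmm.beta, sigma2=lmm.sigma2_hat, D=lmm.D_hat,
                        alpha=-0.03, gamma=0.2,
                        baseline=WeibullBaseline(shape=1.0, log_scale=-6.0))
        ll9 = total_marginal_loglik(long_df, surv_df, p,
                                    JointSpec(gh_points=9), lmm=lmm)
        ll_hi = total_marginal_loglik(long_df, surv_df, p,
                                      JointSpec(gh_points=gh_hi), lmm=lmm)
        assert abs(ll9 - ll_hi) <= tol

    def test_no_visit_subject_matches_monte_carlo_integration(self, rng):
        # the marginal reduces to the prior-integrated survival likelihood
        p = _params(alpha=-0.03)
        T, delta, u = 150.0, 1, 0
        got = subject_marginal_loglik(p, [], [], T, delta, u, JointSpec())
        b = rng.multivariate_normal([0, 0], p.D, size=400_000)
        c0 = p.alpha * (p.beta[0] + b[:, 0])
        d = p.alpha * (p.beta[1] + b[:, 1])
        rate0 = np.exp(p.baseline.log_scale)
        # closed form for shape-1 Weibull: int_0^T r0 e^{c0+ds} ds
        x = d * T
        cum = rate0 * np.exp(c0) * T * np.where(
            np.abs(x) < 1e-8, 1 + x / 2, np.expm1(x) / np.where(x == 0, 1, x))
        logh = np.log(rate0) + c0 + d * T
        ll = delta * logh - cum
        mc = np.log(np.mean(np.exp(ll)))
        assert got == pytest.approx(mc, abs=0.01)


class TestGradientAndFit:
    @pytest.mark.parametrize("baseline", ["weibull", "piecewise_constant"])
    def test_analytic_gradient_matches_numerical(self, small_dataset, baseline):
        long_df = small_dataset.to_longitudinal_frame()
        surv_df = small_dataset.to_survival_frame()
        lmm = fit_lmm(long_df)
        spec = JointSpec(baseline=baseline)
        pr = _Problem(long_df, surv_df, spec, lmm)
        th = pr.pack(_initial_params(pr, long_df, surv_df, lmm, spec))
        th += 0.02 * np.random.default_rng(1).standard_normal(len(th))
        _, g = pr.negloglik_grad(th)
        for j in range(len(th)):
            e = np.zeros_like(th)
            e[j] = 1e-6
            gn = (pr.negloglik(th + e) - pr.negloglik(th - e)) / 2e-6
            assert g[j] == pytest.approx(gn, rel=1e-4, abs=1e-5)

    def test_loglik_invariant_to_subject_relabeling(self, small_dataset):
        # with fixed quadrature centering the likelihood must not depend on
        # id labels or row order
        long_df = small_dataset.to_longitudinal_frame()
        surv_df = small_dataset.to_survival_frame()
        lmm = fit_lmm(long_df)
        ids = sorted(surv_df.subject_id.unique())
        remap = dict(zip(ids, reversed(ids)))
        long_r = long_df.assign(subject_id=long_df.subject_id.map(remap)) \
            .sample(frac=1.0, random_state=0)
        surv_r = surv_df.assign(subject_id=surv_df.subject_id.map(remap)) \
            .sample(frac=1.0, random_state=1)
        p = _params()
        spec = JointSpec(pseudo_adaptive=False)
        ll1 = total_marginal_loglik(long_df, surv_df, p, spec, lmm=lmm)
        ll2 = total_marginal_loglik(long_r, surv_r, p, spec, lmm=lmm)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_zero_association_data_gives_null_alpha(self):
        sc = jc.SimScenario(lambda1=0.0, lambda0=-6.0, seed=31, set_id=90)
        ds = jc.simulate_dataset(sc, 0)
        fit = fit_joint(ds, JointSpec())
        assert fit.converged
        assert abs(fit.alpha) < 2.5 * fit.se_alpha
        lmm = fit_lmm(ds.to_longitudinal_frame())
        assert fit.params.beta == pytest.approx(lmm.beta, abs=0.5)
        assert fit.params.sigma2 == pytest.approx(lmm.sigma2_hat, rel=0.1)

    def test_piecewise_fit_recovers_association_sign(self, set1_dataset):
        fit = fit_joint(set1_dataset, JointSpec(baseline="piecewise_constant"))
        assert fit.converged
        assert np.isfinite(fit.se_alpha) and fit.se_alpha > 0
        assert np.isfinite(fit.loglik)
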