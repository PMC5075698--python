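"""Generator checks: trajectories, hazards, event law, observation rules."""

import numpy as np
import pytest
from scipy import stats as sps

import jointcox as jc
from jointcox.scenarios import COV_FORMS
from jointcox.simulate import _draw_event_times_vec


class TestTrajectoryAndHazard:
    @pytest.mark.parametrize(
        "a0,a1,b0,b1,t,expected",
        [(40, 0.02, 0, 0, 0, 40.0), (40, 0.1, 0, 0, 100, 50.0),
         (40, 0.02, -2, 0.01, 50, 39.5)],
    )
    def test_linear_evaluation(self, a0, a1, b0, b1, t, expected):
        sc = jc.SimScenario(a0=a0, a1=a1)
        assert jc.true_trajectory(sc, b0, b1, t) == pytest.approx(expected)

    def test_outside_horizon_raises(self):
        sc = jc.SimScenario()
        with pytest.raises(ValueError):
            jc.true_trajectory(sc, 0, 0, 365)

    def test_hazard_log_linear(self):
        sc = jc.SimScenario(a0=40, a1=0.0, lambda0=-4.8, lambda1=-0.03, tau=-0.5)
        assert jc.daily_hazard(sc, 0, 0, 0, 10) == pytest.approx(np.exp(-6.0))
        assert jc.daily_hazard(sc, 0, 0, 1, 10) == pytest.approx(np.exp(-6.5))

    def test_constant_hazard_degenerate(self):
        sc = jc.SimScenario(lambda1=0.0, tau=0.0, lambda0=-5.0)
        h = [jc.daily_hazard(sc, b0, b1, g, t)
             for b0, b1, g, t in [(0, 0, 0, 0), (3, 0.1, 1, 200)]]
        assert np.allclose(h, np.exp(-5.0))


class TestRandomEffects:
    @pytest.mark.parametrize("form,rho", [("a", 0.237), ("d", 0.032)])
    def test_sample_correlation_matches_form(self, form, rho, rng):
        b = jc.draw_random_effects(COV_FORMS[form], 100_000, rng)
        assert np.corrcoef(b.T)[0, 1] == pytest.approx(rho, abs=0.01)
        assert b.mean(axis=0) == pytest.approx([0, 0], abs=0.05)

    def test_zero_covariance_independent(self, rng):
        cov = jc.RandomEffectsCov(4.0, 0.01, 0.0)
        b = jc.draw_random_effects(cov, 100_000, rng)
        assert abs(np.corrcoef(b.T)[0, 1]) < 0.01

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            jc.RandomEffectsCov(1.0, 1.0, 1.5)


class TestEventTimes:
    def test_constant_hazard_collapses_to_exponential(self, rng):
        # with no random effects and flat trajectory the scheme is Exp(h)
        sc = jc.SimScenario(a0=40, a1=0.0, lambda0=-1.8, lambda1=0.0)
        h = np.exp(-1.8)
        t = np.array([jc.draw_event_time(sc, 0, 0, 0, rng) for _ in range(4000)])
        assert np.all(t != None)  # noqa: E711  (events certain at this rate)
        assert t.astype(float).mean() == pytest.approx(1 / h, rel=0.05)
        ks = sps.kstest(t.astype(float), "expon", args=(0, 1 / h))
        assert ks.pvalue > 0.01

    def test_degenerate_scenario_ks_exponential(self, rng):
        # zero random-effect variance and flat slope: marginal law is
        # Exponential(exp(lambda0 + lambda1*a0)) for events inside the horizon
        sc = jc.SimScenario(
            a0=40, a1=0.0, lambda0=-3.0, lambda1=-0.03,
            cov=jc.RandomEffectsCov(1e-12, 1e-12, 0.0),
        )
        rate = np.exp(-3.0 - 0.03 * 40)
        b = np.zeros((10_000, 2))
        t = _draw_event_times_vec(sc, b, np.zeros(10_000, dtype=int), rng)
        t = t[np.isfinite(t)]
        trunc = 1 - np.exp(-rate * 365)
        cdf = lambda x: (1 - np.exp(-rate * x)) / trunc
        assert sps.kstest(t, cdf).pvalue > 0.01

    def test_effectively_no_events_at_tiny_hazard(self, rng):
        sc = jc.SimScenario(lambda0=-30.0)
        assert jc.draw_event_time(sc, 0.0, 0.0, 0, rng) is None

    def test_marginal_survival_matches_monte_carlo_oracle(self, rng):
        # empirical S(k) vs E_b[exp(-sum_{t<k} h(t))] by direct integration
        sc = jc.get_scenario(1, seed=5)
        n = 40_000
        b = jc.draw_random_effects(sc.cov, n, rng)
        g = np.zeros(n, dtype=int)
        T = _draw_event_times_vec(sc, b, g, rng)
        b2 = jc.draw_random_effects(sc.cov, n, rng)
        days = np.arange(365)
        m = sc.a0 + sc.a1 * days + b2[:, :1] + b2[:, 1:] * days
        h = np.exp(sc.lambda0 + sc.lambda1 * m)
        cumh = np.cumsum(h, axis=1)
        for k in (30, 120, 364):
            emp = (T > k).mean()
            s_b = np.exp(-cumh[:, k - 1])
            oracle = s_b.mean()
            mc_se = np.sqrt(emp * (1 - emp) / n + s_b.var() / n)
            assert abs(emp - oracle) < 3 * mc_se


class TestCensoringAndObservation:
    def test_censoring_uniform(self, rng):
        c = jc.draw_censoring_monotone(rng, size=100_000)
        assert c.min() >= 1 and c.max() <= 364
        assert c.mean() == pytest.approx(182.5, abs=1.5)
        assert np.mean(c <= 182.5) == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("time,expected_days",
                             [(95, [0, 30, 60, 90]), (15, [0])])
    def test_monotone_visit_grid(self, time, expected_days, rng):
        sc = jc.SimScenario()
        rec = jc.observe_monotone(sc, 1, 0, 0.0, 0.0, time, 1, rng)
        assert rec.visit_days == expected_days

    def test_noiseless_observation_equals_trajectory(self, rng):
        sc = jc.SimScenario(error_var=0.0**2 + 1e-24)
        rec = jc.observe_monotone(sc, 1, 0, 2.0, 0.01, 200, 0, rng)
        expected = [jc.true_trajectory(sc, 2.0, 0.01, d) for d in rec.visit_days]
        assert rec.visit_values == pytest.approx(expected, abs=1e-9)

    def test_nonmonotone_all_missing_censors_at_baseline(self):
        sc = jc.SimScenario()
        # find a stream whose missing-subset size comes out as 12
        for s in range(200):
            rng = np.random.default_rng(s)
            rec = jc.observe_nonmonotone(sc, 1, 0, 0.0, 0.0, np.inf, rng)
            if rec.event_time == 0.0:
                assert rec.status == 0
                assert rec.visit_days == [0.0]
                return
        pytest.fail("never drew a fully-missing subject")

    def test_nonmonotone_full_schedule_censors_at_last_visit(self):
        sc = jc.SimScenario()
        for s in range(400):
            rng = np.random.default_rng(s)
            rec = jc.observe_nonmonotone(sc, 1, 0, 0.0, 0.0, np.inf, rng)
            if len(rec.visits) == 13:
                assert rec.status == 0
                assert rec.event_time == rec.visit_days[-1]
                assert abs(rec.visit_days[-1] - 360) <= 7
                return
        pytest.fail("never drew a fully-observed subject")

    def test_nonmonotone_event_truncates_visits(self, rng):
        sc = jc.SimScenario()
        rec = jc.observe_nonmonotone(sc, 1, 0, 0.0, 0.0, 100.0, rng)
        if rec.status == 1:
            assert rec.event_time == 100.0
            assert all(d < 100.0 for d in rec.visit_days)
        else:  # all occasions after day 100 were missing
            assert rec.event_time < 100.0

    def test_nonmonotone_visit_count_conservation(self):
        sc = jc.SimScenario()
        rng = np.random.default_rng(0)
        for _ in range(50):
            rec = jc.observe_nonmonotone(sc, 1, 0, 0.0, 0.0, np.inf, rng)
            assert 1 <= len(rec.visits) <= 13
            days = np.array(rec.visit_days[1:])
            # jittered days stay inside their windows and keep order
            assert np.all(np.diff(rec.visit_days) > 0)
            if len(days):
                nearest = 30 * np.round(days / 30)
                assert np.all(np.abs(days - nearest) <= 7)


class TestDatasetAndGrid:
    def test_grid_shape_and_numbering(self):
        grid = jc.scenario_grid()
        assert len(grid) == 36
        s1 = grid[0]
        assert (s1.missingness, s1.error_var, s1.a1) == ("monotone", 16.0, 0.02)
        assert s1.cov == COV_FORMS["a"]
        s23 = grid[22]
        assert (s23.missingness, s23.error_var, s23.a1) == ("nonmonotone", 16.0, 0.1)
        assert s23.cov == COV_FORMS["c"]
        for set_id, base in zip((33, 34, 35, 36), (3, 7, 19, 23)):
            clone, orig = grid[set_id - 1], grid[base - 1]
            assert clone.tau == -0.5
            assert (clone.cov, clone.a1, clone.error_var, clone.missingness) == \
                (orig.cov, orig.a1, orig.error_var, orig.missingness)

    def test_simulate_deterministic(self, set1_scenario):
        d1 = jc.simulate_dataset(set1_scenario, 3)
        d2 = jc.simulate_dataset(set1_scenario, 3)
        assert d1.to_longitudinal_frame().equals(d2.to_longitudinal_frame())
        assert d1.to_survival_frame().equals(d2.to_survival_frame())
        d3 = jc.simulate_dataset(set1_scenario, 4)
        assert not d1.to_survival_frame().equals(d3.to_survival_frame())

    def test_dataset_invariants(self, set1_dataset):
        ds = set1_dataset
        surv = ds.to_survival_frame()
        assert len(ds.subjects) == 300
        assert surv.group.value_counts().tolist() == [150, 150]
        assert 0 < surv.status.sum() < 300
        for rec in ds.subjects:
            assert rec.visit_days[0] == 0
            if rec.status == 1:
                assert rec.visit_days[-1] < rec.event_time

    def test_negative_group_effect_reduces_events(self):
        sc = jc.SimScenario(tau=-0.5, n_per_group=5000, seed=8, set_id=99)
        ds = jc.simulate_dataset(sc, 0)
        surv = ds.to_survival_frame()
        frac = surv.groupby("group")["status"].mean()
        assert frac[1] < frac[0]
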