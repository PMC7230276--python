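"""Kaplan-Meier, trend log-rank and Cox regression against independent oracles."""

import numpy as np
import pytest

import hfscore as h


def random_survival_data(seed, n=40, p_event=0.6, tied=False):
    rng = np.random.default_rng(seed)
    if tied:
        time = rng.integers(1, 8, size=n).astype(float)
    else:
        time = rng.permutation(np.arange(1.0, n + 1.0))
    event = rng.random(n) < p_event
    x = rng.normal(size=n)
    return time, event, x


class TestKaplanMeier:
    def test_hand_computed_four_record_fixture(self):
        """times {1+, 2, 3+, 4}: at t=2 three are at risk, one event -> S(2)=2/3."""
        curve = h.km_estimate([1, 2, 3, 4], [False, True, False, True])
        assert curve.survival_at(2) == pytest.approx(2 / 3)
        assert curve.survival_at(1.5) == 1.0
        assert curve.survival_at(4) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        time = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        curve = h.km_estimate(time, np.ones(5, dtype=bool))
        for t in time:
            assert curve.survival_at(t) == pytest.approx((time > t).mean())

    def test_all_censored_is_identically_one(self):
        curve = h.km_estimate([5.0, 8.0, 2.0], [False, False, False])
        assert curve.survival_at(100.0) == 1.0

    def test_never_increases(self):
        time, event, _ = random_survival_data(0, tied=True)
        curve = h.km_estimate(time, event)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        time, event, _ = random_survival_data(5, tied=True)
        curve = h.km_estimate(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )

    def test_nonpositive_times_rejected(self):
        with pytest.raises(h.ValidationError):
            h.km_estimate([0.0, 1.0], [True, True])


class TestTrendLogrank:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_two_groups_reduce_to_standard_logrank(self, seed):
        from lifelines.statistics import logrank_test

        time, event, _ = random_survival_data(seed, n=50, tied=True)
        group = np.random.default_rng(seed + 100).integers(0, 2, size=50)
        res = h.trend_logrank(time, event, group.astype(float))
        ll = logrank_test(time[group == 0], time[group == 1],
                          event[group == 0], event[group == 1])
        assert res.statistic == pytest.approx(ll.test_statistic, abs=1e-8)
        assert res.p == pytest.approx(ll.p_value, abs=1e-10)

    def test_identical_patterns_give_null_result(self):
        """Three groups with byte-identical event/censor patterns: U = 0, p = 1."""
        time = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        event = np.tile([True, False, True, True], 3)
        scores = np.repeat([0.0, 1.0, 2.0], 4)
        res = h.trend_logrank(time, event, scores)
        assert res.u == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_affine_invariance_of_group_scores(self):
        time, event, _ = random_survival_data(7, n=60, tied=True)
        scores = np.random.default_rng(8).integers(0, 3, size=60).astype(float)
        base = h.trend_logrank(time, event, scores)
        shifted = h.trend_logrank(time, event, 10.0 - 4.0 * scores)
        assert shifted.statistic == pytest.approx(base.statistic, abs=1e-10)

    def test_ordered_hazards_detected(self):
        """Strongly increasing hazard across three strata -> tiny p."""
        rng = np.random.default_rng(9)
        scores = np.repeat([0.0, 1.0, 2.0], 50)
        rate = np.exp(1.5 * scores) / 100.0
        time = np.ceil(rng.exponential(1.0 / rate))
        event = time < 50
        time = np.minimum(time, 50.0)
        assert h.trend_logrank(time, event, scores).p < 1e-4

    def test_hfs_strata_trend_detected_at_study_scale(self):
        """Default synthetic cohort (n=214, ~9% events, HR 1.16/point):
        the three ordered HFS strata show a strong dose-response."""
        from hfscore.report import strata_scores

        cohort = h.simulate_cohort(h.CohortSpec(), seed=500)
        res = h.trend_logrank(
            cohort["time_days"], cohort["event"], strata_scores(cohort)
        )
        assert res.p < 1e-4

    def test_constant_scores_rejected(self):
        with pytest.raises(h.ValidationError):
            h.trend_logrank([1.0, 2.0], [True, True], [1.0, 1.0])


def partial_loglik_oracle(beta, time, event, x):
    """Explicit Breslow partial log-likelihood, coded independently."""
    ll = 0.0
    for i in np.where(event)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_six_subject_fixture_matches_grid_search(self):
        """Newton-Raphson maximiser vs a 1e-4 grid over the explicit likelihood."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([True, True, False, True, False, True])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [partial_loglik_oracle(b, time, event, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        fit = h.cox_fit(time, event, x)
        assert abs(fit.coefficients[0].estimate - beta_grid) < 1e-4

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_score_test_equals_logrank_on_binary_covariate(self, seed):
        """Known identity: the Cox score test at beta=0 is the log-rank test
        (exact in the absence of ties)."""
        from lifelines.statistics import logrank_test

        time, event, _ = random_survival_data(seed, n=30, tied=False)
        group = np.random.default_rng(seed).integers(0, 2, size=30)
        res = h.cox_score_test(time, event, group.astype(float))
        ll = logrank_test(time[group == 0], time[group == 1],
                          event[group == 0], event[group == 1])
        assert res.statistic == pytest.approx(ll.test_statistic, abs=1e-8)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    @pytest.mark.parametrize("seed", [21, 22])
    def test_matches_statsmodels_on_tied_data(self, ties, seed):
        from statsmodels.duration.hazard_regression import PHReg

        time, event, x = random_survival_data(seed, n=60, tied=True)
        x2 = np.random.default_rng(seed + 1).normal(size=60)
        X = np.column_stack([x, x2])
        ref = PHReg(time, X, status=event.astype(int), ties=ties).fit()
        fit = h.cox_fit(time, event, X, ties=ties)
        for j in range(2):
            assert fit.coefficients[j].estimate == pytest.approx(
                ref.params[j], abs=1e-6
            )
            assert fit.coefficients[j].se == pytest.approx(ref.bse[j], rel=1e-4)

    def test_translation_invariance(self):
        time, event, x = random_survival_data(31, n=50, tied=True)
        b1 = h.cox_fit(time, event, x).coefficients[0]
        b2 = h.cox_fit(time, event, x + 100.0).coefficients[0]
        assert b2.estimate == pytest.approx(b1.estimate, abs=1e-8)
        assert b2.se == pytest.approx(b1.se, abs=1e-8)

    def test_hr_ci_brackets_hr(self):
        time, event, x = random_survival_data(32, n=50, tied=True)
        c = h.cox_fit(time, event, x).coefficients[0]
        assert c.ci_low < c.hr < c.ci_high
        assert c.hr > 0

    def test_constant_covariate_rejected(self):
        with pytest.raises(h.ValidationError, match="constant"):
            h.cox_fit([1.0, 2.0, 3.0], [True, True, False], [1.0, 1.0, 1.0])

    def test_no_events_rejected(self):
        with pytest.raises(h.ValidationError, match="no events"):
            h.cox_fit([1.0, 2.0], [False, False], [0.0, 1.0])

    def test_collinear_covariates_singular(self):
        time, event, x = random_survival_data(33, n=30, tied=False)
        with pytest.raises(h.ValidationError, match="singular"):
            h.cox_fit(time, event, np.column_stack([x, 2.0 * x]))

    def test_complete_separation_flagged(self):
        """All events in the high-covariate group before any other event:
        monotone likelihood, capped estimate, converged=False."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([True, True, True, True])
        x = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="monotone"):
            fit = h.cox_fit(time, event, x)
        assert not fit.converged
        assert np.isfinite(fit.coefficients[0].estimate)


class TestReplacedMultiple:
    def test_independent_adjuster_leaves_primary_stable(self):
        cohort = h.simulate_cohort(h.CohortSpec(), seed=44)
        time = cohort["time_days"].to_numpy()
        event = cohort["event"].to_numpy()
        x = cohort["hfs"].to_numpy() - 100.0
        noise = np.random.default_rng(45).normal(size=len(cohort))
        simple = h.cox_fit(time, event, x, names=["hfs"])["hfs"]
        table = h.replaced_multiple(time, event, x, {"noise": noise})
        adjusted_hr = table.loc["noise", "hr"]
        assert simple.ci_low < adjusted_hr < simple.ci_high

    def test_duplicate_of_primary_is_singular(self):
        cohort = h.simulate_cohort(h.CohortSpec(), seed=46)
        x = cohort["hfs"].to_numpy() - 100.0
        with pytest.raises(h.ValidationError, match="singular"):
            h.replaced_multiple(
                cohort["time_days"].to_numpy(),
                cohort["event"].to_numpy(),
                x,
                {"copy": x.copy()},
            )
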