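import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from pairsig.datamodel import DomainError, SurvivalData
from pairsig.survival import (BreslowWorkspace, SeparationError, adjust_fwer,
                              cox_fit, km_estimate, logrank_chi2_many,
                              logrank_test)
from conftest import make_exponential_surv


def _surv(times, events, label="OS"):
    return SurvivalData([f"s{i}" for i in range(len(times))], times, events, label)


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_estimate(_surv([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_curve_median_not_reached(self):
        km = km_estimate(_surv([1, 2, 3], [0, 0, 0]))
        assert km.event_times.size == 0
        assert not km.median_reached
        assert km.survival_at(10.0) == 1.0

    def test_six_subject_hand_computed_product_limit(self, toy_surv6):
        # by hand: S(1)=5/6; at t=3 risk set 4, 2 events -> 5/6*1/2=5/12;
        # at t=5 risk set 1 -> 0; median = 3 (first time S <= 0.5)
        km = km_estimate(toy_surv6)
        np.testing.assert_array_equal(km.event_times, [1, 3, 5])
        np.testing.assert_allclose(km.survival, [5 / 6, 5 / 12, 0.0])
        np.testing.assert_array_equal(km.n_at_risk, [6, 4, 1])
        assert km.median_time == 3.0

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 200)
        km = km_estimate(_surv(t, np.ones(200, int)))
        for u in km.event_times:
            assert km.survival_at(u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            km_estimate(_surv([], []))


class TestLogRank:
    def test_exchangeable_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        res = logrank_test(_surv(times, events), [0, 0, 0, 0, 1, 1, 1, 1])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_matches_direct_summation_oracle(self):
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.ones(6, int)
        groups = np.array([0, 0, 0, 1, 1, 1])
        # brute force: loop over event times, O-E and hypergeometric variance
        o1 = e1 = v = 0.0
        for t in times:
            at = times >= t
            n, n1 = at.sum(), (at & (groups == 1)).sum()
            d = 1
            o1 += (groups[times == t] == 1).sum()
            e1 += d * n1 / n
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0
        expected = (o1 - e1) ** 2 / v
        res = logrank_test(_surv(times, events), groups)
        assert res.chi2 == pytest.approx(expected, rel=1e-12)
        assert res.df == 1

    def test_invariant_to_relabeling_and_time_shift(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        g = rng.integers(0, 2, 60)
        base = logrank_test(_surv(t, e), g)
        relabeled = logrank_test(_surv(t, e), 1 - g)
        shifted = logrank_test(_surv(t + 100.0, e), g)
        assert relabeled.chi2 == pytest.approx(base.chi2, rel=1e-10)
        assert shifted.chi2 == pytest.approx(base.chi2, rel=1e-10)

    def test_three_group_test_has_two_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 90)
        res = logrank_test(_surv(t, np.ones(90, int)), np.repeat([0, 1, 2], 30))
        assert res.df == 2
        assert 0 <= res.p_value <= 1

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 80)
        e = rng.integers(0, 2, 80)
        e[:5] = 1
        g = rng.integers(0, 3, 80)
        mine = logrank_test(_surv(t, e), g)
        theirs = multivariate_logrank_test(t, g, e)
        assert mine.chi2 == pytest.approx(theirs.test_statistic, rel=1e-8)

    def test_vectorized_two_group_agrees_with_scalar(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 50)
        e = rng.integers(0, 2, 50)
        e[:3] = 1
        G = rng.integers(0, 2, size=(20, 50))
        chi2s, ps = logrank_chi2_many(t, e, G)
        for i in range(20):
            if len(np.unique(G[i])) < 2:
                continue
            ref = logrank_test(_surv(t, e), G[i])
            assert chi2s[i] == pytest.approx(ref.chi2, rel=1e-10, abs=1e-12)

    def test_permutation_null_p_values_are_uniform(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 100)
        e = (rng.random(100) < 0.7).astype(int)
        G = (rng.random((300, 100)) < 0.5).astype(int)
        _, ps = logrank_chi2_many(t, e, G)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_group_and_zero_events_rejected(self):
        with pytest.raises(DomainError):
            logrank_test(_surv([1, 2], [1, 1]), [0, 0])
        with pytest.raises(DomainError):
            logrank_test(_surv([1, 2], [0, 0]), [0, 1])


def _direct_partial_loglik(beta, x, time, event):
    """Independent Breslow partial likelihood by explicit risk-set loops."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = dead.sum()
        ll += beta * x[dead].sum() - d * np.log(np.exp(beta * x[at_risk]).sum())
    return ll


class TestCoxFit:
    def test_toy_fit_matches_grid_search_of_partial_likelihood(self):
        x = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0], float)
        time = np.array([2.0, 1, 5, 3, 4, 8, 2.5, 9, 1.5, 7])
        event = np.array([1, 1, 1, 1, 0, 1, 1, 0, 1, 1])
        surv = _surv(time, event)
        res = cox_fit(x, surv)
        oracle = minimize_scalar(
            lambda b: -_direct_partial_loglik(b, x, time, event),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert res.beta[0] == pytest.approx(oracle.x, abs=1e-6)

    def test_score_vanishes_at_optimum(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(150, 3))
        surv = make_exponential_surv(rng, 150, 0.1 * np.exp(X @ [0.5, 0, -0.5]), 30)
        res = cox_fit(X, surv)
        ws = BreslowWorkspace(surv.time, surv.event)
        score = ws.grad_beta(X, X @ res.beta)
        assert np.max(np.abs(score)) < 1e-8

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 2))
        surv = make_exponential_surv(rng, 60, 0.1, 30)
        ws = BreslowWorkspace(surv.time, surv.event)
        beta = np.array([0.3, -0.7])
        grad = ws.grad_beta(X, X @ beta)
        h = 1e-6
        for j in range(2):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += h
            bm[j] -= h
            fd = (ws.loglik(X @ bp) - ws.loglik(X @ bm)) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-5)

    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=2000)
        surv = make_exponential_surv(rng, 2000, 0.1, 30)
        res = cox_fit(x, surv)
        assert abs(res.beta[0]) < 0.1
        assert res.ci_low[0] < 1.0 < res.ci_high[0]

    def test_true_hazard_ratio_two_recovered(self):
        rng = np.random.default_rng(14)
        x = (rng.random(2000) < 0.5).astype(float)
        surv = make_exponential_surv(rng, 2000, 0.05 * 2.0 ** x, 45)
        assert 0.25 < 1 - surv.event.mean() < 0.45   # ~30% censoring regime
        res = cox_fit(x, surv)
        assert 1.8 <= res.hr[0] <= 2.2

    def test_matches_lifelines_on_multivariate_data(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(15)
        X = rng.normal(size=(200, 4))
        surv = make_exponential_surv(rng, 200, 0.08 * np.exp(X @ [0.6, -0.4, 0, 0.2]), 40)
        res = cox_fit(X, surv)
        df = pd.DataFrame(X, columns=res.names)
        df["T"], df["E"] = surv.time, surv.event
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(res.beta, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(res.se, ref.standard_errors_.values, atol=1e-5)

    def test_complete_separation_raises_advice(self):
        time = np.linspace(1, 10, 20)
        event = np.ones(20, int)
        x = (time > 5).astype(float)   # early deaths all in one group
        with pytest.raises(SeparationError, match="penalized"):
            cox_fit(x, _surv(time, event))

    def test_constant_covariate_rejected(self):
        with pytest.raises(DomainError, match="constant"):
            cox_fit(np.ones(10), _surv(np.arange(1, 11.0), np.ones(10, int)))


class TestAdjustFwer:
    def test_bonferroni_scales_by_family_size(self):
        p = np.full(31, 0.5)
        p[0] = 0.001
        adj = adjust_fwer(p, "bonferroni")
        assert adj[0] == pytest.approx(0.031)

    def test_single_test_is_identity(self):
        assert adjust_fwer([0.04], "holm")[0] == pytest.approx(0.04)

    def test_holm_step_down_hand_computed(self):
        np.testing.assert_allclose(adjust_fwer([0.01, 0.04], "holm"), [0.02, 0.04])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(16)
        p = rng.random(50)
        for method in ("holm", "bonferroni"):
            assert (adjust_fwer(p, method) >= p - 1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(DomainError):
            adjust_fwer([0.5, 1.2])
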