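"""Survival primitives against brute-force oracles and lifelines /
scikit-survival as independent reference implementations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as ll_concordance
from statsmodels.stats.multitest import multipletests

from prognae import survival as sv
from prognae.errors import ValidationError


def brute_force_cindex(risk, time, event):
    """Exhaustive pair enumeration of Harrell's C (test-side oracle)."""
    conc = comp = 0.0
    n = len(risk)
    for i, j in itertools.combinations(range(n), 2):
        if time[i] == time[j]:
            continue
        lo, hi = (i, j) if time[i] < time[j] else (j, i)
        if event[lo] != 1:
            continue
        comp += 1
        if risk[lo] > risk[hi]:
            conc += 1
        elif risk[lo] == risk[hi]:
            conc += 0.5
    return conc, comp


class TestCoxUnivariate:
    def test_constant_covariate_gives_zero_and_p1(self, rng, survival_factory):
        time, event = survival_factory(rng, 20)
        fit = sv.cox_univariate(np.ones(20), time, event)
        assert fit.coefficient == 0.0 and fit.p_value == 1.0

    def test_two_sample_closed_form(self):
        # times (1, 2), both events, x = (1, 0).  Partial likelihood
        # L = e^b/(e^b+1) * 1; dlogL/db = 1 - e^b/(e^b+1) > 0 for all b:
        # the likelihood is monotone, so the coefficient must be capped.
        with pytest.warns(UserWarning, match="monotone"):
            fit = sv.cox_univariate([1.0, 0.0], [1.0, 2.0], [1, 1])
        assert fit.coefficient == pytest.approx(sv._COEF_CAP)

    def test_two_sample_finite_mle_matches_hand_derivation(self):
        # times (1,1.5,2,3), all events, x=(1,0,0,1); risk sets
        # {1,2,3,4},{2,3,4},{3,4},{4} give the hand-written score
        # U(b) = [1 - 2e^b/(2e^b+2)] - e^b/(e^b+2) - e^b/(e^b+1) + 0
        from scipy.optimize import brentq
        def U(b):
            e = np.exp(b)
            return (1 - 2 * e / (2 * e + 2)) - e / (e + 2) - e / (e + 1)
        expected = brentq(U, -10, 10)
        fit = sv.cox_univariate([1.0, 0.0, 0.0, 1.0], [1, 1.5, 2, 3], [1, 1, 1, 1])
        assert fit.coefficient == pytest.approx(expected, abs=1e-6)

    def test_matches_lifelines_on_continuous_data(self, rng, survival_factory):
        import pandas as pd
        x = rng.normal(size=120)
        time, event = survival_factory(rng, 120, hr_group=(x > 0).astype(int))
        fit = sv.cox_univariate(x, time, event)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "t": time, "e": event}), "t", "e")
        assert fit.coefficient == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_parameter_recovery_log_hr_one(self, rng):
        errs = []
        for _ in range(30):
            x = rng.normal(size=300)
            t_event = rng.exponential(np.exp(-x))
            c = rng.exponential(2.0, size=300)
            time, event = np.minimum(t_event, c), (t_event <= c).astype(int)
            errs.append(sv.cox_univariate(x, time, event).coefficient - 1.0)
        assert abs(np.mean(errs)) < 0.1

    def test_screen_matches_single_feature_score_test(self, rng, survival_factory):
        X = rng.normal(size=(5, 60))
        time, event = survival_factory(rng, 60)
        chi2, p = sv.cox_score_screen(X, time, event)
        for i in range(5):
            fit = sv.cox_univariate(X[i], time, event)
            assert chi2[i] == pytest.approx(fit.score_statistic, rel=1e-10)
            assert p[i] == pytest.approx(fit.p_value, rel=1e-10)

    def test_score_invariant_to_positive_scaling(self, rng, survival_factory):
        x = rng.normal(size=50)
        time, event = survival_factory(rng, 50)
        _, p1 = sv.cox_score_screen(x[None, :], time, event)
        _, p2 = sv.cox_score_screen(7.3 * x[None, :], time, event)
        assert p1[0] == pytest.approx(p2[0], rel=1e-10)


class TestLogrank:
    def test_identical_groups_give_null(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = sv.logrank_two_group(labels, time, event)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_sample_hand_table(self):
        # groups A={t 1+,3+,5 ev}, B={t 2 ev,4 ev,6+}; hand O-E table:
        # t=2: risk 5 (A 2), d=1 in B -> O_A-E_A = 0-2/5, V = (2/5)(3/5)
        # t=4: risk 3 (A 1), d=1 in B -> O_A-E_A = 0-1/3, V = (1/3)(2/3)
        # t=5: risk 2 (A 1), d=1 in A -> O_A-E_A = 1-1/2, V = (1/2)(1/2)
        labels = np.array([0, 1, 0, 1, 0, 1])
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.array([0, 1, 0, 1, 1, 0])
        ome = (0 - 2 / 5) + (0 - 1 / 3) + (1 - 1 / 2)
        var = (2 / 5) * (3 / 5) + (1 / 3) * (2 / 3) + (1 / 2) * (1 / 2)
        res = sv.logrank_two_group(labels, time, event)
        # the statistic is symmetric in which group is summed
        assert res.chi_square == pytest.approx(ome ** 2 / var, rel=1e-12)
        assert res.group_sizes == (3, 3)

    def test_matches_lifelines(self, rng, survival_factory):
        labels = rng.integers(0, 2, size=80)
        time, event = survival_factory(rng, 80, hr_group=labels)
        res = sv.logrank_two_group(labels, time, event)
        ref = logrank_test(time[labels == 0], time[labels == 1],
                           event[labels == 0], event[labels == 1])
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-8)

    def test_one_group_empty_is_error(self):
        with pytest.raises(ValidationError):
            sv.logrank_two_group([1, 1, 1], [1.0, 2, 3], [1, 1, 1])

    def test_equals_cox_score_for_binary_covariate_no_ties(self, rng):
        labels = rng.integers(0, 2, size=60)
        time = rng.exponential(10, size=60) + rng.random(60) * 1e-6
        event = rng.integers(0, 2, size=60)
        event[0] = 1
        res = sv.logrank_two_group(labels, time, event)
        chi2, _ = sv.cox_score_screen(labels.astype(float)[None, :], time, event)
        assert res.chi_square == pytest.approx(chi2[0], abs=1e-6)


class TestConcordance:
    def test_perfect_ordering(self):
        res = sv.concordance_index([3.0, 2, 1], [1.0, 2, 3], [1, 1, 1])
        assert res.c_index == 1.0 and res.comparable_pairs == 3

    def test_perfect_anti_ordering(self):
        res = sv.concordance_index([1.0, 2, 3], [1.0, 2, 3], [1, 1, 1])
        assert res.c_index == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 10_000))
    def test_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        risk = rng.integers(0, 5, size=n).astype(float)  # ties likely
        time = rng.integers(1, 6, size=n).astype(float)
        event = rng.integers(0, 2, size=n)
        conc, comp = brute_force_cindex(risk, time, event)
        if comp == 0:
            with pytest.raises(ValidationError):
                sv.concordance_index(risk, time, event)
            return
        res = sv.concordance_index(risk, time, event)
        assert res.comparable_pairs == comp
        assert res.concordant == pytest.approx(conc)
        assert res.c_index == pytest.approx(conc / comp)

    def test_matches_lifelines_util(self, rng, survival_factory):
        risk = rng.normal(size=100)
        time, event = survival_factory(rng, 100)
        res = sv.concordance_index(risk, time, event)
        assert res.c_index == pytest.approx(
            ll_concordance(time, -risk, event), abs=1e-12)

    def test_shift_invariance_and_complement(self, rng, survival_factory):
        risk = rng.normal(size=40)  # continuous: no ties
        time, event = survival_factory(rng, 40)
        c0 = sv.concordance_index(risk, time, event).c_index
        assert sv.concordance_index(risk + 5.0, time, event).c_index == c0
        assert sv.concordance_index(-risk, time, event).c_index == pytest.approx(1 - c0)


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        curve = sv.km_curve([1.0, 2, 3], [0, 0, 0])
        assert curve.shape == (1, 2) and curve[0, 1] == 1.0

    def test_no_censoring_empirical_survival(self):
        curve = sv.km_curve([1.0, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(curve[1:, 1], [0.75, 0.5, 0.25, 0.0])

    def test_censored_five_sample_hand_product(self):
        # events at 1 (n=5) and 4 (n=2); censored at 2, 3; last obs 5
        # S(1) = 4/5; S(4) = 4/5 * 1/2 = 2/5
        curve = sv.km_curve([1.0, 2, 3, 4, 5], [1, 0, 0, 1, 0])
        np.testing.assert_allclose(curve, [[0, 1.0], [1, 0.8], [4, 0.4]])

    def test_matches_lifelines(self, rng, survival_factory):
        time, event = survival_factory(rng, 50)
        curve = sv.km_curve(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        for t, s in curve[1:]:
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)

    def test_restricted_mean_exponential(self, rng):
        time = rng.exponential(10.0, size=4000)
        event = np.ones(4000, dtype=int)
        # E[min(T, tau)] = scale * (1 - exp(-tau/scale))
        tau = 15.0
        expected = 10.0 * (1 - np.exp(-tau / 10.0))
        assert sv.restricted_mean_survival(time, event, tau) == pytest.approx(
            expected, rel=0.05)


class TestBhFdr:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(sv.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert sv.bh_fdr([0.42])[0] == pytest.approx(0.42)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sv.bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_at_least_raw(self, ps):
        adj = sv.bh_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
        np.testing.assert_allclose(adj, multipletests(ps, method="fdr_bh")[1])
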