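"""Unit and oracle tests for the survival-statistics kernel."""

import numpy as np
import pytest
from scipy import stats

from multirisk import survival as sv


def make_data(n, seed, beta=0.7, censor=0.3, p=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    lam = 0.1 * np.exp(X @ (np.full(p, beta) / np.sqrt(p)))
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / (0.1 * censor / (1 - censor)), n) if censor > 0 else np.full(n, np.inf)
    event = (t <= c).astype(int)
    return sv.SurvivalData(np.minimum(t, c), event, X)


class TestPartialLoglik:
    def test_closed_form_at_zero_tie_free(self):
        # at beta=0 the partial log-likelihood is -sum(log risk-set sizes)
        data = make_data(40, 1)
        order = np.argsort(data.time)
        rsizes = [np.sum(data.time >= data.time[i]) for i in order if data.event[i] == 1]
        expected = -np.sum(np.log(rsizes))
        for ties in ("efron", "breslow"):
            assert sv.cox_partial_loglik(np.zeros(1), data, ties) == pytest.approx(expected)

    def test_two_patient_closed_form(self):
        data = sv.SurvivalData([1.0, 2.0], [1, 0], [[1.0], [0.0]])
        for b in (-1.3, 0.0, 0.4, 2.0):
            expected = b - np.log(np.exp(b) + 1)
            assert sv.cox_partial_loglik(np.array([b]), data) == pytest.approx(expected)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_gradient_matches_finite_differences(self, ties):
        data = make_data(30, 2, p=3)
        # introduce ties to exercise both tie corrections
        data.time = np.round(data.time, 0) + 0.5
        beta = np.array([0.3, -0.5, 0.1])
        grad, _ = sv.cox_gradient(beta, data, ties)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            num = (
                sv.cox_partial_loglik(beta + e, data, ties)
                - sv.cox_partial_loglik(beta - e, data, ties)
            ) / (2 * eps)
            assert grad[j] == pytest.approx(num, rel=1e-5)

    def test_nonfinite_beta_rejected(self):
        data = make_data(10, 3)
        with pytest.raises(ValueError):
            sv.cox_partial_loglik(np.array([np.nan]), data)


class TestFitCoxph:
    def test_matches_1d_grid_oracle(self):
        # brute-force golden-section maximization of the same likelihood
        data = sv.SurvivalData([1, 2, 3, 4], [1, 1, 1, 1], [[1.0], [0.0], [1.0], [0.0]])
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda b: -sv.cox_partial_loglik(np.array([b]), data),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-10},
        )
        fit = sv.fit_coxph(data)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(res.x, abs=1e-6)

    def test_efron_equals_breslow_tie_free(self):
        data = make_data(60, 4, p=2)
        fe = sv.fit_coxph(data, ties="efron")
        fb = sv.fit_coxph(data, ties="breslow")
        np.testing.assert_allclose(fe.coefficients, fb.coefficients, atol=1e-8)

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        data = make_data(120, 5, p=3)
        fit = sv.fit_coxph(data)
        df = pd.DataFrame(data.covariates, columns=data.names)
        df["T"] = data.time
        df["E"] = data.event
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(
            fit.coefficients, cph.params_.to_numpy(), atol=1e-5
        )
        np.testing.assert_allclose(
            fit.standard_errors, cph.standard_errors_.to_numpy(), atol=1e-5
        )

    def test_constant_covariate_rejected(self):
        data = make_data(20, 6)
        data.covariates[:, 0] = 2.0
        with pytest.raises(ValueError, match="degenerate"):
            sv.fit_coxph(data)

    def test_duplicated_covariate_singular(self):
        base = make_data(30, 7)
        X = np.column_stack([base.covariates[:, 0], base.covariates[:, 0]])
        data = sv.SurvivalData(base.time, base.event, X)
        with pytest.raises(np.linalg.LinAlgError):
            sv.fit_coxph(data)

    def test_separation_flags_nonconvergence(self):
        # perfectly separating covariate -> monotone likelihood
        data = sv.SurvivalData(
            [1, 2, 3, 10, 11, 12],
            [1, 1, 1, 1, 1, 1],
            [[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]],
        )
        with pytest.warns(RuntimeWarning):
            fit = sv.fit_coxph(data)
        assert not fit.converged


class TestKaplanMeier:
    def test_no_censoring_empirical_survival(self):
        t = np.array([3.0, 1.0, 2.0, 2.0, 5.0])
        km = sv.km_estimate(t, np.ones(5, dtype=int))
        for tt, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(np.mean(t > tt))

    def test_hand_computation_with_censoring(self):
        km = sv.km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.median == 3.0

    def test_all_censored_median_not_reached(self):
        km = sv.km_estimate([1, 2, 3], [0, 0, 0])
        assert km.median == sv.NOT_REACHED
        assert not km.median_reached

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        t = rng.exponential(5, 80)
        e = rng.integers(0, 2, 80)
        e[0] = 1
        km = sv.km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt, s in zip(km.event_times, km.survival):
            assert kmf.predict(tt) == pytest.approx(s, abs=1e-10)

    def test_integral_equals_mean_on_uncensored(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(3, 200)
        km = sv.km_estimate(t, np.ones(200, dtype=int))
        # area under the step survival curve equals the sample mean
        grid = np.concatenate([[0.0], km.event_times])
        heights = np.concatenate([[1.0], km.survival[:-1]])
        area = np.sum(np.diff(grid) * heights)
        assert area == pytest.approx(t.mean(), rel=1e-10)


class TestLogrank:
    def test_identical_groups(self):
        t = np.array([1.0, 2, 3, 1, 2, 3])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = sv.logrank_test(t, e, g)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_worked_table(self):
        # A events at 1,2; B events at 3,4: accumulate O-E and V by hand
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        g = np.array(["A", "A", "B", "B"])
        # time 1: n=4, nA=2, O-E = 1 - 2/4, V = (2/4)(2/4)(3/3)
        # time 2: n=3, nA=1, O-E = 1 - 1/3, V = (1/3)(2/3)(2/2)
        # times 3, 4: group A exhausted, nA=0 -> no contribution
        o_minus_e = (1 - 2 / 4) + (1 - 1 / 3)
        var = (2 / 4) * (2 / 4) + (1 / 3) * (2 / 3)
        res = sv.logrank_test(t, e, g)
        assert res["chi2"] == pytest.approx(o_minus_e**2 / var)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(4, 60)
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        g = rng.choice(["x", "y"], 60)
        g[:2] = ["x", "y"]
        r1 = sv.logrank_test(t, e, g)
        swapped = np.where(g == "x", "y", "x")
        r2 = sv.logrank_test(t, e, swapped)
        assert r1["chi2"] == pytest.approx(r2["chi2"])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(11)
        t = rng.exponential(4, 100)
        e = rng.integers(0, 2, 100)
        e[:10] = 1
        g = rng.choice(["x", "y"], 100)
        g[:2] = ["x", "y"]
        mine = sv.logrank_test(t, e, g)
        ref = ll_logrank(t[g == "x"], t[g == "y"], e[g == "x"], e[g == "y"])
        assert mine["chi2"] == pytest.approx(ref.test_statistic, rel=1e-8)
        assert mine["p"] == pytest.approx(ref.p_value, rel=1e-8)

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            sv.logrank_test([1, 2], [1, 1], ["a", "a"])


def cindex_bruteforce(risk, time, event):
    conc = tied = comp = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if event[i] == 1 and time[i] < time[j]:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    tied += 1
    return (conc + 0.5 * tied) / comp


class TestConcordance:
    def test_perfect_ranking(self):
        t = np.array([5.0, 3.0, 9.0, 1.0])
        assert sv.concordance_index(-t, t, np.ones(4, int)) == 1.0

    def test_constant_risk_is_half(self):
        t = np.array([5.0, 3.0, 9.0, 1.0])
        assert sv.concordance_index(np.ones(4), t, np.ones(4, int)) == 0.5

    def test_equals_bruteforce(self):
        rng = np.random.default_rng(12)
        n = 200
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n)
        e[:3] = 1
        r = np.round(rng.normal(0, 1, n), 1)  # rounding forces some risk ties
        assert sv.concordance_index(r, t, e) == pytest.approx(
            cindex_bruteforce(r, t, e), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(5, 50)
        e = np.ones(50, int)
        r = rng.normal(0, 1, 50)
        c1 = sv.concordance_index(r, t, e)
        c2 = sv.concordance_index(np.exp(3 * r) + 7, t, e)
        assert c1 == pytest.approx(c2)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            sv.concordance_index([1.0, 2.0], [1.0, 2.0], [0, 1])


class TestBHAdjust:
    def test_single_p_identity(self):
        assert sv.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        np.testing.assert_allclose(
            sv.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_direct_step_up_formula(self):
        rng = np.random.default_rng(14)
        p = rng.random(37)
        q = sv.bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        for rank_pos, idx in enumerate(order, start=1):
            expected = min(
                min(p[j] * m / (list(order).index(j) + 1) for j in order[rank_pos - 1:]),
                1.0,
            )
            assert q[idx] == pytest.approx(expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(15)
        p = rng.random(500) ** 2
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(sv.bh_adjust(p), q_ref, atol=1e-12)

    def test_dominance_and_range(self):
        rng = np.random.default_rng(16)
        p = rng.random(100)
        q = sv.bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sv.bh_adjust([0.5, 1.2])


class TestPropertyBased:
    """Derandomized hypothesis checks of the kernel's invariants."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60)
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_bh_dominates_raw_and_preserves_rank_order(self, p):
        q = sv.bh_adjust(p)
        p_arr = np.asarray(p)
        assert np.all(q >= p_arr - 1e-12)
        order = np.argsort(p_arr, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    @given(data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_km_survival_nonincreasing_from_one(self, data):
        st = self.st
        n = data.draw(st.integers(1, 30))
        t = data.draw(
            st.lists(st.floats(0.1, 50, allow_nan=False), min_size=n, max_size=n)
        )
        e = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        km = sv.km_estimate(np.array(t), np.array(e))
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert km.survival.size == 0 or km.survival[0] <= 1.0


def test_parameter_recovery_single_fit():
    """A Cox fit at n=600 recovers the generating log-HR within ~3 SE."""
    data = make_data(600, 17, beta=np.log(2))
    fit = sv.fit_coxph(data)
    assert abs(fit.coefficients[0] - np.log(2)) < 3 * fit.standard_errors[0]
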