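"""Cox core: partial likelihood, Newton fitting, concordance."""

import numpy as np
import pytest
from lifelines import CoxPHFitter

from bascox.cox import (CoxPH, DegenerateDesignError, SurvivalData,
                        concordance_index, fit_cox,
                        neg_log_partial_likelihood)

from conftest import random_survival


def three_subject_data():
    return SurvivalData(time=[1, 2, 3], event=[1, 1, 1],
                        X=np.array([0.0, 1.0, 0.0]))


class TestPartialLikelihood:
    def test_null_value_is_log_risk_set_product(self):
        # at beta=0 each event term is log(risk-set size): log 3 + log 2 + log 1
        val = neg_log_partial_likelihood(
            np.zeros(1), three_subject_data(), "breslow", order=0)
        assert val == pytest.approx(np.log(6), abs=1e-12)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(3)
        data = random_survival(rng, n=50, p=3, beta=[0.4, -0.2, 0.0])
        beta = rng.normal(size=3) * 0.3
        vb, gb, hb = neg_log_partial_likelihood(beta, data, "breslow")
        ve, ge, he = neg_log_partial_likelihood(beta, data, "efron")
        assert vb == pytest.approx(ve, abs=1e-12)
        np.testing.assert_allclose(gb, ge, atol=1e-12)
        np.testing.assert_allclose(hb, he, atol=1e-10)

    def test_efron_matches_term_by_term_oracle_with_ties(self):
        # 8 subjects, one tied event pair at t=2: evaluate the Efron product
        # formula directly, term by term, independent of the implementation
        time = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 1, 0, 1, 0])
        x = np.array([0.5, -1.0, 0.3, 0.8, -0.2, 1.5, 0.0, -0.7])
        beta = np.array([0.4])
        r = np.exp(beta[0] * x)

        def risk(idx):
            return r[list(idx)].sum()

        # event at t=1: risk set all 8
        oracle = -(beta[0] * x[0]) + np.log(risk(range(8)))
        # tied events at t=2 (subjects 1, 2), risk set subjects 1..7
        d_set = [1, 2]
        rs = list(range(1, 8))
        oracle += -(beta[0] * (x[1] + x[2]))
        for l in range(2):
            oracle += np.log(risk(rs) - l / 2 * risk(d_set))
        # event at t=3 (subject 4), risk set 4..7
        oracle += -(beta[0] * x[4]) + np.log(risk(range(4, 8)))
        # event at t=5 (subject 6), risk set 6..7
        oracle += -(beta[0] * x[6]) + np.log(risk(range(6, 8)))

        data = SurvivalData(time, event, x)
        val = neg_log_partial_likelihood(beta, data, "efron", order=0)
        assert val == pytest.approx(oracle, abs=1e-12)

    def test_gradient_and_hessian_match_finite_differences(self):
        rng = np.random.default_rng(5)
        data = random_survival(rng, n=30, p=3, beta=[0.5, 0, -0.3], ties=True)
        beta = np.array([0.2, -0.1, 0.4])
        for ties in ("breslow", "efron"):
            val, grad, hess = neg_log_partial_likelihood(beta, data, ties)
            eps = 1e-6
            for j in range(3):
                e = np.zeros(3)
                e[j] = eps
                vp = neg_log_partial_likelihood(beta + e, data, ties, order=0)
                vm = neg_log_partial_likelihood(beta - e, data, ties, order=0)
                assert grad[j] == pytest.approx((vp - vm) / (2 * eps), abs=1e-5)
                _, gp = neg_log_partial_likelihood(beta + e, data, ties, order=1)
                _, gm = neg_log_partial_likelihood(beta - e, data, ties, order=1)
                np.testing.assert_allclose(
                    hess[:, j], (gp - gm) / (2 * eps), atol=1e-4)

    def test_convexity_along_random_segments(self):
        rng = np.random.default_rng(7)
        data = random_survival(rng, n=40, p=2, ties=True)
        for _ in range(20):
            a, b = rng.normal(size=(2, 2))
            va = neg_log_partial_likelihood(a, data, "efron", order=0)
            vb = neg_log_partial_likelihood(b, data, "efron", order=0)
            t = rng.uniform()
            vm = neg_log_partial_likelihood(
                t * a + (1 - t) * b, data, "efron", order=0)
            assert vm <= t * va + (1 - t) * vb + 1e-10


class TestNewtonFit:
    def test_closed_form_single_covariate(self):
        # stationary point of l(b) = b - log(2+e^b) - log(1+e^b) is ln sqrt(2)
        res = fit_cox(three_subject_data())
        assert res.converged
        assert res.params[0] == pytest.approx(np.log(np.sqrt(2)), abs=1e-9)

    def test_sign_equivariance(self):
        rng = np.random.default_rng(1)
        data = random_survival(rng, n=60, p=2, beta=[0.5, -0.5])
        flipped = SurvivalData(data.time, data.event,
                               data.X * np.array([-1.0, 1.0]))
        a = fit_cox(data).params
        b = fit_cox(flipped).params
        assert a[0] == pytest.approx(-b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)

    def test_rank_invariance_in_time(self):
        # the partial likelihood depends on times only through their order
        rng = np.random.default_rng(2)
        data = random_survival(rng, n=50, p=2, beta=[0.4, 0.0])
        warped = SurvivalData(np.exp(data.time), data.event, data.X)
        np.testing.assert_allclose(fit_cox(data).params,
                                   fit_cox(warped).params, atol=1e-9)

    def test_monotone_likelihood_is_flagged(self):
        # the x=1 subject fails first: beta diverges, must be flagged
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 0, 0, 0])
        x = np.array([1.0, 0.0, 0.0, 0.0])
        res = fit_cox(SurvivalData(time, event, x))
        assert not res.converged
        assert "monotone" in res.diagnostics

    def test_constant_column_raises(self):
        data = SurvivalData([1, 2, 3], [1, 1, 0], np.ones(3))
        with pytest.raises(DegenerateDesignError):
            CoxPH(data)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines_on_random_instances(self, ties):
        # tie-free data, so lifelines' Efron fit is the reference for both
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(40, 120))
            p = int(rng.integers(1, 5))
            data = random_survival(rng, n=n, p=p,
                                   beta=rng.normal(size=p) * 0.4,
                                   ties=False)
            mine = fit_cox(data, ties=ties)
            if not mine.converged:
                continue
            import pandas as pd
            df = pd.DataFrame(data.X, columns=data.names)
            df["T"], df["E"] = data.time, data.event
            ref = CoxPHFitter().fit(
                df, "T", "E", fit_options={"precision": 1e-14})
            np.testing.assert_allclose(
                mine.params, ref.params_.to_numpy(), atol=1e-6)
            np.testing.assert_allclose(
                mine.bse, ref.standard_errors_.to_numpy(), atol=1e-6)

    def test_wald_summary_is_consistent(self):
        rng = np.random.default_rng(9)
        data = random_survival(rng, n=80, p=2, beta=[0.6, 0.0])
        res = fit_cox(data)
        ci = res.conf_int()
        assert np.all(ci[:, 0] <= res.hazard_ratios)
        assert np.all(res.hazard_ratios <= ci[:, 1])
        assert "Cox PH model" in res.summary()


def brute_force_cindex(risk, time, event):
    """Independent O(n^2) pair enumeration of Harrell's C."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0)
            if not comparable:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestConcordance:
    def test_all_ties_is_half(self):
        assert concordance_index(
            np.ones(5), np.arange(1, 6.0), np.ones(5, int)) == 0.5

    def test_perfect_reverse_ordering_is_one(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        risk = -time
        assert concordance_index(risk, time, np.ones(4, int)) == 1.0

    def test_six_subject_instance_with_censoring_and_risk_tie(self):
        time = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 9.0])
        event = np.array([1, 1, 0, 0, 1, 0])
        risk = np.array([1.2, 0.5, 0.5, -0.3, 0.8, -1.0])
        assert concordance_index(risk, time, event) == pytest.approx(
            brute_force_cindex(risk, time, event), abs=1e-15)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(5, 50))
            time = np.round(rng.exponential(3, n), 1) + 0.1
            event = (rng.uniform(size=n) < 0.7).astype(int)
            if event.sum() == 0:
                event[0] = 1
            risk = np.round(rng.normal(size=n), 1)  # rounded -> risk ties
            assert concordance_index(risk, time, event) == pytest.approx(
                brute_force_cindex(risk, time, event), abs=1e-15)

    def test_matches_scikit_survival_without_time_ties(self):
        from sksurv.metrics import concordance_index_censored
        rng = np.random.default_rng(4)
        time = rng.exponential(3, 80) + 0.01
        event = (rng.uniform(size=80) < 0.6).astype(int)
        risk = rng.normal(size=80)
        ref = concordance_index_censored(event.astype(bool), time, risk)[0]
        assert concordance_index(risk, time, event) == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [1.0, 2.0], [0, 1])

    def test_true_linear_predictor_beats_random_scores(self):
        # mean C over 100 synthetic PH replicates: truth >> noise
        rng = np.random.default_rng(21)
        c_true, c_rand = [], []
        for _ in range(100):
            beta = np.array([0.8, -0.5])
            data = random_survival(rng, n=100, p=2, beta=beta)
            lp = data.X @ beta
            c_true.append(concordance_index(lp, data.time, data.event))
            c_rand.append(concordance_index(rng.normal(size=100),
                                            data.time, data.event))
        assert np.mean(c_true) > np.mean(c_rand) + 0.1
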