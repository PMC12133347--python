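"""Information criteria and PSIS-LOO against brute-force and conjugate oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erpdcm.selection import (
    aic,
    bic,
    compare_models,
    psis_loo,
    reduced_model,
    waic,
)


class TestAICBIC:
    def test_aic_values(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-10.0, 10) == 40.0

    def test_bic_value(self):
        assert bic(-10.0, 10, 201) == pytest.approx(20 + 10 * math.log(201))
        assert 20 + 10 * math.log(201) == pytest.approx(73.033, abs=5e-4)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            aic(0.0, -1)
        with pytest.raises(ValueError):
            bic(0.0, 1, 0)


def _waic_bruteforce(ll):
    # direct summation of the defining formulas
    S, n = ll.shape
    lpd = sum(math.log(np.mean(np.exp(ll[:, i]))) for i in range(n))
    p = sum(np.var(ll[:, i], ddof=1) for i in range(n)) if S > 1 else 0.0
    return lpd, p, -2 * (lpd - p)


class TestWAIC:
    def test_identical_draws_have_zero_penalty(self):
        row = np.array([-1.2, -0.3, -2.0])
        ll = np.tile(row, (5, 1))
        res = waic(ll)
        assert res.p_waic == 0.0
        assert res.waic == pytest.approx(-2 * row.sum())

    def test_two_by_two_toy_matches_bruteforce(self):
        ll = np.array([[-1.0, -2.0], [-1.5, -0.5]])
        res = waic(ll)
        lpd, p, w = _waic_bruteforce(ll)
        assert res.lpd_hat == pytest.approx(lpd, rel=1e-12)
        assert res.p_waic == pytest.approx(p, rel=1e-12)
        assert res.waic == pytest.approx(w, rel=1e-12)

    @given(
        st.integers(2, 3), st.integers(1, 3),
        st.floats(-5, 0), st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_small_matrices_match_bruteforce(self, S, n, shift, seed):
        ll = np.random.default_rng(seed).uniform(-4, 0, size=(S, n)) + shift
        res = waic(ll)
        lpd, p, w = _waic_bruteforce(ll)
        assert res.lpd_hat == pytest.approx(lpd, rel=1e-9)
        assert res.p_waic == pytest.approx(p, rel=1e-9)
        assert res.waic == pytest.approx(w, rel=1e-9)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(4)
        ll = rng.uniform(-3, -0.5, size=(20, 7))
        c = 0.37
        base, shifted = waic(ll), waic(ll + c)
        assert shifted.lpd_hat == pytest.approx(base.lpd_hat + 7 * c, rel=1e-9)
        assert shifted.p_waic == pytest.approx(base.p_waic, rel=1e-9)

    def test_single_draw_warns(self):
        with pytest.warns(UserWarning, match="single draw"):
            res = waic(np.array([[-1.0, -2.0]]))
        assert res.p_waic == 0.0

    def test_waic_identity_holds_exactly(self):
        rng = np.random.default_rng(5)
        ll = rng.uniform(-4, 0, size=(50, 11))
        res = waic(ll)
        assert res.waic == -2.0 * (res.lpd_hat - res.p_waic)


class TestPSISLOO:
    def test_degenerate_weights_reduce_to_plain_lpd(self):
        row = np.array([-1.2, -0.3, -2.0, -0.7, -1.9])
        ll = np.tile(row, (40, 1))
        res = psis_loo(ll)
        assert res.elpd_psis_loo == pytest.approx(-2 * row.sum(), rel=1e-9)

    def test_matches_exact_loo_on_conjugate_model(self):
        # theta ~ N(0, s0^2), y_i ~ N(theta, s^2): each leave-one-out
        # predictive is available in closed form from the n-1 point posterior
        rng = np.random.default_rng(8)
        s0, s, n, S = 2.0, 1.0, 5, 4000
        y = rng.normal(0.7, s, size=n)
        post_var = 1.0 / (1 / s0**2 + n / s**2)
        post_mean = post_var * y.sum() / s**2
        thetas = rng.normal(post_mean, math.sqrt(post_var), size=S)
        ll = -0.5 * ((y[None, :] - thetas[:, None]) / s) ** 2 - math.log(
            s * math.sqrt(2 * math.pi)
        )
        exact = np.empty(n)
        for i in range(n):
            rest = np.delete(y, i)
            v = 1.0 / (1 / s0**2 + (n - 1) / s**2)
            m = v * rest.sum() / s**2
            pred_var = v + s**2
            exact[i] = -0.5 * (y[i] - m) ** 2 / pred_var - 0.5 * math.log(
                2 * math.pi * pred_var
            )
        res = psis_loo(ll)
        np.testing.assert_allclose(res.pointwise, exact, atol=0.05)
        assert res.elpd_psis_loo == pytest.approx(-2 * exact.sum(), abs=0.3)

    def test_agrees_with_arviz_reference(self):
        import arviz as az

        rng = np.random.default_rng(9)
        thetas = rng.normal(0.5, 0.4, size=(4, 250))
        y = rng.normal(0.5, 1.0, size=8)
        ll = -0.5 * (y[None, None, :] - thetas[:, :, None]) ** 2 - 0.5 * math.log(2 * math.pi)
        idata = az.from_dict(
            posterior={"theta": thetas}, log_likelihood={"y": ll}
        )
        ref = az.loo(idata, pointwise=True)
        res = psis_loo(ll.reshape(-1, 8))
        assert res.elpd == pytest.approx(float(ref.elpd_loo), abs=0.05)
        np.testing.assert_allclose(res.pointwise, np.asarray(ref.loo_i), atol=0.05)

    def test_waic_loo_agreement_on_well_specified_fit(self, tails_run):
        ll = tails_run.samples.pointwise_loglik.reshape(-1, 201)
        w = waic(ll)
        loo = psis_loo(ll)
        assert abs(loo.elpd_psis_loo - w.waic) < 0.05 * abs(w.waic)
        assert np.nanmax(loo.pareto_k) < 0.7

    def test_too_few_draws_falls_back_with_warning(self):
        ll = np.random.default_rng(1).uniform(-2, 0, size=(4, 3))
        with pytest.warns(UserWarning, match="unsmoothed"):
            psis_loo(ll)


class TestReducedModel:
    def test_masking_bookkeeping(self, dcm_model):
        red = reduced_model(dcm_model, "g1")
        assert red.k == 9
        assert red.reduced_mask == ("g1",)

    def test_idempotent(self, dcm_model):
        red = reduced_model(reduced_model(dcm_model, "g3"), "g3")
        assert red.k == 9

    def test_rejects_non_gain(self, dcm_model):
        with pytest.raises(ValueError):
            reduced_model(dcm_model, "tau_e")

    def test_g1_zero_dynamics_remain_stable(self, dcm_model):
        from erpdcm import TRUE_PARAMETERS, integrate_euler

        p = TRUE_PARAMETERS.replace(g1=0.0)
        traj = integrate_euler(p)
        assert traj.stable
        # its response still resembles an evoked potential (order-1 voltage)
        assert 0.1 < np.max(np.abs(traj.pyramidal)) < 20


class TestCompareModels:
    @staticmethod
    def _score(name, w, fingerprint="abc"):
        from erpdcm.selection import ComparisonScores

        return ComparisonScores(
            name=name, k=10, n=201, aic=w, bic=w, lpd_hat=-w / 2, p_waic=0.0,
            waic=w, elpd_psis_loo=w, pareto_k=np.zeros(1), data_fingerprint=fingerprint,
        )

    def test_tied_scores_tie_ranks(self):
        df = compare_models([self._score("a", 10.0), self._score("b", 10.0)])
        assert df["rank_waic"].tolist() == [1, 1]

    def test_rejects_mismatched_observations(self):
        with pytest.raises(ValueError, match="different observations"):
            compare_models([self._score("a", 1.0), self._score("b", 2.0, "xyz")])

    def test_shifting_one_model_moves_only_its_rank(self):
        df1 = compare_models([self._score("a", 5.0), self._score("b", 6.0), self._score("c", 7.0)])
        df2 = compare_models([self._score("a", 5.0), self._score("b", 6.0), self._score("c", 5.5)])
        assert df1.loc["a", "rank_waic"] == df2.loc["a", "rank_waic"] == 1
        assert df1.loc["c", "rank_waic"] == 3 and df2.loc["c", "rank_waic"] == 2

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            compare_models([self._score("a", 1.0)])
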