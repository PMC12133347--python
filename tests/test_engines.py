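"""Inference engines on analytically tractable targets and the ERP model."""

import math

import numpy as np
import pytest

from erpdcm import ERPModel, VIConfig
from erpdcm.engines import SamplerConfig, run_advi, run_laplace, run_nuts


class MockGaussianModel:
    """Model stand-in whose unconstrained log-joint is an exact Gaussian.

    Presents the same surface as :class:`ERPModel` so the engines can be
    exercised against closed-form posteriors.
    """

    def __init__(self, mean, cov, prior_scale=3.0):
        self.mu = np.asarray(mean, dtype=float)
        self.cov = np.atleast_2d(np.asarray(cov, dtype=float))
        self.prec = np.linalg.inv(self.cov)
        self.k = len(self.mu)
        self.free_names = tuple(f"p{i}" for i in range(self.k))
        self.n_obs = 1
        self.prior_scale = prior_scale

    def logp_grad_unconstrained(self, z, want_grad=True):
        d = z - self.mu
        lp = -0.5 * float(d @ self.prec @ d)
        return lp, (-(self.prec @ d) if want_grad else None)

    def draw_prior(self, rng):
        return np.exp(self.mu + self.prior_scale * rng.normal(size=self.k))

    def draw_prior_tails(self, rng, tail_mass=0.025):
        return self.draw_prior(rng)

    def params_from_free(self, free_theta):
        return free_theta

    def pointwise_loglik(self, params):
        return np.zeros(self.n_obs)


class ConjugateNormalModel(MockGaussianModel):
    """Normal prior x normal likelihood with known evidence and posterior."""

    def __init__(self, y, sigma=1.0, m0=0.0, s0=2.0):
        self.y = np.asarray(y, dtype=float)
        self.sigma, self.m0, self.s0 = sigma, m0, s0
        n = len(self.y)
        post_var = 1.0 / (1.0 / s0**2 + n / sigma**2)
        post_mean = post_var * (m0 / s0**2 + self.y.sum() / sigma**2)
        super().__init__([post_mean], [[post_var]])
        self.n_obs = n

    def logp_grad_unconstrained(self, z, want_grad=True):
        th = z[0]
        lp = -0.5 * ((th - self.m0) / self.s0) ** 2 - math.log(self.s0 * math.sqrt(2 * math.pi))
        lp += float(np.sum(-0.5 * ((self.y - th) / self.sigma) ** 2)) - self.n_obs * math.log(
            self.sigma * math.sqrt(2 * math.pi)
        )
        g = -(th - self.m0) / self.s0**2 + float(np.sum(self.y - th)) / self.sigma**2
        return lp, (np.array([g]) if want_grad else None)

    def log_evidence(self) -> float:
        # marginal of y under theta ~ N(m0, s0^2): N(m0 1, sigma^2 I + s0^2 J)
        n = len(self.y)
        cov = self.sigma**2 * np.eye(n) + self.s0**2 * np.ones((n, n))
        d = self.y - self.m0
        sign, logdet = np.linalg.slogdet(cov)
        return float(-0.5 * d @ np.linalg.solve(cov, d) - 0.5 * logdet - 0.5 * n * math.log(2 * math.pi))

    def pointwise_loglik(self, params):
        th = math.log(params[0])  # engines hand back exp(zeta)
        return -0.5 * ((self.y - th) / self.sigma) ** 2 - math.log(
            self.sigma * math.sqrt(2 * math.pi)
        )


class TestNUTS:
    def test_standard_normal_target(self):
        target = MockGaussianModel(np.zeros(2), np.eye(2))
        res = run_nuts(target, SamplerConfig(n_chains=4, n_warmup=150, n_samples=400, seed=0))
        zeta = np.log(res.samples.flat())
        ess = 4 * 400 * 0.5  # conservative effective-draw count
        mcse = 1.0 / np.sqrt(ess)
        assert np.all(np.abs(zeta.mean(axis=0)) < 3 * mcse)
        assert zeta.std(axis=0) == pytest.approx(1.0, rel=0.15)

    def test_conjugate_posterior_sd(self):
        rng = np.random.default_rng(3)
        y = rng.normal(1.5, 1.0, size=20)
        target = ConjugateNormalModel(y)
        res = run_nuts(target, SamplerConfig(n_chains=4, n_warmup=150, n_samples=400, seed=1))
        zeta = np.log(res.samples.flat())[:, 0]
        post_sd = math.sqrt(target.cov[0, 0])
        assert zeta.mean() == pytest.approx(target.mu[0], abs=4 * post_sd / math.sqrt(400))
        assert zeta.std(ddof=1) == pytest.approx(post_sd, rel=0.12)

    def test_seed_determinism(self):
        target = MockGaussianModel(np.zeros(2), np.eye(2))
        cfg = SamplerConfig(n_chains=2, n_warmup=50, n_samples=50, seed=9)
        a = run_nuts(target, cfg)
        b = run_nuts(target, cfg)
        np.testing.assert_array_equal(a.samples.draws, b.samples.draws)

    def test_recorded_lp_decomposes_into_prior_plus_likelihood(self, dcm_model, tails_run):
        # row-sums of the pointwise log-likelihood must reconstruct the
        # likelihood part of the recorded log-probability
        s = tails_run.samples
        priors = dcm_model.priors
        for c in range(0, s.n_chains, 3):
            for i in range(0, s.n_draws, 50):
                theta = s.draws[c, i]
                zeta = np.log(theta)
                lp_rec = s.stats["lp"][c, i]
                ll = s.pointwise_loglik[c, i].sum()
                # prior + exp-map Jacobian, computed independently
                prior_part = float(
                    np.sum(priors.shapes * zeta - theta / priors.scales)
                ) + dcm_model._gamma_norm_free
                assert lp_rec == pytest.approx(prior_part + ll, abs=1e-6)


class TestADVI:
    def test_full_rank_recovers_correlated_gaussian(self):
        cov = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.3], [0.0, 0.3, 0.5]])
        target = MockGaussianModel([1.0, -0.5, 0.2], cov)
        res = run_advi(target, VIConfig(guide="full_rank", n_iters=20000,
                                        learning_rate=0.02, seed=0))
        np.testing.assert_allclose(res.extra["guide_mean"], target.mu, atol=0.1)
        np.testing.assert_allclose(res.extra["guide_cov"], cov, atol=0.15)

    def test_mean_field_underestimates_marginal_sds(self):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        target = MockGaussianModel([0.0, 0.0], cov)
        res = run_advi(target, VIConfig(guide="mean_field", n_iters=20000,
                                        learning_rate=0.02, seed=0))
        fitted_sd = np.sqrt(np.diag(res.extra["guide_cov"]))
        assert np.all(fitted_sd <= np.sqrt(np.diag(cov)) + 0.02)
        # for this correlation the conditional sd is sqrt(1 - 0.9^2)
        assert fitted_sd == pytest.approx(math.sqrt(1 - 0.81), abs=0.1)

    def test_seed_determinism(self):
        target = MockGaussianModel([0.0], [[1.0]])
        cfg = VIConfig(guide="mean_field", n_iters=500, seed=4)
        a = run_advi(target, cfg)
        b = run_advi(target, cfg)
        np.testing.assert_array_equal(a.samples.draws, b.samples.draws)

    def test_elbo_trace_trend_on_the_erp_model(self, dcm_model):
        res = dcm_model.fit("meanfield", seed=2, n_iters=4000, init_strategy="prior_tails")
        trace = res.extra["elbo_trace"]
        window = 1000
        means = [np.nanmean(trace[i : i + window]) for i in range(0, 4000, window)]
        # non-decreasing after smoothing (small stochastic slack)
        for a, b in zip(means, means[1:]):
            assert b >= a - 0.01 * abs(a)


class TestLaplace:
    def test_exact_on_gaussian_target(self):
        cov = np.array([[0.5, 0.2], [0.2, 0.8]])
        target = MockGaussianModel([0.3, -0.7], cov)
        res = run_laplace(target, VIConfig(guide="laplace", seed=0))
        np.testing.assert_allclose(res.extra["map_unconstrained"], target.mu, atol=1e-5)
        np.testing.assert_allclose(res.extra["guide_cov"], cov, atol=1e-4)

    def test_elbo_equals_conjugate_evidence(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0.8, 1.0, size=12)
        target = ConjugateNormalModel(y)
        res = run_laplace(target, VIConfig(guide="laplace", seed=1))
        assert res.extra["elbo_laplace"] == pytest.approx(target.log_evidence(), abs=1e-6)

    def test_reduced_model_lowers_dimension_in_elbo(self, study_obs):
        # k enters the evidence approximation as the sampled dimension
        full = ERPModel(study_obs)
        red = ERPModel(study_obs, reduced_mask=("g1",))
        assert full.k - red.k == 1

    def test_agrees_with_nuts_on_the_erp_model(self, dcm_model, tails_run):
        lap = dcm_model.fit("laplace", seed=5)
        agree = np.abs(tails_run.mean - lap.mean) <= 2 * tails_run.sd
        assert agree.all()


def test_mean_field_variance_deficit_on_the_erp_model(dcm_model):
    mf = dcm_model.fit("meanfield", seed=3, n_iters=20000, init_strategy="prior_tails")
    fr = dcm_model.fit("fullrank", seed=3, n_iters=20000, init_strategy="prior_tails")
    assert int(np.sum(mf.sd <= fr.sd)) >= 8
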