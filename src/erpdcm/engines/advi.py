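"""Automatic-differentiation-style variational inference (mean-field / full-rank).

Both guides are Gaussians over the unconstrained parameters: the mean-field
guide is a factorized Normal with free means and log-sds, the full-rank
guide a Normal with a free Cholesky factor (log-parametrized diagonal).
The ELBO is maximized by stochastic gradient ascent (Adam) with the
reparametrization trick; the per-iteration ELBO trace is recorded.  After
optimization the fitted guide is sampled ``n_chains * n_samples`` times and
the draws are mapped back to constrained space so every downstream
diagnostic applies uniformly across engines.
"""

from __future__ import annotations

import math

import numpy as np

from .config import VIConfig
from .nuts import _initial_position
from .results import PosteriorResults, PosteriorSamples, pointwise_loglik_matrix

__all__ = ["run_advi"]

_PATIENCE = 500  # consecutive non-finite ELBO evaluations tolerated


class _Adam:
    def __init__(self, shape, lr):
        self.lr = lr
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, x, grad):
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.t += 1
        self.m = b1 * self.m + (1 - b1) * grad
        self.v = b2 * self.v + (1 - b2) * grad**2
        mhat = self.m / (1 - b1**self.t)
        vhat = self.v / (1 - b2**self.t)
        return x + self.lr * mhat / (np.sqrt(vhat) + eps)


def _vi_initial_mean(model, cfg: VIConfig, rng):
    from .config import SamplerConfig

    scfg = SamplerConfig(
        init_strategy=cfg.init_strategy, init_value=cfg.init_value, seed=cfg.seed
    )
    return _initial_position(model, scfg, rng)


def run_advi(model, cfg: VIConfig | None = None, **kwargs) -> PosteriorResults:
    """Fit a Gaussian guide by stochastic ELBO ascent and sample it."""
    cfg = cfg or VIConfig()
    if kwargs:
        cfg = cfg.replace(**kwargs)
    if cfg.guide not in ("mean_field", "full_rank"):
        raise ValueError(f"run_advi expects a Gaussian guide, got {cfg.guide!r}")
    rng = np.random.default_rng(cfg.seed)
    k = model.k
    mu = _vi_initial_mean(model, cfg, rng)
    ent_const = 0.5 * k * (1.0 + math.log(2.0 * math.pi))

    full_rank = cfg.guide == "full_rank"
    omega = np.full(k, math.log(0.1))  # log-sd (mean-field) / log-diagonal (full-rank)
    L_low = np.zeros((k, k))  # strictly lower triangle, full-rank only
    opt_mu = _Adam(k, cfg.learning_rate)
    opt_om = _Adam(k, cfg.learning_rate)
    opt_L = _Adam((k, k), cfg.learning_rate) if full_rank else None
    tril = np.tril_indices(k, -1)

    elbo_trace = np.full(cfg.n_iters, np.nan)
    bad_run = 0
    for it in range(cfg.n_iters):
        g_mu = np.zeros(k)
        g_om = np.zeros(k)
        g_L = np.zeros((k, k)) if full_rank else None
        elbo_lik = 0.0
        finite = 0
        sd = np.exp(omega)
        for _ in range(cfg.elbo_samples):
            eta = rng.normal(size=k)
            if full_rank:
                L = L_low * 1.0
                L[np.diag_indices(k)] = sd
                zeta = mu + L @ eta
            else:
                zeta = mu + sd * eta
            lp, g = model.logp_grad_unconstrained(zeta)
            if not np.isfinite(lp):
                continue
            finite += 1
            elbo_lik += lp
            g_mu += g
            if full_rank:
                outer = np.outer(g, eta)
                g_L[tril] += outer[tril]
                g_om += np.diag(outer) * sd
            else:
                g_om += g * sd * eta
        if finite == 0:
            bad_run += 1
            if bad_run > _PATIENCE:
                raise RuntimeError(
                    f"ELBO non-finite for {bad_run} consecutive iterations "
                    f"(at iteration {it}); optimization diverged"
                )
            elbo_trace[it] = -np.inf
            continue
        bad_run = 0
        inv = 1.0 / finite
        # entropy of the guide: sum(omega) + const in both parametrizations
        elbo_trace[it] = elbo_lik * inv + float(np.sum(omega)) + ent_const
        g_mu *= inv
        g_om = g_om * inv + 1.0  # +1 from d entropy / d omega
        mu = opt_mu.step(mu, g_mu)
        omega = opt_om.step(omega, g_om)
        if full_rank:
            g_L *= inv
            L_low = opt_L.step(L_low, g_L)
            L_low[np.triu_indices(k)] = 0.0
        if cfg.early_stop and it >= 2 * cfg.plateau_window:
            recent = np.nanmean(elbo_trace[it - cfg.plateau_window : it])
            prev = np.nanmean(elbo_trace[it - 2 * cfg.plateau_window : it - cfg.plateau_window])
            if np.isfinite(recent) and np.isfinite(prev):
                if abs(recent - prev) < cfg.plateau_rel_tol * max(1.0, abs(prev)):
                    elbo_trace = elbo_trace[: it + 1]
                    break

    # sample the fitted guide, shaped as chains for uniform diagnostics
    sd = np.exp(omega)
    if full_rank:
        L = L_low * 1.0
        L[np.diag_indices(k)] = sd
        cov = L @ L.T
    else:
        L = None
        cov = np.diag(sd**2)
    c, s = cfg.n_chains, cfg.n_samples
    eta = rng.normal(size=(c * s, k))
    zeta = mu + (eta @ L.T if full_rank else eta * sd)
    draws = np.exp(zeta).reshape(c, s, k)
    samples = PosteriorSamples(
        draws=draws,
        param_names=model.free_names,
        pointwise_loglik=pointwise_loglik_matrix(model, draws),
        stats={},
        method=cfg.guide,
    )
    extra = {
        "config": cfg,
        "elbo_trace": elbo_trace,
        "elbo": _smoothed_final_elbo(elbo_trace),
        "guide_mean": mu,
        "guide_cov": cov,
    }
    return PosteriorResults(model, samples, extra=extra)


def _smoothed_final_elbo(trace, window: int = 1000) -> float:
    """Average of the last recorded ELBO values to damp gradient noise."""
    t = np.asarray(trace, dtype=float)
    t = t[np.isfinite(t)]
    if len(t) == 0:
        return -np.inf
    return float(t[-min(window, len(t)):].mean())
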