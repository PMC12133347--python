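"""No-U-Turn Sampler: dynamic HMC with self-tuned step size and metric.

A self-contained implementation of the dynamic-trajectory HMC variant: the
leapfrog trajectory is doubled recursively until the path makes a U-turn
or the maximum tree depth is reached, candidate points are selected
multinomially within the trajectory (biased toward the newer subtree), the
step size is tuned during warm-up by dual averaging toward a target
acceptance statistic, and a dense metric is estimated from expanding
warm-up windows.  Parameter draws whose forward simulation blows up carry
log-density ``-inf`` and terminate trajectory expansion as divergences, so
the sampler rejects them instead of crashing.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

from .config import SamplerConfig
from .results import PosteriorResults, PosteriorSamples, pointwise_loglik_matrix

__all__ = ["run_nuts", "NUTSChain"]

_DELTA_MAX = 1000.0  # divergence threshold on the energy error
_MAX_INIT_TRIES = 1000


class _Tree:
    """A trajectory subtree: endpoints, multinomial-weighted sample, stats."""

    __slots__ = ("z_m", "r_m", "g_m", "z_p", "r_p", "g_p", "z", "lp", "g", "logw", "s", "a", "na")

    def __init__(self, z_m, r_m, g_m, z_p, r_p, g_p, z, lp, g, logw, s, a, na):
        self.z_m, self.r_m, self.g_m = z_m, r_m, g_m
        self.z_p, self.r_p, self.g_p = z_p, r_p, g_p
        self.z, self.lp, self.g = z, lp, g
        self.logw, self.s, self.a, self.na = logw, s, a, na


def _initial_position(model, cfg: SamplerConfig, rng) -> np.ndarray:
    """Unconstrained start with finite log-joint, per the init strategy."""
    if cfg.init_strategy == "value":
        if cfg.init_value is None:
            raise ValueError("init_strategy='value' requires init_value")
        zeta = np.log(np.asarray(cfg.init_value, dtype=float))
        lp, _ = model.logp_grad_unconstrained(zeta, want_grad=False)
        if not np.isfinite(lp):
            raise RuntimeError("initialization failed: supplied init_value has -inf log-joint")
        return zeta
    draw = model.draw_prior_tails if cfg.init_strategy == "prior_tails" else model.draw_prior
    for _ in range(_MAX_INIT_TRIES):
        zeta = np.log(draw(rng))
        lp, _ = model.logp_grad_unconstrained(zeta, want_grad=False)
        if np.isfinite(lp):
            return zeta
    raise RuntimeError(
        f"initialization failed: no finite log-joint in {_MAX_INIT_TRIES} "
        f"{cfg.init_strategy!r} draws"
    )


class NUTSChain:
    """One NUTS chain over an unconstrained log-density with gradient."""

    def __init__(self, logp_grad, z0, rng, max_tree_depth=10, target_accept=0.8):
        self.f = logp_grad
        self.rng = rng
        self.max_depth = max_tree_depth
        self.delta = target_accept
        self.z = np.asarray(z0, dtype=float).copy()
        self.lp, self.g = self.f(self.z)
        if not np.isfinite(self.lp):
            raise RuntimeError("initialization failed: -inf log-joint at chain start")
        self.dim = len(self.z)
        # dense metric: estimated posterior covariance of the unconstrained
        # parameters (k is small, so a full matrix costs next to nothing and
        # absorbs the strong posterior correlations of this model)
        self.set_metric(np.eye(self.dim), readapt=False)
        self.eps = self._find_reasonable_eps()
        # dual-averaging state
        self._da_reset(self.eps)

    # -- hamiltonian pieces ------------------------------------------------
    def _kinetic(self, r):
        v = self._chol.T @ r
        return 0.5 * float(v @ v)

    def _draw_momentum(self):
        # r ~ N(0, Sigma^{-1}) via back-substitution with Sigma = L L^T
        eta = self.rng.normal(size=self.dim)
        return solve_triangular(self._chol.T, eta, lower=False)

    def _leapfrog(self, z, r, g, eps):
        r = r + 0.5 * eps * g
        z = z + eps * (self.metric @ r)
        lp, g = self.f(z)
        if np.isfinite(lp):
            r = r + 0.5 * eps * g
        return z, r, lp, g

    def _find_reasonable_eps(self):
        eps = 1.0
        r = self._draw_momentum()
        joint0 = self.lp - self._kinetic(r)
        z1, r1, lp1, _ = self._leapfrog(self.z, r, self.g, eps)
        joint1 = lp1 - self._kinetic(r1) if np.isfinite(lp1) else -np.inf
        # shrink first if the very first step is unstable
        while not np.isfinite(joint1):
            eps *= 0.5
            if eps < 1e-10:
                return 1e-10
            z1, r1, lp1, _ = self._leapfrog(self.z, r, self.g, eps)
            joint1 = lp1 - self._kinetic(r1) if np.isfinite(lp1) else -np.inf
        direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
        for _ in range(50):
            eps *= 2.0**direction
            z1, r1, lp1, _ = self._leapfrog(self.z, r, self.g, eps)
            joint1 = lp1 - self._kinetic(r1) if np.isfinite(lp1) else -np.inf
            if direction * (joint1 - joint0) <= direction * np.log(0.5):
                break
        return eps

    def _da_reset(self, eps):
        self._mu = np.log(10.0 * max(eps, 1e-10))
        self._log_eps_bar = 0.0
        self._h_bar = 0.0
        self._m_da = 0

    def _da_update(self, accept_stat):
        gamma, t0, kappa = 0.05, 10.0, 0.75
        self._m_da += 1
        m = self._m_da
        self._h_bar += (self.delta - accept_stat - self._h_bar) / (m + t0)
        log_eps = self._mu - np.sqrt(m) / gamma * self._h_bar
        w = m**-kappa
        self._log_eps_bar = w * log_eps + (1 - w) * self._log_eps_bar
        self.eps = float(np.exp(log_eps))

    def freeze_step_size(self):
        self.eps = float(np.exp(self._log_eps_bar))

    def set_metric(self, covariance, readapt=True):
        cov = np.atleast_2d(np.asarray(covariance, dtype=float))
        if cov.shape == (1, self.dim):  # accept a variance vector
            cov = np.diag(cov[0])
        self.metric = cov
        self._chol = np.linalg.cholesky(cov)
        if readapt:
            self.eps = self._find_reasonable_eps()
            self._da_reset(self.eps)

    # -- tree building -----------------------------------------------------
    def _uturn(self, z_m, r_m, z_p, r_p):
        dz = z_p - z_m
        return (dz @ (self.metric @ r_m) < 0.0) or (dz @ (self.metric @ r_p) < 0.0)

    def _base_tree(self, z, r, g, v, joint0):
        z1, r1, lp1, g1 = self._leapfrog(z, r, g, v * self.eps)
        joint1 = lp1 - self._kinetic(r1) if np.isfinite(lp1) else -np.inf
        diverging = (joint0 - joint1) > _DELTA_MAX or not np.isfinite(joint1)
        logw = joint1 - joint0  # multinomial weight of this leapfrog point
        s = int(not diverging)
        a = min(1.0, np.exp(min(joint1 - joint0, 0.0))) if np.isfinite(joint1) else 0.0
        return _Tree(z1, r1, g1, z1, r1, g1, z1, lp1, g1, logw, s, a, 1), diverging

    def _build_tree(self, z, r, g, v, depth, joint0):
        if depth == 0:
            return self._base_tree(z, r, g, v, joint0)
        t1, div = self._build_tree(z, r, g, v, depth - 1, joint0)
        if t1.s == 1:
            if v == -1:
                t2, div2 = self._build_tree(t1.z_m, t1.r_m, t1.g_m, v, depth - 1, joint0)
                t1.z_m, t1.r_m, t1.g_m = t2.z_m, t2.r_m, t2.g_m
            else:
                t2, div2 = self._build_tree(t1.z_p, t1.r_p, t1.g_p, v, depth - 1, joint0)
                t1.z_p, t1.r_p, t1.g_p = t2.z_p, t2.r_p, t2.g_p
            div = div or div2
            # multinomial sampling within the combined subtree
            logw_tot = np.logaddexp(t1.logw, t2.logw)
            if np.isfinite(t2.logw) and self.rng.random() < np.exp(t2.logw - logw_tot):
                t1.z, t1.lp, t1.g = t2.z, t2.lp, t2.g
            t1.logw = logw_tot
            t1.a += t2.a
            t1.na += t2.na
            t1.s = int(t2.s == 1 and not self._uturn(t1.z_m, t1.r_m, t1.z_p, t1.r_p))
        return t1, div

    def step(self):
        """One NUTS transition (multinomial variant); returns a stats dict."""
        r0 = self._draw_momentum()
        joint0 = self.lp - self._kinetic(r0)
        z_m = z_p = self.z
        r_m = r_p = r0
        g_m = g_p = self.g
        depth = 0
        logw_tot = 0.0  # weight of the initial point
        s = 1
        diverging = False
        accept_stat = 0.0
        n_alpha = 0
        while s == 1 and depth < self.max_depth:
            v = 1 if self.rng.random() < 0.5 else -1
            if v == -1:
                t, div = self._build_tree(z_m, r_m, g_m, v, depth, joint0)
                z_m, r_m, g_m = t.z_m, t.r_m, t.g_m
            else:
                t, div = self._build_tree(z_p, r_p, g_p, v, depth, joint0)
                z_p, r_p, g_p = t.z_p, t.r_p, t.g_p
            diverging = diverging or div
            if t.s == 1:
                # biased progressive sampling: favour the new subtree
                if np.isfinite(t.logw) and self.rng.random() < np.exp(
                    min(t.logw - logw_tot, 0.0)
                ):
                    self.z, self.lp, self.g = t.z, t.lp, t.g
                logw_tot = np.logaddexp(logw_tot, t.logw)
            accept_stat += t.a
            n_alpha += t.na
            s = int(t.s == 1 and not self._uturn(z_m, r_m, z_p, r_p))
            depth += 1
        accept_stat = accept_stat / max(n_alpha, 1)
        return {
            "lp": self.lp,
            "accept_stat": accept_stat,
            "diverging": diverging,
            "tree_depth": depth,
            "step_size": self.eps,
            "energy": -(self.lp - self._kinetic(r0)),
        }


def _run_single_chain(model, cfg: SamplerConfig, rng):
    z0 = _initial_position(model, cfg, rng)
    chain = NUTSChain(
        lambda z: model.logp_grad_unconstrained(z),
        z0,
        rng,
        max_tree_depth=cfg.max_tree_depth,
        target_accept=cfg.target_accept,
    )
    n_w = cfg.n_warmup
    # expanding metric-estimation windows between a step-size-only initial
    # buffer and a terminal step-size re-adaptation buffer
    init_buf = 75 if n_w >= 150 else int(0.15 * n_w)
    term_buf = 50 if n_w >= 150 else int(0.1 * n_w)
    spans = []
    if n_w - init_buf - term_buf >= 20:
        pos, size = init_buf, 25
        while pos < n_w - term_buf:
            end = pos + size
            if end + 2 * size > n_w - term_buf:
                end = n_w - term_buf
            spans.append((pos, end))
            pos = end
            size *= 2
    span_ends = {end for _, end in spans}
    window = []
    for it in range(n_w):
        stats = chain.step()
        chain._da_update(stats["accept_stat"])
        if any(lo <= it < end for lo, end in spans):
            window.append(chain.z.copy())
        if (it + 1) in span_ends and window:
            w = np.asarray(window)
            nw = len(w)
            if nw > chain.dim:
                cov = np.cov(w, rowvar=False)
            else:
                cov = np.diag(w.var(axis=0, ddof=1) if nw > 1 else np.ones(chain.dim))
            shrunk = nw / (nw + 5.0) * cov + 1e-3 * 5.0 / (nw + 5.0) * np.eye(chain.dim)
            chain.set_metric(shrunk)
            window = []
    chain.freeze_step_size()
    draws = np.empty((cfg.n_samples, chain.dim))
    rec = {k: np.zeros(cfg.n_samples) for k in
           ("lp", "accept_stat", "diverging", "tree_depth", "step_size", "energy")}
    for it in range(cfg.n_samples):
        stats = chain.step()
        draws[it] = chain.z
        for k in rec:
            rec[k][it] = float(stats[k])
    return draws, rec


def run_nuts(model, cfg: SamplerConfig | None = None, **kwargs) -> PosteriorResults:
    """Run ``cfg.n_chains`` independent NUTS chains on an :class:`ERPModel`.

    Draws are returned in constrained space together with the pointwise
    log-likelihood matrix and per-iteration sampler statistics.
    """
    cfg = cfg or SamplerConfig()
    if kwargs:
        cfg = cfg.replace(**kwargs)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    all_draws, all_stats = [], []
    failures = []
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        try:
            draws, rec = _run_single_chain(model, cfg, rng)
        except RuntimeError as err:
            failures.append(str(err))
            continue
        all_draws.append(draws)
        all_stats.append(rec)
    if not all_draws:
        raise RuntimeError(
            f"all {cfg.n_chains} chains failed at initialization "
            f"(strategy {cfg.init_strategy!r}): {failures[0]}"
        )
    zeta = np.stack(all_draws)  # (C, S, k) unconstrained
    draws = np.exp(zeta)
    stats = {k: np.stack([s[k] for s in all_stats]) for k in all_stats[0]}
    samples = PosteriorSamples(
        draws=draws,
        param_names=model.free_names,
        pointwise_loglik=pointwise_loglik_matrix(model, draws),
        stats=stats,
        method="nuts",
    )
    return PosteriorResults(model, samples, extra={"config": cfg, "init_failures": failures})
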