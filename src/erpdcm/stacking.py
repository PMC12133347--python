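"""Stacking of Bayesian predictive distributions over chains or models.

Given leave-one-out predictive densities ``p(y_i | y_-i, M_k)`` for K
members (chains or models), stacking finds simplex weights maximizing the
average leave-one-out log score

    max_w  (1/n) sum_i log sum_k w_k p_ik,   w >= 0, sum w = 1.

The optimum smooths out chains stuck in phantom posterior modes: members
with poor predictive power receive (near-)zero weight, unlike naive
pooling which mixes every chain equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, softmax

from .engines.results import PosteriorSamples
from .selection import psis_loo

__all__ = [
    "StackingResult",
    "stacking_weights",
    "stacking_objective",
    "chain_pointwise_loo",
    "pool_chains",
    "stack_chains",
]

_RIDGE = 1e-8  # tie-break toward uniform weights


@dataclass
class StackingResult:
    weights: np.ndarray
    objective: float  # achieved average leave-one-out log score
    member_elpds: np.ndarray  # (K, n) pointwise log predictive densities


def stacking_objective(weights, log_pointwise: np.ndarray) -> float:
    """(1/n) sum_i log sum_k w_k p_ik, from log densities."""
    w = np.asarray(weights, dtype=float)
    lpw = np.asarray(log_pointwise, dtype=float)
    with np.errstate(divide="ignore"):
        lw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
    return float(np.mean(logsumexp(lpw + lw[:, None], axis=0)))


def stacking_weights(pointwise_predictive, log: bool = True) -> StackingResult:
    """Maximize the stacked leave-one-out log score over the simplex.

    ``pointwise_predictive`` is a (K members x n points) array of
    leave-one-out predictive densities, log-scale by default
    (``log=False`` accepts raw positive densities).  Members with any
    non-finite entry are dropped with a warning.  The simplex constraint is
    handled by a softmax reparametrization with multiple starts; exact ties
    are broken toward uniform weights by a tiny L2 ridge.
    """
    lpw = np.asarray(pointwise_predictive, dtype=float)
    if lpw.ndim != 2:
        raise ValueError(f"expected (K, n) array, got shape {lpw.shape}")
    if not log:
        if np.any(lpw <= 0):
            raise ValueError("densities must be positive (or pass log=True)")
        lpw = np.log(lpw)
    K_all = lpw.shape[0]
    keep = np.all(np.isfinite(lpw), axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} member(s) with non-finite predictive density"
        )
    lpw_k = lpw[keep]
    K = lpw_k.shape[0]
    if K == 0:
        raise ValueError("no member with finite predictive densities")
    if K == 1:
        w_full = np.zeros(K_all)
        w_full[np.flatnonzero(keep)[0]] = 1.0
        return StackingResult(w_full, stacking_objective(w_full[keep], lpw_k), lpw)

    def neg(a):
        w = softmax(a)
        # gradient of mean log-mixture wrt w, chained through softmax
        lmix = logsumexp(lpw_k + np.log(np.maximum(w, 1e-300))[:, None], axis=0)
        dw = np.mean(np.exp(lpw_k - lmix[None, :]), axis=1)
        pen = _RIDGE * (w - 1.0 / K)
        obj = stacking_objective(w, lpw_k) - _RIDGE / 2.0 * float(np.sum((w - 1.0 / K) ** 2))
        g_w = dw - pen
        g_a = w * (g_w - float(w @ g_w))
        return -obj, -g_a

    starts = [np.zeros(K)]
    starts.extend(5.0 * np.eye(K))
    rng = np.random.default_rng(0)
    starts.extend(rng.normal(size=(3, K)))
    best = None
    for a0 in starts:
        res = optimize.minimize(neg, a0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    w = softmax(best.x)
    w_full = np.zeros(K_all)
    w_full[keep] = w
    return StackingResult(
        weights=w_full,
        objective=stacking_objective(w, lpw_k),
        member_elpds=lpw,
    )


def chain_pointwise_loo(samples: PosteriorSamples) -> np.ndarray:
    """Per-chain PSIS-LOO pointwise log predictive densities, (C, n)."""
    C = samples.n_chains
    out = np.empty((C, samples.pointwise_loglik.shape[2]))
    for c in range(C):
        out[c] = psis_loo(samples.pointwise_loglik[c]).pointwise
    return out


def pool_chains(samples: PosteriorSamples) -> PosteriorSamples:
    """Concatenate all chains with equal weight into one chain."""
    return PosteriorSamples(
        draws=samples.flat()[None, :, :],
        param_names=samples.param_names,
        pointwise_loglik=samples.pointwise_loglik.reshape(1, -1, samples.pointwise_loglik.shape[2]),
        stats={},
        method=samples.method + "+pooled",
    )


def stack_chains(
    samples: PosteriorSamples, result: StackingResult, n_out: int, seed: int
) -> PosteriorSamples:
    """Resample draws chain-by-weight into a single stacked chain."""
    w = np.asarray(result.weights, dtype=float)
    if w.shape != (samples.n_chains,):
        raise ValueError("weight vector length must equal the number of chains")
    if abs(w.sum() - 1.0) > 1e-8 or np.any(w < 0):
        raise ValueError("weights must be a probability vector")
    rng = np.random.default_rng(seed)
    chain_idx = rng.choice(samples.n_chains, size=n_out, p=w)
    draw_idx = rng.integers(0, samples.n_draws, size=n_out)
    draws = samples.draws[chain_idx, draw_idx][None, :, :]
    ll = samples.pointwise_loglik[chain_idx, draw_idx][None, :, :]
    return PosteriorSamples(
        draws=draws,
        param_names=samples.param_names,
        pointwise_loglik=ll,
        stats={"source_chain": chain_idx[None, :]},
        method=samples.method + "+stacked",
    )
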