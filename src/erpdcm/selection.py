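"""Model comparison: information criteria, evidence approximations, reduced models.

All criteria are reported on the deviance scale (-2 x predictive density),
so smaller is better for every column of a comparison table; the positive
expected-log-predictive-density convention is stored alongside.

* AIC / BIC penalize the maximum log-likelihood by parameter count.
* WAIC combines the log pointwise predictive density with a variance-based
  effective parameter count estimated from posterior draws.
* PSIS-LOO approximates exact leave-one-out cross-validation with
  Pareto-smoothed importance weights, with a per-point shape diagnostic.
* VI engines contribute their final (smoothed) ELBO as a free-energy score.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .params import CONNECTIVITY_GAINS

__all__ = [
    "aic",
    "bic",
    "waic",
    "psis_loo",
    "WAICResult",
    "LOOResult",
    "ComparisonScores",
    "reduced_model",
    "fit_mle",
    "score_model",
    "compare_models",
]


def aic(max_loglik: float, k: int) -> float:
    """Akaike information criterion ``-2 log p(y|theta_mle) + 2k``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * max_loglik + 2.0 * k


def bic(max_loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion ``-2 log p(y|theta_mle) + k log n``."""
    if k < 0 or n < 1:
        raise ValueError("need k >= 0 and n >= 1")
    return -2.0 * max_loglik + k * np.log(n)


@dataclass
class WAICResult:
    lpd_hat: float
    p_waic: float
    waic: float  # deviance scale: -2 (lpd_hat - p_waic)

    @property
    def elpd(self) -> float:
        return self.lpd_hat - self.p_waic


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC from an (S draws x n points) pointwise log-likelihood matrix.

    ``lpd_hat`` is the column-wise log-mean-exp, ``p_waic`` the column-wise
    sample variance of the log-likelihood; both are summed over points.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError(f"expected (S, n) matrix, got shape {ll.shape}")
    S = ll.shape[0]
    lpd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    if S < 2:
        warnings.warn("single draw: p_waic set to 0")
        p = 0.0
    else:
        p = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WAICResult(lpd_hat=lpd, p_waic=p, waic=-2.0 * (lpd - p))


def _gpd_fit(x: np.ndarray):
    """Generalized-Pareto (k, sigma) fit to tail exceedances.

    The profile-posterior quantile estimator of Zhang & Stephens (the
    standard choice for Pareto-smoothed importance sampling), with the
    weakly informative shrinkage of the shape used there.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    prior_bs = 3.0
    m = 30 + int(np.sqrt(n))
    bs = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    bs = bs / (prior_bs * x[int(n / 4 + 0.5) - 1]) + 1.0 / x[-1]
    ks = -bs[:, None] * x[None, :]
    ks = np.mean(np.log1p(ks), axis=1)
    L = n * (np.log(-bs / ks) - ks - 1.0)
    w = 1.0 / np.sum(np.exp(L[None, :] - L[:, None]), axis=1)
    b_post = np.sum(bs * w)
    k_post = np.mean(np.log1p(-b_post * x))
    sigma = -k_post / b_post
    k_post = k_post * n / (n + 10.0) + 5.0 / (n + 10.0)  # shrink toward 0.5
    return k_post, sigma


@dataclass
class LOOResult:
    elpd_psis_loo: float  # deviance scale: -2 * sum_i pointwise
    pointwise: np.ndarray  # per-point log predictive density log p(y_i | y_-i)
    pareto_k: np.ndarray
    smoothed: bool = True

    @property
    def elpd(self) -> float:
        return float(self.pointwise.sum())


def psis_loo(pointwise_loglik: np.ndarray) -> LOOResult:
    """Pareto-smoothed importance-sampling leave-one-out cross-validation.

    Raw importance ratios for point i are ``1 / p(y_i | theta_s)``
    (normalized over draws); the largest ratios — the top 20%, at least 5 —
    are replaced by expected order statistics of a generalized Pareto
    distribution fitted to the tail, and log weights are truncated at the
    raw maximum.  Falls back to plain importance sampling with a warning
    when the tail is too short to fit.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError(f"expected (S, n) matrix, got shape {ll.shape}")
    S, n = ll.shape
    if S < 2:
        raise ValueError("PSIS-LOO needs at least 2 draws")
    log_ratios = -ll  # up to normalization
    log_ratios = log_ratios - np.max(log_ratios, axis=0, keepdims=True)
    n_tail = max(5, int(np.ceil(0.2 * S)))
    pointwise = np.empty(n)
    ks = np.empty(n)
    smoothed = n_tail < S
    if not smoothed:
        warnings.warn(
            f"too few draws (S={S}) to fit a Pareto tail of {n_tail}; "
            "using unsmoothed importance sampling"
        )
    for i in range(n):
        lw = log_ratios[:, i].copy()
        khat = np.nan
        if smoothed:
            order = np.argsort(lw)
            tail_idx = order[-n_tail:]
            cutoff = lw[order[-n_tail - 1]]
            exceed = np.exp(lw[tail_idx]) - np.exp(cutoff)
            if np.ptp(exceed) > 0:
                khat, sigma = _gpd_fit(exceed)
                if np.isfinite(khat):
                    # expected order statistics of the fitted GPD
                    p = (np.arange(1, n_tail + 1) - 0.5) / n_tail
                    if abs(khat) < 1e-12:
                        q = -sigma * np.log1p(-p)
                    else:
                        q = sigma / khat * (np.power(1.0 - p, -khat) - 1.0)
                    smoothed_tail = np.log(q + np.exp(cutoff))
                    ranks = np.argsort(lw[tail_idx])
                    new = np.empty(n_tail)
                    new[ranks] = smoothed_tail
                    lw[tail_idx] = np.minimum(new, lw.max())
        ks[i] = khat
        # self-normalized weighted predictive density
        lw = lw - logsumexp(lw)
        pointwise[i] = logsumexp(lw + ll[:, i])
    return LOOResult(
        elpd_psis_loo=-2.0 * float(pointwise.sum()),
        pointwise=pointwise,
        pareto_k=ks,
        smoothed=smoothed,
    )


# ---------------------------------------------------------------------------
# model-level machinery


def reduced_model(model, zero_param: str):
    """Clamp one connectivity gain to zero and drop it from inference."""
    if zero_param not in CONNECTIVITY_GAINS:
        raise ValueError(
            f"only connectivity gains {CONNECTIVITY_GAINS} can be reduced, got {zero_param!r}"
        )
    from .model import ERPModel

    mask = tuple(sorted(set(model.reduced_mask) | {zero_param}))
    return ERPModel(
        model.observation,
        priors=model.priors,
        sigma_obs=model.sigma_obs,
        reduced_mask=mask,
    )


def fit_mle(model, results=None, starts=None) -> tuple[np.ndarray, float]:
    """Maximize the likelihood alone; returns (free_theta_mle, max_loglik).

    Started from the posterior mean and the best posterior draw when a
    results object is given (keeping the better optimum), or from supplied
    free-parameter vectors.
    """
    cand = []
    if results is not None:
        cand.append(results.mean)
        flat_ll = results.samples.pointwise_loglik.reshape(results.samples.n_chains * results.samples.n_draws, -1).sum(axis=1)
        cand.append(results.samples.flat()[int(np.argmax(flat_ll))])
    if starts is not None:
        cand.extend(np.asarray(s, dtype=float) for s in starts)
    if not cand:
        raise ValueError("fit_mle needs a results object or explicit starts")

    def neg(zeta):
        ll, g = model.loglik_grad_unconstrained(zeta)
        if not np.isfinite(ll):
            return 1e30, np.zeros_like(zeta)
        return -ll, -g

    best = None
    for theta0 in cand:
        res = optimize.minimize(
            neg, np.log(theta0), jac=True, method="L-BFGS-B",
            options={"maxiter": 1000, "gtol": 1e-10, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x), -float(best.fun)


@dataclass
class ComparisonScores:
    """All criteria for one fitted model on one observation series."""

    name: str
    k: int
    n: int
    aic: float
    bic: float
    lpd_hat: float
    p_waic: float
    waic: float
    elpd_psis_loo: float
    pareto_k: np.ndarray = field(repr=False)
    rmse_fit: float = np.nan
    elbo: float | None = None
    data_fingerprint: str = ""


def _fingerprint(y: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(y).tobytes()).hexdigest()[:16]


def score_model(results, name: str = "model") -> ComparisonScores:
    """Compute every criterion from one :class:`PosteriorResults`."""
    model = results.model
    ll = results.samples.pointwise_loglik.reshape(-1, model.n_obs)
    w = waic(ll)
    loo = psis_loo(ll)
    _, max_ll = fit_mle(model, results)
    from .diagnostics import rmse_fit as _rmse_fit

    return ComparisonScores(
        name=name,
        k=model.k,
        n=model.n_obs,
        aic=aic(max_ll, model.k),
        bic=bic(max_ll, model.k, model.n_obs),
        lpd_hat=w.lpd_hat,
        p_waic=w.p_waic,
        waic=w.waic,
        elpd_psis_loo=loo.elpd_psis_loo,
        pareto_k=loo.pareto_k,
        rmse_fit=_rmse_fit(results, model),
        elbo=results.extra.get("elbo"),
        data_fingerprint=_fingerprint(model.observation.y),
    )


def compare_models(scores) -> pd.DataFrame:
    """Rank >= 2 scored models; all must be scored on the same observation.

    Returns a table sorted by WAIC with per-criterion ranks, flagging
    whether the criteria agree on the best and worst model.
    """
    scores = list(scores)
    if len(scores) < 2:
        raise ValueError("need at least two models to compare")
    prints = {s.data_fingerprint for s in scores}
    if len(prints) > 1:
        raise ValueError("models were scored on different observations; comparison rejected")
    df = pd.DataFrame(
        {
            "model": [s.name for s in scores],
            "k": [s.k for s in scores],
            "aic": [s.aic for s in scores],
            "bic": [s.bic for s in scores],
            "waic": [s.waic for s in scores],
            "psis_loo": [s.elpd_psis_loo for s in scores],
            "elbo": [s.elbo for s in scores],
            "rmse_fit": [s.rmse_fit for s in scores],
        }
    ).set_index("model")
    crits = ["aic", "bic", "waic", "psis_loo"]
    for c in crits:
        df[f"rank_{c}"] = df[c].rank(method="min").astype(int)
    best = {c: df[c].idxmin() for c in crits}
    worst = {c: df[c].idxmax() for c in crits}
    df.attrs["best_by"] = best
    df.attrs["worst_by"] = worst
    df.attrs["criteria_agree"] = len(set(best.values())) == 1 and len(set(worst.values())) == 1
    return df.sort_values("waic")
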