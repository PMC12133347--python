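"""Convergence and accuracy diagnostics for fitted posteriors.

Split rank-normalized R-hat and bulk/tail effective sample sizes follow the
modern split-chain, rank-normalized definitions (delegated to arviz, which
implements exactly those estimators).  On top of them sit the accuracy
metrics used throughout the workflow: posterior z-scores against the
generative truth, the fit RMSE of the posterior-mean prediction, the
relative parameter RMSE, and the faithful-fit classification at the 0.25
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import NMMParameters

__all__ = [
    "FAITHFUL_RMSE_THRESHOLD",
    "FitDiagnostics",
    "split_rhat",
    "ess_bulk",
    "ess_tail",
    "z_scores",
    "rmse_fit",
    "rmse_params",
    "compute_diagnostics",
]

#: a posterior-mean prediction with RMSE at or below this is a faithful fit
FAITHFUL_RMSE_THRESHOLD = 0.25


def _as_chain_draw(draws) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"expected (chains, iterations) draws, got shape {arr.shape}")
    return arr


def _degenerate(arr) -> bool:
    return bool(np.all(arr == arr.flat[0]))


def split_rhat(draws) -> float:
    """Split rank-normalized potential-scale-reduction factor.

    Each chain is split in halves, pooled draws are rank-normalized through
    the inverse-normal transform of fractional ranks, and the classic
    between/within variance ratio is computed over the split chains.
    Constant input yields NaN with a warning.
    """
    import arviz as az

    arr = _as_chain_draw(draws)
    if arr.shape[1] < 2:
        raise ValueError("split R-hat needs at least 2 iterations per chain")
    if _degenerate(arr):
        warnings.warn("constant draws: split R-hat undefined, returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr, method="rank"))


def ess_bulk(draws) -> float:
    """Bulk effective sample size on rank-normalized split chains."""
    import arviz as az

    arr = _as_chain_draw(draws)
    if arr.shape[1] < 4:
        raise ValueError("ESS needs at least 4 iterations per chain")
    if _degenerate(arr):
        warnings.warn("constant draws: ESS undefined, returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(arr, method="bulk"))


def ess_tail(draws) -> float:
    """Tail ESS: minimum over the 5% and 95% quantile indicator series."""
    import arviz as az

    arr = _as_chain_draw(draws)
    if arr.shape[1] < 4:
        raise ValueError("ESS needs at least 4 iterations per chain")
    if _degenerate(arr):
        warnings.warn("constant draws: ESS undefined, returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(arr, method="tail"))


def z_scores(results, truth: NMMParameters) -> np.ndarray:
    """(posterior mean - truth) / posterior sd, per free parameter."""
    from .params import PARAM_NAMES

    names = results.param_names
    truth_arr = np.array([truth.to_array()[PARAM_NAMES.index(n)] for n in names])
    mean = results.mean
    sd = results.sd
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-sd) posterior: z-scores undefined")
    return (mean - truth_arr) / sd


def rmse_fit(results, model) -> float:
    """RMSE between the data and the noise-free posterior-mean prediction.

    An unstable posterior-mean draw yields ``inf``.
    """
    pred = model.predict(results.posterior_mean_params())
    if not np.all(np.isfinite(pred)):
        return float("inf")
    return float(np.sqrt(np.mean((model.observation.y - pred) ** 2)))


def rmse_params(results, truth: NMMParameters) -> float:
    """Root-mean-square of relative errors of the posterior means.

    Relative errors put the ten parameters — whose magnitudes span two
    orders — on a common scale.
    """
    from .params import PARAM_NAMES

    names = results.param_names
    truth_arr = np.array([truth.to_array()[PARAM_NAMES.index(n)] for n in names])
    rel = (results.mean - truth_arr) / truth_arr
    return float(np.sqrt(np.mean(rel**2)))


@dataclass
class FitDiagnostics:
    """Per-parameter convergence metrics and scalar accuracy summaries."""

    param_names: tuple
    r_hat: np.ndarray
    ess_bulk: np.ndarray
    ess_tail: np.ndarray
    rel_ess_bulk: np.ndarray
    rel_ess_tail: np.ndarray
    z_score: np.ndarray | None
    rmse_fit: float
    rmse_params: float | None
    n_divergent: int
    faithful: bool


def compute_diagnostics(results, truth: NMMParameters | None = None) -> FitDiagnostics:
    """Assemble the full diagnostics record for one fitted posterior."""
    draws = results.samples.draws
    total = draws.shape[0] * draws.shape[1]
    kk = draws.shape[2]
    rh = np.array([split_rhat(draws[:, :, i]) for i in range(kk)])
    eb = np.array([ess_bulk(draws[:, :, i]) for i in range(kk)])
    et = np.array([ess_tail(draws[:, :, i]) for i in range(kk)])
    rf = rmse_fit(results, results.model)
    return FitDiagnostics(
        param_names=results.param_names,
        r_hat=rh,
        ess_bulk=eb,
        ess_tail=et,
        rel_ess_bulk=eb / total,
        rel_ess_tail=et / total,
        z_score=None if truth is None else z_scores(results, truth),
        rmse_fit=rf,
        rmse_params=None if truth is None else rmse_params(results, truth),
        n_divergent=results.n_divergent,
        faithful=bool(rf <= FAITHFUL_RMSE_THRESHOLD),
    )
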