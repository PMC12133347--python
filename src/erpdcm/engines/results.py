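"""Posterior containers shared by every inference back-end.

:class:`PosteriorSamples` is the raw chains-by-draws record (constrained
draws, pointwise log-likelihood matrix, per-iteration sampler statistics).
:class:`PosteriorResults` wraps it together with the fitted model and
carries the user-facing API: summary table, convergence diagnostics,
information criteria and export helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PosteriorSamples", "PosteriorResults", "pointwise_loglik_matrix"]


def pointwise_loglik_matrix(model, draws: np.ndarray) -> np.ndarray:
    """Pointwise log-likelihood for every draw; shape (chains, iters, N)."""
    c, s, k = draws.shape
    out = np.empty((c, s, model.n_obs))
    for i in range(c):
        for j in range(s):
            out[i, j] = model.pointwise_loglik(model.params_from_free(draws[i, j]))
    return out


@dataclass
class PosteriorSamples:
    """chains x iterations x free-parameters draws plus bookkeeping."""

    draws: np.ndarray  # (C, S, k), constrained space
    param_names: tuple
    pointwise_loglik: np.ndarray  # (C, S, N)
    stats: dict = field(default_factory=dict)  # per-iteration arrays, (C, S)
    method: str = ""

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @property
    def k(self) -> int:
        return self.draws.shape[2]

    def flat(self) -> np.ndarray:
        """All draws pooled, shape (C*S, k)."""
        return self.draws.reshape(-1, self.k)


class PosteriorResults:
    """Results object returned by :meth:`erpdcm.model.ERPModel.fit`."""

    def __init__(self, model, samples: PosteriorSamples, extra: dict | None = None):
        self.model = model
        self.samples = samples
        self.extra = extra or {}

    # -- basic posterior summaries ---------------------------------------
    @property
    def param_names(self):
        return self.samples.param_names

    @property
    def mean(self) -> np.ndarray:
        return self.samples.flat().mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.samples.flat().std(axis=0, ddof=1)

    def posterior_mean_params(self):
        return self.model.params_from_free(self.mean)

    def summary(self) -> pd.DataFrame:
        """Per-parameter mean, sd, quantiles, R-hat and ESS."""
        from .. import diagnostics as diag

        flat = self.samples.flat()
        q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
        rows = {
            "mean": self.mean,
            "sd": self.sd,
            "hdi_2.5%": q[0],
            "median": q[1],
            "hdi_97.5%": q[2],
            "r_hat": [diag.split_rhat(self.samples.draws[:, :, i]) for i in range(self.samples.k)],
            "ess_bulk": [diag.ess_bulk(self.samples.draws[:, :, i]) for i in range(self.samples.k)],
            "ess_tail": [diag.ess_tail(self.samples.draws[:, :, i]) for i in range(self.samples.k)],
        }
        return pd.DataFrame(rows, index=list(self.param_names))

    # -- diagnostics ------------------------------------------------------
    def diagnostics(self, truth=None):
        from ..diagnostics import compute_diagnostics

        return compute_diagnostics(self, truth=truth)

    def rmse_fit(self) -> float:
        from ..diagnostics import rmse_fit

        return rmse_fit(self, self.model)

    def z_scores(self, truth) -> np.ndarray:
        from ..diagnostics import z_scores

        return z_scores(self, truth)

    @property
    def n_divergent(self) -> int:
        d = self.samples.stats.get("diverging")
        return int(np.sum(d)) if d is not None else 0

    # -- model comparison --------------------------------------------------
    def waic(self):
        from ..selection import waic

        ll = self.samples.pointwise_loglik.reshape(-1, self.model.n_obs)
        return waic(ll)

    def psis_loo(self):
        from ..selection import psis_loo

        ll = self.samples.pointwise_loglik.reshape(-1, self.model.n_obs)
        return psis_loo(ll)

    # -- export ------------------------------------------------------------
    def to_inference_data(self):
        """In-memory arviz InferenceData: posterior / sample_stats / log_likelihood."""
        import arviz as az

        posterior = {
            name: self.samples.draws[:, :, i] for i, name in enumerate(self.param_names)
        }
        sample_stats = {k: v for k, v in self.samples.stats.items()}
        return az.from_dict(
            posterior=posterior,
            sample_stats=sample_stats or None,
            log_likelihood={"y": self.samples.pointwise_loglik},
        )

    def summary_to_csv(self, path) -> None:
        self.summary().to_csv(path, index_label="parameter")
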