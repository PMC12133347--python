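"""The probabilistic model: Gamma priors x Gaussian likelihood over an ERP series.

:class:`ERPModel` ties together a prior set, an observation series and an
optional reduced-model mask, and exposes the log-joint density and its exact
gradient in an unconstrained (componentwise log) parametrization.  Inference
engines (:mod:`erpdcm.engines`) consume only this surface, so NUTS, ADVI and
the Laplace approximation all see one model object.

Model:

    theta_j ~ Gamma(shape_j, scale_j)            (independent, j = 1..10)
    y_i | theta ~ Normal(x9(t_i; theta), sigma_obs)   (i = 1..N)

with ``x9(t; theta)`` the Euler-integrated pyramidal voltage, downsampled to
the observation grid.  ``sigma_obs`` is fixed at its generative value (0.1 by
default); the observation noise is not inferred.  A reduced model clamps a
subset of the connectivity gains {g1..g4} to exactly zero and removes them
from the sampled vector, so the unconstrained dimension is ``10 - |mask|``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _kernels, nmm
from .data import ObservationSeries
from .params import CONNECTIVITY_GAINS, NMMParameters, PARAM_NAMES
from .priors import DEFAULT_PRIORS, GammaPriorSet, sample_prior_tails

__all__ = ["ERPModel", "log_prior"]

_LOG_2PI = math.log(2.0 * math.pi)


def log_prior(params: NMMParameters, priors: GammaPriorSet = DEFAULT_PRIORS) -> float:
    """Sum of the ten marginal Gamma log-densities; -inf off the positive orthant."""
    terms = priors.log_pdf_terms(params.to_array())
    return float(terms.sum())


class ERPModel:
    """Bayesian neural-mass model of one observed ERP series.

    Parameters
    ----------
    observation
        The observed (noisy, downsampled) pyramidal voltage.
    priors
        Gamma prior set; defaults to the study priors.
    sigma_obs
        Likelihood sd.  Defaults to the observation's recorded noise sd.
    reduced_mask
        Iterable of connectivity-gain names ({"g1".."g4"}) structurally fixed
        to zero and excluded from inference.
    """

    def __init__(
        self,
        observation: ObservationSeries,
        priors: GammaPriorSet = DEFAULT_PRIORS,
        sigma_obs: float | None = None,
        reduced_mask=(),
    ):
        self.observation = observation
        self.priors = priors
        self.sigma_obs = float(observation.sigma_obs if sigma_obs is None else sigma_obs)
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be positive")
        mask = tuple(sorted(set(reduced_mask), key=PARAM_NAMES.index))
        for name in mask:
            if name not in CONNECTIVITY_GAINS:
                raise ValueError(
                    f"only connectivity gains {CONNECTIVITY_GAINS} can be masked, got {name!r}"
                )
        self.reduced_mask = mask
        self._free = np.array([n not in mask for n in PARAM_NAMES])
        self.free_names = tuple(n for n in PARAM_NAMES if n not in mask)
        # simulation grid implied by the observation spacing
        self.dt = nmm.DEFAULT_DT
        self.downsample = observation.downsample_factor
        self.n_steps = (len(observation) - 1) * self.downsample
        self._y = observation.y
        self._gamma_norm_free = float(
            np.sum(
                -gammaln(priors.shapes[self._free])
                - priors.shapes[self._free] * np.log(priors.scales[self._free])
            )
        )

    # -- dimensions -----------------------------------------------------
    @property
    def k(self) -> int:
        """Number of free (inferred) parameters."""
        return int(self._free.sum())

    @property
    def n_obs(self) -> int:
        return len(self._y)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, time_col="time_ms", value_col="y", **kw):
        """Build a model from a two-column time/value table (times in ms)."""
        times = np.asarray(frame[time_col], dtype=float)
        y = np.asarray(frame[value_col], dtype=float)
        ds = 1
        if len(times) >= 2:
            ds = max(1, int(round((times[1] - times[0]) / nmm.DEFAULT_DT)))
        obs = ObservationSeries(times=times, y=y, downsample_factor=ds)
        return cls(obs, **kw)

    # -- parameter packing ----------------------------------------------
    def full_theta(self, free_theta: np.ndarray) -> np.ndarray:
        """Expand a free-parameter vector to all ten slots (masked gains = 0)."""
        free_theta = np.asarray(free_theta, dtype=np.float64)
        full = np.zeros(10)
        full[self._free] = free_theta
        return full

    def params_from_free(self, free_theta: np.ndarray) -> NMMParameters:
        return NMMParameters.from_array(self.full_theta(free_theta))

    def free_from_params(self, params: NMMParameters) -> np.ndarray:
        return params.to_array()[self._free]

    # -- transforms ------------------------------------------------------
    def to_unconstrained(self, free_theta: np.ndarray) -> np.ndarray:
        """Componentwise log map of the free parameters."""
        free_theta = np.asarray(free_theta, dtype=np.float64)
        if np.any(free_theta <= 0):
            raise ValueError("free parameters must be strictly positive")
        return np.log(free_theta)

    def from_unconstrained(self, zeta: np.ndarray) -> np.ndarray:
        """Inverse (exp) map; the log-|Jacobian| of exp is ``zeta.sum()``."""
        return np.exp(np.asarray(zeta, dtype=np.float64))

    def log_abs_det_jacobian(self, zeta: np.ndarray) -> float:
        return float(np.sum(zeta))

    # -- densities -------------------------------------------------------
    def predict(self, params: NMMParameters) -> np.ndarray:
        """Noise-free downsampled pyramidal voltage; NaN past a blow-up."""
        y, _ = _kernels.euler_observe(
            params.to_array(), self.dt, self.n_steps, self.downsample, nmm.BLOWUP_BOUND
        )
        return y

    def log_prior(self, params: NMMParameters) -> float:
        """Prior log-density over the free parameters (masked entries contribute 0)."""
        terms = self.priors.log_pdf_terms(params.to_array())
        return float(terms[self._free].sum())

    def pointwise_loglik(self, params: NMMParameters) -> np.ndarray:
        """Per-observation Gaussian log-density; a -inf vector when unstable."""
        pred, stable = _kernels.euler_observe(
            params.to_array(), self.dt, self.n_steps, self.downsample, nmm.BLOWUP_BOUND
        )
        if not stable:
            return np.full(self.n_obs, -np.inf)
        s2 = self.sigma_obs**2
        return -0.5 * _LOG_2PI - math.log(self.sigma_obs) - 0.5 * (self._y - pred) ** 2 / s2

    def log_likelihood(self, params: NMMParameters) -> float:
        return float(self.pointwise_loglik(params).sum())

    def log_joint(self, params: NMMParameters) -> float:
        lp = self.log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(params)

    # -- unconstrained-space callables for the engines -------------------
    def logp_unconstrained(self, zeta: np.ndarray) -> float:
        """log-joint plus the exp-map log-Jacobian, as a function of zeta."""
        return self.logp_grad_unconstrained(zeta, want_grad=False)[0]

    def logp_grad_unconstrained(self, zeta: np.ndarray, want_grad: bool = True):
        """Return ``(logp, grad)`` of the unconstrained target density.

        The gradient is exact for the discrete Euler simulator (forward
        sensitivities), so Hamiltonian trajectories and ELBO gradients are
        consistent with the density they explore.  Unstable draws map to
        ``(-inf, zeros)``; samplers treat them as divergences.
        """
        zeta = np.asarray(zeta, dtype=np.float64)
        if zeta.shape != (self.k,):
            raise ValueError(f"expected shape ({self.k},), got {zeta.shape}")
        with np.errstate(over="ignore"):
            free_theta = np.exp(zeta)
        if not np.all(np.isfinite(free_theta) & (free_theta > 1e-10) & (free_theta < 1e10)):
            return -np.inf, (np.zeros(self.k) if want_grad else None)
        full = self.full_theta(free_theta)
        shapes = self.priors.shapes[self._free]
        scales = self.priors.scales[self._free]
        # Gamma log-prior + log|Jacobian| collapses to shape*zeta - theta/scale
        lp_prior = float(np.sum(shapes * zeta - free_theta / scales)) + self._gamma_norm_free
        grad = None
        if want_grad:
            pred, sens, stable = _kernels.euler_observe_sens(
                full, self.dt, self.n_steps, self.downsample, nmm.BLOWUP_BOUND
            )
        else:
            pred, stable = _kernels.euler_observe(
                full, self.dt, self.n_steps, self.downsample, nmm.BLOWUP_BOUND
            )
            sens = None
        if not stable:
            return -np.inf, (np.zeros(self.k) if want_grad else None)
        s2 = self.sigma_obs**2
        resid = self._y - pred
        loglik = (
            self.n_obs * (-0.5 * _LOG_2PI - math.log(self.sigma_obs))
            - 0.5 * float(resid @ resid) / s2
        )
        logp = lp_prior + loglik
        if want_grad:
            dl_dtheta = (resid @ sens[:, self._free]) / s2
            grad = shapes - free_theta / scales + dl_dtheta * free_theta
        return logp, grad

    def loglik_grad_unconstrained(self, zeta: np.ndarray):
        """``(log-likelihood, gradient)`` alone (no prior), as a function of zeta.

        Used for maximum-likelihood fits backing AIC/BIC.
        """
        zeta = np.asarray(zeta, dtype=np.float64)
        with np.errstate(over="ignore"):
            free_theta = np.exp(zeta)
        if not np.all(np.isfinite(free_theta) & (free_theta > 1e-10) & (free_theta < 1e10)):
            return -np.inf, np.zeros(self.k)
        full = self.full_theta(free_theta)
        pred, sens, stable = _kernels.euler_observe_sens(
            full, self.dt, self.n_steps, self.downsample, nmm.BLOWUP_BOUND
        )
        if not stable:
            return -np.inf, np.zeros(self.k)
        s2 = self.sigma_obs**2
        resid = self._y - pred
        loglik = (
            self.n_obs * (-0.5 * _LOG_2PI - math.log(self.sigma_obs))
            - 0.5 * float(resid @ resid) / s2
        )
        grad = (resid @ sens[:, self._free]) / s2 * free_theta
        return loglik, grad

    # -- initialization draws --------------------------------------------
    def draw_prior(self, rng: np.random.Generator) -> np.ndarray:
        """A free-parameter draw from the prior (random init strategy)."""
        return self.priors.sample(rng)[self._free]

    def draw_prior_tails(self, rng: np.random.Generator, tail_mass: float = 0.025) -> np.ndarray:
        """A free-parameter draw uniform in the prior tails (see the priors module)."""
        return sample_prior_tails(self.priors, rng, tail_mass).to_array()[self._free]

    # -- fitting ----------------------------------------------------------
    def fit(self, method: str = "nuts", config=None, seed: int = 0, **kwargs):
        """Fit the model and return a :class:`~erpdcm.engines.results.PosteriorResults`.

        ``method`` is one of ``"nuts"``, ``"meanfield"``, ``"fullrank"``,
        ``"laplace"``.  Extra keyword arguments override fields of the
        relevant config (:class:`SamplerConfig` for NUTS, :class:`VIConfig`
        otherwise).
        """
        from .engines import run_advi, run_laplace, run_nuts
        from .engines.config import SamplerConfig, VIConfig

        method = method.lower()
        if method == "nuts":
            cfg = config or SamplerConfig(seed=seed)
            if kwargs:
                cfg = cfg.replace(**kwargs)
            return run_nuts(self, cfg)
        if method in ("meanfield", "mean_field", "fullrank", "full_rank"):
            guide = "mean_field" if method.startswith("mean") else "full_rank"
            cfg = config or VIConfig(guide=guide, seed=seed)
            if kwargs:
                cfg = cfg.replace(**kwargs)
            return run_advi(self, cfg)
        if method == "laplace":
            cfg = config or VIConfig(guide="laplace", seed=seed)
            if kwargs:
                cfg = cfg.replace(**kwargs)
            return run_laplace(self, cfg)
        raise ValueError(f"unknown inference method {method!r}")
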