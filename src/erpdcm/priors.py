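"""Gamma priors over the neural-mass parameters.

Each of the ten parameters carries an independent Gamma(shape, scale) prior.
The defaults are the weakly informative priors used to generate the study
conditions; they concentrate around the true values while leaving roughly
half of all joint prior draws dynamically unstable, which is what makes the
inversion problem genuinely hard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy import stats

from .params import NMMParameters, PARAM_NAMES

__all__ = ["GammaPriorSet", "DEFAULT_PRIORS", "sample_prior_tails"]

# parameter -> (shape, scale)
_DEFAULT_TABLE = {
    "g1": (18.16, 0.03),
    "g2": (29.9, 0.02),
    "g3": (29.14, 0.005),
    "g4": (30.77, 0.007),
    "delta": (22.87, 0.51),
    "tau_i": (34.67, 0.23),
    "h_i": (20.44, 0.96),
    "tau_e": (33.02, 0.16),
    "h_e": (24.17, 0.07),
    "u": (23.62, 0.13),
}

# guards for inverting the Gamma CDF in the unbounded upper tail
_Q_FLOOR = 1e-6
_Q_CEIL = 1.0 - 1e-6


@dataclass(frozen=True)
class GammaPriorSet:
    """Per-parameter Gamma(shape, scale) pairs, in canonical parameter order."""

    shapes: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shapes", np.asarray(self.shapes, dtype=np.float64))
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=np.float64))
        if self.shapes.shape != (10,) or self.scales.shape != (10,):
            raise ValueError("need one (shape, scale) pair per parameter (10)")
        if np.any(self.shapes <= 0) or np.any(self.scales <= 0):
            raise ValueError("Gamma shapes and scales must be strictly positive")

    @classmethod
    def from_mapping(cls, mapping) -> "GammaPriorSet":
        """Build from ``{name: {"shape": a, "scale": s}}`` (all ten required)."""
        shapes, scales = [], []
        for name in PARAM_NAMES:
            if name not in mapping:
                raise KeyError(f"prior for parameter {name!r} missing")
            entry = mapping[name]
            shapes.append(float(entry["shape"]))
            scales.append(float(entry["scale"]))
        return cls(np.array(shapes), np.array(scales))

    @classmethod
    def from_yaml(cls, path) -> "GammaPriorSet":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_mapping(self) -> dict:
        return {
            n: {"shape": float(a), "scale": float(s)}
            for n, a, s in zip(PARAM_NAMES, self.shapes, self.scales)
        }

    @property
    def means(self) -> np.ndarray:
        return self.shapes * self.scales

    def log_pdf_terms(self, theta: np.ndarray) -> np.ndarray:
        """Vector of the ten marginal Gamma log-densities; -inf off-support."""
        theta = np.asarray(theta, dtype=np.float64)
        out = np.full(10, -np.inf)
        ok = theta > 0
        out[ok] = stats.gamma.logpdf(theta[ok], a=self.shapes[ok], scale=self.scales[ok])
        return out

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draw from the joint (independent) prior; shape (..., 10)."""
        sz = (10,) if size is None else (size, 10)
        return rng.gamma(self.shapes, self.scales, size=sz)

    def ppf(self, q) -> np.ndarray:
        """Componentwise inverse CDF at quantile level(s) q (scalar or (10,))."""
        return stats.gamma.ppf(q, a=self.shapes, scale=self.scales)

    def cdf(self, theta) -> np.ndarray:
        return stats.gamma.cdf(theta, a=self.shapes, scale=self.scales)


DEFAULT_PRIORS = GammaPriorSet.from_mapping(
    {k: {"shape": a, "scale": s} for k, (a, s) in _DEFAULT_TABLE.items()}
)


def sample_prior_tails(
    priors: GammaPriorSet,
    seed: int | np.random.Generator,
    tail_mass: float = 0.025,
) -> NMMParameters:
    """Draw a parameter set uniformly from the tails of the prior.

    Independently per parameter: pick lower or upper tail with probability
    1/2, draw a quantile level uniformly within that tail (i.e. in
    ``[q_floor, tail_mass]`` or ``[1 - tail_mass, q_ceil]``) and invert the
    Gamma CDF.  Every component then lies outside the central
    ``1 - 2*tail_mass`` prior interval.
    """
    if not 0.0 < tail_mass < 0.5:
        raise ValueError("tail_mass must lie in (0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    upper = rng.random(10) < 0.5
    lo = np.where(upper, 1.0 - tail_mass, _Q_FLOOR)
    hi = np.where(upper, _Q_CEIL, tail_mass)
    q = rng.uniform(lo, hi)
    return NMMParameters.from_array(priors.ppf(q))
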