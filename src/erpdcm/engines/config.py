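"""Configuration surfaces for the posterior-approximation back-ends."""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

__all__ = ["SamplerConfig", "VIConfig"]


@dataclass(frozen=True)
class SamplerConfig:
    """Adaptive-HMC (NUTS) settings.

    ``init_strategy`` is one of ``"random"`` (a prior draw), ``"prior_tails"``
    (uniform draw from the 2.5%/97.5% prior tails) or ``"value"`` (use
    ``init_value``, a free-parameter vector in constrained space).
    """

    n_chains: int = 4
    n_warmup: int = 200
    n_samples: int = 200
    max_tree_depth: int = 10
    target_accept: float = 0.8
    init_strategy: str = "random"
    init_value: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.max_tree_depth < 1:
            raise ValueError("max_tree_depth must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.n_chains < 1 or self.n_warmup < 1 or self.n_samples < 1:
            raise ValueError("chain and iteration counts must be >= 1")
        if self.init_strategy not in ("random", "prior_tails", "value"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")

    def replace(self, **kw) -> "SamplerConfig":
        return _dc_replace(self, **kw)


@dataclass(frozen=True)
class VIConfig:
    """Stochastic variational inference / Laplace settings.

    ``guide`` selects the variational family: a factorized Gaussian
    (``mean_field``), a full-covariance Gaussian via a Cholesky factor
    (``full_rank``), or the quadratic expansion around the MAP
    (``laplace``).  ``n_iters`` is the fixed Adam budget; early stopping on
    an ELBO plateau is available but off by default.
    """

    guide: str = "mean_field"
    n_iters: int = 100_000
    elbo_samples: int = 1
    learning_rate: float = 0.0005
    n_chains: int = 4
    n_samples: int = 200
    init_strategy: str = "random"
    init_value: tuple | None = None
    early_stop: bool = False
    plateau_rel_tol: float = 1e-8
    plateau_window: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.guide not in ("mean_field", "full_rank", "laplace"):
            raise ValueError(f"unknown guide {self.guide!r}")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.init_strategy not in ("random", "prior_tails", "value"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")

    def replace(self, **kw) -> "VIConfig":
        return _dc_replace(self, **kw)
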