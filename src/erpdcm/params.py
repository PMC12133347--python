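"""Biophysical parameters of the three-population ERP neural mass model.

The model is governed by ten positive quantities: four effective-connectivity
gains (g1..g4), the intrinsic delay ``delta`` (ms), the excitatory and
inhibitory postsynaptic rate constants ``tau_e``/``tau_i`` (ms), the maximum
EPSP/IPSP amplitudes ``h_e``/``h_i`` (mV) and the intensity ``u`` of the
Heaviside step input driving the spiny-stellate population.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: canonical parameter ordering used by every array interface in the package
PARAM_NAMES = ("g1", "g2", "g3", "g4", "delta", "tau_i", "h_i", "tau_e", "h_e", "u")

#: the four connectivity gains eligible for reduced-model masking
CONNECTIVITY_GAINS = ("g1", "g2", "g3", "g4")


@dataclass(frozen=True)
class NMMParameters:
    """The ten parameters of the ERP neural mass model.

    All components are strictly positive in the generative model; a reduced
    model may force a connectivity gain to exactly 0 (see
    :func:`erpdcm.selection.reduced_model`).
    """

    g1: float
    g2: float
    g3: float
    g4: float
    delta: float
    tau_i: float
    h_i: float
    tau_e: float
    h_e: float
    u: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "NMMParameters":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected shape ({len(PARAM_NAMES)},), got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))

    def replace(self, **kwargs) -> "NMMParameters":
        d = {n: getattr(self, n) for n in PARAM_NAMES}
        d.update(kwargs)
        return NMMParameters(**d)


#: ground-truth parameter values used throughout to generate synthetic data
TRUE_PARAMETERS = NMMParameters(
    g1=0.42,
    g2=0.76,
    g3=0.15,
    g4=0.16,
    delta=12.13,
    tau_i=7.77,
    h_i=27.88,
    tau_e=5.77,
    h_e=1.63,
    u=3.94,
)
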