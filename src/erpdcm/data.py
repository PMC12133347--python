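"""Synthetic observation series: noisy, downsampled pyramidal voltage.

The study conditions are fixed here: the full model is integrated for
200 ms at dt = 0.1 ms from the origin with the step input active, zero-mean
Gaussian noise with standard deviation 0.1 is added to all 2001 pyramidal
voltage samples, and the noisy series is then thinned by a factor of 10
(keeping index 0), leaving N = 201 observed points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, nmm
from .params import NMMParameters

__all__ = ["ObservationSeries", "generate_observation", "load_observation", "save_observation"]

DEFAULT_SIGMA_OBS = 0.1
DEFAULT_DOWNSAMPLE = 10


@dataclass
class ObservationSeries:
    """Observed voltage ``y`` on a uniform time grid (ms)."""

    times: np.ndarray
    y: np.ndarray
    sigma_obs: float = DEFAULT_SIGMA_OBS
    downsample_factor: int = DEFAULT_DOWNSAMPLE
    seed: int | None = None
    #: noise-free downsampled signal, kept when generated synthetically
    clean: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.times.shape != self.y.shape:
            raise ValueError("times and y must have equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8):
                raise ValueError("times must be strictly increasing and uniformly spaced")

    def __len__(self) -> int:
        return len(self.y)


def generate_observation(
    params: NMMParameters,
    seed: int,
    sigma_obs: float = DEFAULT_SIGMA_OBS,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
    dt: float = nmm.DEFAULT_DT,
    duration: float = nmm.DEFAULT_DURATION,
) -> ObservationSeries:
    """Simulate, add observation noise, then downsample.

    Noise is added to the full-resolution series (2001 points by default)
    before thinning, which keeps index 0 — hence 201 retained samples under
    defaults.  Raises if the parameter set is dynamically unstable.
    """
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be >= 0")
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    n_steps = int(round(duration / dt))
    y_full, stable = _kernels.euler_observe(
        params.to_array(), dt, n_steps, 1, nmm.BLOWUP_BOUND
    )
    if not stable:
        raise ValueError(
            f"unstable dynamics for parameter draw {params}; cannot generate observation"
        )
    rng = np.random.default_rng(seed)
    noisy = y_full + rng.normal(0.0, sigma_obs, size=y_full.shape)
    keep = slice(None, None, downsample_factor)
    times = (np.arange(n_steps + 1) * dt)[keep]
    return ObservationSeries(
        times=times,
        y=noisy[keep],
        sigma_obs=sigma_obs,
        downsample_factor=downsample_factor,
        seed=seed,
        clean=y_full[keep],
    )


def save_observation(obs: ObservationSeries, path) -> None:
    """Write a two-column CSV with a seed/sigma comment line and header."""
    with open(path, "w") as fh:
        fh.write(f"# seed={obs.seed} sigma={obs.sigma_obs}\n")
        fh.write("time_ms,y\n")
        for t, v in zip(obs.times, obs.y):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def load_observation(path) -> ObservationSeries:
    """Read a two-column time/value table written by :func:`save_observation`.

    User-supplied tables are accepted too: any header line, optional
    ``# key=value`` comments, then numeric ``time,value`` rows.
    """
    times, values = [], []
    seed, sigma = None, DEFAULT_SIGMA_OBS
    with open(path) as fh:
        lines = fh.readlines()
    data_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("seed=") and tok[5:] != "None":
                    seed = int(tok[5:])
                elif tok.startswith("sigma="):
                    sigma = float(tok[6:])
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected two comma-separated columns")
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError:
            if data_seen:
                raise ValueError(f"{path}: line {lineno}: non-numeric row {line!r}") from None
            continue  # header row
        times.append(t)
        values.append(v)
        data_seen = True
    if not data_seen:
        raise ValueError(f"{path}: no numeric data rows found")
    times = np.asarray(times)
    ds = DEFAULT_DOWNSAMPLE
    if len(times) >= 2:
        spacing = times[1] - times[0]
        ds = max(1, int(round(spacing / nmm.DEFAULT_DT)))
    return ObservationSeries(
        times=times, y=np.asarray(values), sigma_obs=sigma, downsample_factor=ds, seed=seed
    )
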