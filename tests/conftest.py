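"""Shared fixtures: the study observation and expensive shared posterior runs."""

from __future__ import annotations

import numpy as np
import pytest

from erpdcm import ERPModel, TRUE_PARAMETERS, generate_observation


@pytest.fixture(scope="session")
def study_obs():
    """The default synthetic observation series (201 noisy points)."""
    return generate_observation(TRUE_PARAMETERS, seed=42)


@pytest.fixture(scope="session")
def dcm_model(study_obs):
    return ERPModel(study_obs)


@pytest.fixture(scope="session")
def tails_run(dcm_model):
    """Eight tail-initialized NUTS chains at the study's sampling settings.

    Shared across the convergence, faithful-fit and efficiency checks so the
    expensive sampling happens once.
    """
    return dcm_model.fit(
        "nuts",
        seed=11,
        n_chains=8,
        n_warmup=200,
        n_samples=200,
        max_tree_depth=10,
        target_accept=0.8,
        init_strategy="prior_tails",
    )


def per_chain_rmse(results):
    """Fit RMSE of each chain's own posterior-mean prediction."""
    model = results.model
    out = []
    for c in range(results.samples.n_chains):
        params = model.params_from_free(results.samples.draws[c].mean(axis=0))
        pred = model.predict(params)
        if not np.all(np.isfinite(pred)):
            out.append(np.inf)
        else:
            out.append(float(np.sqrt(np.mean((model.observation.y - pred) ** 2))))
    return np.array(out)
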