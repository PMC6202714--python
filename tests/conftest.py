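"""Shared fixtures: handmade frames and reusable posterior fits.

Fits are session-scoped because MCMC is the expensive step; tests that
need a specific generating regime build their own frame instead.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from eivpool import (
    EIVChangeModel,
    McmcConfig,
    ModelFrame,
    SimParams,
    fit_model,
    simulate_survey,
)


def make_frame(y, plot, period, habitat=None, index="N") -> ModelFrame:
    """Small handmade long-format frame for unit tests."""
    n = len(y)
    habitat = habitat if habitat is not None else ["hab"] * n
    df = pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "plot": list(plot),
            "period": list(period),
            "habitat": list(habitat),
            "species": [f"sp{i}" for i in range(n)],
        }
    )
    return ModelFrame(df=df, index=index)


@pytest.fixture(scope="session")
def quick_mcmc():
    return McmcConfig(chains=2, warmup=400, draws=500, seed=17)


@pytest.fixture(scope="session")
def survey20():
    """20 plots in 2 habitats, 30 species per cell, moderate change."""
    params = SimParams(
        n_habitats=2,
        plots_per_habitat=10,
        species_per_cell=30,
        mu_alpha=(4.0, 5.0),
        mu_beta=(-0.3, 0.3),
        seed=42,
    )
    return simulate_survey(params)


@pytest.fixture(scope="session")
def m1_fit(survey20, quick_mcmc):
    frame, _ = survey20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(frame, "M1", mcmc=quick_mcmc)


@pytest.fixture(scope="session")
def m2_fit(survey20, quick_mcmc):
    frame, _ = survey20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(frame, "M2", mcmc=quick_mcmc)


@pytest.fixture(scope="session")
def m3_fit(survey20, quick_mcmc):
    frame, _ = survey20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(frame, "M3", mcmc=quick_mcmc)


def fake_fit(posterior, frame, pooling) -> EIVChangeModel:
    """Fitted model wrapped around hand-constructed draws."""
    post = {k: np.asarray(v, dtype=float) for k, v in posterior.items()}
    return EIVChangeModel._from_posterior(post, frame, pooling)
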