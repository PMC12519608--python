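"""Shared fixtures.

The expensive derivation-scale pipeline (n = 50,000 simulate -> fit ->
validate) is session-scoped so the acceptance tests share a single run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import crvalid as cv
from crvalid.simulator import scenario_configs, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

DERIVATION_SEED = 20250101
CORRECT_TERMS = ["x1", "x1**2", "x2", "x3", "C(x4)"]


def make_dataset(time, status, **covs) -> cv.SurvivalDataset:
    """Small hand-written dataset helper."""
    frame = pd.DataFrame({"time": time, "status": status})
    for name, vals in covs.items():
        frame[name] = vals
    if not covs:
        frame["x"] = 0.0
    return cv.SurvivalDataset(frame)


def random_dataset(seed: int, n: int = 200, n_causes: int = 2,
                   tie_grid: float | None = 0.25) -> cv.SurvivalDataset:
    """Random competing-risks data with heavy ties for estimator stress tests."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(2.0, size=n)
    if tie_grid:
        t = np.maximum(np.round(t / tie_grid) * tie_grid, tie_grid)
    status = rng.integers(0, n_causes + 1, size=n)
    x = rng.standard_normal(n)
    return make_dataset(t, status, x=x)


@pytest.fixture(scope="session")
def scenarios():
    return scenario_configs(n=50_000, seed=DERIVATION_SEED)


@pytest.fixture(scope="session")
def derivation_data(scenarios):
    return simulate_dataset(scenarios["derivation"])


@pytest.fixture(scope="session")
def derivation_models(derivation_data):
    return cv.fit_model_set(derivation_data, CORRECT_TERMS, df=3)


@pytest.fixture(scope="session")
def derivation_report(derivation_models, derivation_data):
    return cv.validate(derivation_models, derivation_data, 10.0)


@pytest.fixture(scope="session")
def small_sim():
    """Moderate-size simulated dataset + fitted models for cheap model tests."""
    cfg = scenario_configs(n=4000, seed=17)["derivation"]
    data = simulate_dataset(cfg)
    models = cv.fit_model_set(data, CORRECT_TERMS, df=3)
    return cfg, data, models
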