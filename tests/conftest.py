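"""Shared fixtures: a session-scoped simulated ensemble and its analysis.

The ensemble (50 replicates of each of the six fishing treatments, fast
burn-in) is simulated once and reused by the property and acceptance
tests; analysis results are cached per metric set.
"""

from __future__ import annotations

import numpy as np
import pytest

from recoverews import (SpeciesParams, build_size_grid, generate_ensemble)
from recoverews.evaluate import analyze_ensemble
from recoverews.simulator import DEFAULT_TREATMENTS

ENSEMBLE_SEED = 20_250_101
N_REPS = 50


@pytest.fixture(scope="session")
def params() -> SpeciesParams:
    return SpeciesParams()


@pytest.fixture(scope="session")
def grid():
    return build_size_grid()


@pytest.fixture(scope="session")
def ensemble(params, grid):
    """50 replicates x 6 treatments with the default calibration."""
    return generate_ensemble(params, DEFAULT_TREATMENTS, n_reps=N_REPS,
                             base_seed=ENSEMBLE_SEED, grid=grid,
                             burn_in="fast")


@pytest.fixture(scope="session")
def headline_results(ensemble):
    """Per-replicate detections for the two headline composite metrics."""
    return analyze_ensemble(
        ensemble, metrics=[("AR1", "SD_SIZE"), ("AR1", "CV", "SD_SIZE")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
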