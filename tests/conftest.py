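"""Shared fixtures: small synthetic cohorts and cached feature matrices."""

from __future__ import annotations

import functools

import numpy as np
import pytest

import sprintkan as sk
from sprintkan import emg, imc, pipeline


@functools.lru_cache(maxsize=4)
def _cohort(seed: int, n_participants: int = 30):
    cfg = sk.CohortConfig.default(seed=seed, n_participants=n_participants)
    return sk.generate_cohort(cfg)


@functools.lru_cache(maxsize=4)
def _feature_matrix(seed: int):
    cohort = _cohort(seed)
    return pipeline.build_feature_matrix(
        emg.feature_table(cohort), imc.coherence_table(cohort),
        cohort.velocities())


@functools.lru_cache(maxsize=4)
def _formula_matrix(seed: int, noise_sd: float = 0.15):
    return pipeline.apply_formula_velocities(_feature_matrix(seed), noise_sd,
                                             seed=seed)


@pytest.fixture(scope="session")
def cohort30():
    """Full default-size cohort (30 x 3 x 3), seed 0."""
    return _cohort(0)


@pytest.fixture(scope="session")
def feature_matrix():
    """270-row x1..x9 + velocity design matrix from the seed-0 cohort."""
    return _feature_matrix(0)


@pytest.fixture(scope="session")
def formula_matrix():
    """Same matrix with the closed-form-equation outcome (noise sd 0.15)."""
    return _formula_matrix(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
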