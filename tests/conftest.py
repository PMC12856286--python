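"""Shared fixtures: calibrated parameter sets, benefit models, cohorts.

Expensive objects (quadrature models, a 100k-patient twin cohort) are
session-scoped; tests that need modified parameters build small "fast"
profile models themselves.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import dxtwin as dx

# deterministic property-test runs
settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def mindact_params() -> dx.DGPParams:
    return dx.default_params("mindact")


@pytest.fixture(scope="session")
def tailorx_params() -> dx.DGPParams:
    return dx.default_params("tailorx")


@pytest.fixture(scope="session")
def mindact_model(mindact_params) -> dx.BenefitModel:
    return dx.BenefitModel(mindact_params, profile="full")


@pytest.fixture(scope="session")
def mindact_cohort(mindact_params, mindact_model):
    """100k-patient calibrated twin cohort, fixed seed."""
    config = dx.CohortConfig("mindact", n_patients=100_000, seed=42,
                             params=mindact_params)
    return dx.generate_cohort(config, model=mindact_model)


@pytest.fixture(scope="session")
def toy_params() -> dx.DGPParams:
    """Mild, uncalibrated parameters for structural tests."""
    return dx.DGPParams(s0_10=0.90, beta_c=0.5, beta_mp=0.3, beta_ot=0.4,
                        rho_c_mp=0.5, rho_c_ot=0.4, rho_mp_ot=0.6,
                        mp_latent_cutoff=0.2)


@pytest.fixture(scope="session")
def toy_model(toy_params) -> dx.BenefitModel:
    return dx.BenefitModel(toy_params, profile="fast")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
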