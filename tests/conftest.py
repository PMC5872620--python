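"""Shared fixtures: a desk-scale path-length LUT and cached evaluation runs.

The LUT uses fewer photons than the library default so the whole suite
stays fast; generation and fitting share the LUT, so Monte Carlo noise in
the table cancels out of recovery comparisons.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcdrs.evaluation import run_liquid_evaluation, run_solid_evaluation
from mcdrs.inverse import FitConfig
from mcdrs.phantoms import LiquidPhantomScenario, NoiseModel, default_solid_scenarios
from mcdrs.transport import ProbeGeometry, build_lut

settings.register_profile(
    "suite", deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    derandomize=True,
)
settings.load_profile("suite")

TEST_LUT_PHOTONS = 30_000


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def lut(geometry):
    """Full-axes LUT at test scale (5 thicknesses x 4 scattering nodes)."""
    return build_lut(
        geometry,
        tepi_grid_um=(0.0, 75.0, 150.0, 300.0, 600.0),
        musp_grid=(0.5, 1.0, 2.0, 4.0),
        n_photons=TEST_LUT_PHOTONS,
        seed=1,
    )


@pytest.fixture(scope="session")
def liquid_eval(lut):
    """Liquid time-series recovery at fRBC = 0.8%, 1% noise, 20 fits."""
    scenario = LiquidPhantomScenario(frbc=0.008, seed=5)
    return run_liquid_evaluation(scenario, lut, FitConfig(seed=2))


@pytest.fixture(scope="session")
def solid_eval(lut):
    """Solid-matrix recovery: 20 phantoms x 4 replicates, 1% noise, gated."""
    return run_solid_evaluation(
        default_solid_scenarios(), lut, FitConfig(seed=2), seed=7
    )


@pytest.fixture(scope="session")
def solid_eval_noiseless(lut):
    """Noise-free solid matrix (1 replicate) for self-consistency bounds."""
    scenarios = default_solid_scenarios(
        noise=NoiseModel(sigma_rel=0.0, dark_rel=0.0)
    )
    return run_solid_evaluation(
        scenarios, lut, FitConfig(seed=2), n_replicates=1, seed=7
    )
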