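import numpy as np
import pytest

from reappose import (DissectionGeometry, GOHParameters, SolverOptions,
                      load_flap_parameters, load_wall_parameters)


@pytest.fixture(scope="session")
def flap_params():
    return load_flap_parameters()


@pytest.fixture(scope="session")
def wall_params():
    return load_wall_parameters()


@pytest.fixture(scope="session")
def all_params(flap_params, wall_params):
    d = dict(flap_params)
    d.update(wall_params)
    return d


@pytest.fixture()
def generic_artery():
    """A moderate, well-conditioned arterial GOH set for solver benchmarks."""
    return GOHParameters(c10=80e3, k1=200e3, k2=5.0, alpha_deg=30.0,
                         kappa=0.2, thickness_mm=0.5, label="generic")


@pytest.fixture(scope="session")
def solver_options():
    return SolverOptions(member_step_mm=0.3, newton_tol=1e-6,
                         flap_drape_bias_mmhg=0.5)


@pytest.fixture(scope="session")
def mid_geometry(flap_params, wall_params):
    return DissectionGeometry.for_region(
        "mid", flap_params["mid_1"].thickness_mm,
        wall_params["mid_fl_wall"].thickness_mm,
        wall_params["tl_wall"].thickness_mm)


def rng(seed=0):
    return np.random.default_rng(seed)
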