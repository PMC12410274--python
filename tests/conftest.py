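"""Shared fixtures: one run design, aperture movie, HRF, and a coarse fit grid."""

import numpy as np
import pytest

from afield.prf_fit_glm import GridConfig, precompute_grid
from afield.prf_forward import canonical_hrf
from afield.stimulus_design import ScreenConfig, make_aperture_movie, make_run_design


@pytest.fixture(scope="session")
def design():
    return make_run_design("focused")


@pytest.fixture(scope="session")
def screen():
    # 8 px/deg: the minimum resolution contract, keeps test matrices small
    return ScreenConfig(px_per_deg=8.0)


@pytest.fixture(scope="session")
def movie(design, screen):
    return make_aperture_movie(design, screen)


@pytest.fixture(scope="session")
def hrf(design):
    return canonical_hrf(design.tr_s)


@pytest.fixture(scope="session")
def coarse_grid_config():
    # coarse exhaustive stage; the nonlinear refinement supplies precision
    return GridConfig(xy_step=0.5, n_sd=10)


@pytest.fixture(scope="session")
def grid(movie, hrf, design, coarse_grid_config):
    return precompute_grid(movie, hrf, design, grid_config=coarse_grid_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
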