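"""Shared fixtures: expensive solver setups are session-scoped."""

import pytest

from ehgsim import AbdomenModel, DipoleBandParams, ForwardSolver


@pytest.fixture(scope="session")
def band_params() -> DipoleBandParams:
    return DipoleBandParams()


@pytest.fixture(scope="session")
def abdomen_model() -> AbdomenModel:
    return AbdomenModel()


@pytest.fixture(scope="session")
def abdomen_solver(abdomen_model) -> ForwardSolver:
    """One factorized solver on the default grid, shared by all tests."""
    return ForwardSolver(abdomen_model)


@pytest.fixture(scope="session")
def coarse_model() -> AbdomenModel:
    """A coarse abdomen for fast contract/determinism tests."""
    return AbdomenModel(grid_spacing=8.0, bounding_box_half_width=120.0)


@pytest.fixture(scope="session")
def coarse_solver(coarse_model) -> ForwardSolver:
    return ForwardSolver(coarse_model)
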