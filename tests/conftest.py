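"""Shared fixtures: the default train, desk-scale grids/dictionaries and a
noiseless digital phantom acquisition reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mcmrf import (
    PhantomSpec,
    build_dictionary,
    build_grid,
    default_train,
    equivalent_lambda_norm,
    make_phantom,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def train50():
    return default_train(50)


@pytest.fixture(scope="session")
def desk_grid():
    """10%-step relaxation grid over the full protocol ranges, narrow b1."""
    return build_grid((30, 4000), (5, 3000), 0.10, (0.9, 1.1), 0.05)


@pytest.fixture(scope="session")
def desk_dict(train50, desk_grid):
    return build_dictionary(train50, desk_grid)


@pytest.fixture(scope="session")
def desk_lambda(desk_grid):
    """Grid-equivalent of the default normalized regularization (11)."""
    return equivalent_lambda_norm(desk_grid)


@pytest.fixture(scope="session")
def tiny_grid():
    """Single-b1 grid small enough for the exact inner solver."""
    return build_grid((400, 2000), (20, 1500), 0.25, (1.0, 1.0), 0.05)


@pytest.fixture(scope="session")
def tiny_dict(train50, tiny_grid):
    return build_dictionary(train50, tiny_grid)


@pytest.fixture(scope="session")
def patient_phantom(desk_grid):
    """Compact patient phantom snapped to the desk grid (noiseless truth)."""
    spec = PhantomSpec(shape=(48, 48, 2), seed=1, lesion_radius_vox=(1, 1)).snapped(desk_grid)
    return make_phantom(spec, b1_values=desk_grid.b1_values)


@pytest.fixture(scope="session")
def patient_series(patient_phantom, train50):
    return simulate_acquisition(patient_phantom, train50, snr=None)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
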