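"""Shared fixtures: the default sensor model is expensive enough to build once."""

import numpy as np
import pytest

from cryomap import (
    ConductivityField,
    SensorGeometry,
    build_mesh,
    compute_jacobian,
    forward_solve,
    generate_stim_pattern,
)


@pytest.fixture(scope="session")
def geometry():
    return SensorGeometry()


@pytest.fixture(scope="session")
def mesh(geometry):
    return build_mesh(geometry, target_elements=576)


@pytest.fixture(scope="session")
def pattern():
    return generate_stim_pattern(8)


@pytest.fixture(scope="session")
def homogeneous_field(mesh):
    return ConductivityField.homogeneous(mesh, sigma0=1.0)


@pytest.fixture(scope="session")
def baseline_frame(mesh, homogeneous_field, pattern):
    return forward_solve(mesh, homogeneous_field, pattern)


@pytest.fixture(scope="session")
def jacobian(mesh, pattern, homogeneous_field):
    return compute_jacobian(mesh, pattern, homogeneous_field)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
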