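"""Shared fixtures: all meshes are generated at test time (no binary data).

The "fast" FPD uses a coarser voxel pitch than the package default so the
unit-test suite stays quick; the default-pitch bridge is session-scoped and
shared by the end-to-end tests.
"""
import numpy as np
import pytest

from fpdremodel.connector_detection import detect_connectors
from fpdremodel.synthetic_fpd import (
    SyntheticSpec,
    generate_cylinder,
    generate_dumbbell,
    generate_fpd,
)


@pytest.fixture(scope="session")
def fpd_fast():
    """Default 4-unit bridge geometry at a coarse 0.3 mm pitch."""
    return generate_fpd(SyntheticSpec(pitch=0.3))


@pytest.fixture(scope="session")
def fpd_fast_detection(fpd_fast):
    mesh, _ = fpd_fast
    return detect_connectors(mesh)


@pytest.fixture(scope="session")
def fpd_default():
    """The default synthetic 4-unit FPD at the default 0.15 mm pitch."""
    return generate_fpd(SyntheticSpec())


@pytest.fixture(scope="session")
def fpd_default_detection(fpd_default):
    mesh, _ = fpd_default
    return detect_connectors(mesh)


@pytest.fixture(scope="session")
def dumbbell():
    return generate_dumbbell()


@pytest.fixture(scope="session")
def dumbbell_detection(dumbbell):
    mesh, _ = dumbbell
    return detect_connectors(mesh)


@pytest.fixture(scope="session")
def cylinder_mesh():
    return generate_cylinder(radius=2.0, length=20.0, pitch=0.2)
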