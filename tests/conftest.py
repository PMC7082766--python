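import dataclasses

import numpy as np
import pytest

from tumorextent import (
    BinaryMask,
    PhantomSpec,
    VoxelGeometry,
    generate_phantom,
)


@pytest.fixture(scope="session")
def geometry():
    return VoxelGeometry(0.5, 1.0, (64, 64, 10))


@pytest.fixture(scope="session")
def small_geometry():
    return VoxelGeometry(0.5, 1.0, (16, 16, 16))


@pytest.fixture(scope="session")
def default_phantom():
    """One noisy study with histology, shared across tests (read-only)."""
    return generate_phantom(PhantomSpec(), seed=20)


@pytest.fixture(scope="session")
def light_phantom():
    """Noisy study without histology/vessels, for MRI-only tests."""
    spec = dataclasses.replace(
        PhantomSpec(), include_histology=False, include_vessels=False
    )
    return generate_phantom(spec, seed=21)


@pytest.fixture(scope="session")
def noise_phantom():
    """Tumor-free pure-noise study."""
    return generate_phantom(PhantomSpec().without_tumor(), seed=22)


def mask_from(values, geometry, label=""):
    return BinaryMask(np.asarray(values, bool), geometry, label)
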