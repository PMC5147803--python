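import numpy as np
import pytest

from confinedspt.geometry import CellGeometry


@pytest.fixture
def geometry() -> CellGeometry:
    """Default idealized cell: radius 0.5 μm, cylinder length 1.0 μm."""
    return CellGeometry()


@pytest.fixture
def planar_geometry() -> CellGeometry:
    """Huge-radius cell whose surface is locally flat (planar-diffusion limit)."""
    return CellGeometry(radius=1e6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160862)


@pytest.fixture(scope="session")
def model_cache() -> dict:
    """Shared cache of simulated model MSD curves, reused across fit tests."""
    return {}
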