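"""Shared fixtures: small geometries and phantoms sized for fast tests."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from gatedspect.gating import GateConfig
from gatedspect.phantom import LVPhantomSpec
from gatedspect.projector import CDRModel, Geometry, Projector


@pytest.fixture(scope="session")
def small_geometry() -> Geometry:
    """16×16×4 grid, 8 angles: big enough for real projections, fast."""
    return Geometry(
        grid_shape=(16, 16, 4),
        voxel_size_mm=4.0,
        angles_deg=tuple(np.arange(8) * 180.0 / 8),
        radius_mm=80.0,
    )


@pytest.fixture(scope="session")
def small_projector(small_geometry) -> Projector:
    return Projector(small_geometry, CDRModel())


@pytest.fixture(scope="session")
def sharp_projector(small_geometry) -> Projector:
    """No collimator blur: pure rotate-and-sum (ray sums)."""
    return Projector(small_geometry, CDRModel(fwhm0_mm=0.0, slope=0.0))


@pytest.fixture(scope="session")
def desk_geometry() -> Geometry:
    return Geometry()


@pytest.fixture(scope="session")
def desk_projector(desk_geometry) -> Projector:
    return Projector(desk_geometry, CDRModel())


@pytest.fixture(scope="session")
def small_phantom(small_geometry) -> LVPhantomSpec:
    """LV phantom scaled into the 64 mm small-geometry field of view."""
    return LVPhantomSpec(
        grid_shape=small_geometry.grid_shape,
        voxel_size_mm=small_geometry.voxel_size_mm,
        epicardial_radius_mm=20.0,
        endocardial_radius_mm=12.0,
        z_extent=(1, 3),
    )


@pytest.fixture(scope="session")
def gate_config() -> GateConfig:
    return GateConfig()
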