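"""Shared fixtures: coarse-voxel phantoms that keep the unit suite fast.

The "fast" phantoms use a 10 µm voxel with a thickened (35 µm) leaflet so a
whole valve voxelizes in about a second; tolerances in tests that use them
account for the coarse grid.  Fine-resolution checks live in the acceptance
suite.
"""

import numpy as np
import pytest

from valvegeom.geometry_gqoi import compute_gqoi
from valvegeom.synthetic_valve import (
    ValvePhantomParams, murine_preset, generate_valve_phantom,
)

FAST_VOXEL = 10.0
FAST_THICKNESS = 35.0


@pytest.fixture(scope="session")
def fast_phantom():
    """Murine-like phantom at coarse voxel: (volume, meshes, truth)."""
    params = murine_preset(tvp=10.0, voxel_size=FAST_VOXEL,
                           leaflet_thickness=FAST_THICKNESS)
    return generate_valve_phantom(params)


@pytest.fixture(scope="session")
def fast_gqoi(fast_phantom):
    volume, _, truth = fast_phantom
    record, landmarks = compute_gqoi(volume, tvp=10.0, seed=3)
    return record, landmarks, truth


@pytest.fixture(scope="session")
def fine_phantom():
    """Murine preset at 5 µm voxel with the true 19 µm leaflet thickness."""
    params = murine_preset(tvp=10.0, voxel_size=5.0)
    return generate_valve_phantom(params)


@pytest.fixture(scope="session")
def fine_gqoi(fine_phantom):
    volume, _, truth = fine_phantom
    record, landmarks = compute_gqoi(volume, tvp=10.0, seed=2)
    return record, landmarks, truth


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Untilted phantom with equal leaflet scales (120° commissure spacing)."""
    params = ValvePhantomParams(
        leaflet_scale={"anterior": 1.0, "left": 1.0, "right": 1.0},
        tilt_angle_true=0.0, voxel_size=FAST_VOXEL,
        leaflet_thickness_true=FAST_THICKNESS)
    return generate_valve_phantom(params)
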