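import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rootspace import RootSystemTruth, Scene


def cylinder_truth(radius_mm, length_mm, top_mm=2.0, xy=(0.0, 0.0)):
    """Single vertical-cylinder vector model with exact analytic totals."""
    start = np.array([xy[0], xy[1], top_mm])
    end = np.array([xy[0], xy[1], top_mm + length_mm])
    return RootSystemTruth(
        segments=[(start, end, radius_mm, -1)],
        tip_coordinates=[end],
        origin_xyz_mm=start,
        analytic_length_mm=length_mm,
        analytic_surface_area_mm2=2 * np.pi * radius_mm * length_mm,
        analytic_volume_mm3=np.pi * radius_mm**2 * length_mm,
        seed=0,
    )


@pytest.fixture
def cylinder_scene():
    def _make(radius_mm, length_mm, container=(30.0, 40.0), top_mm=2.0):
        truth = cylinder_truth(radius_mm, length_mm, top_mm=top_mm)
        return Scene(
            treatment="control",
            individuals=[("aspen", truth)],
            container=container,
        )

    return _make


@pytest.fixture
def sphere_grid():
    """Binary grid of a digitized ball, with its analytic volume."""
    from rootspace import VoxelGrid

    def _make(radius_mm, resolution_mm):
        half = radius_mm + 2 * resolution_mm
        n = int(np.ceil(2 * half / resolution_mm))
        ax = (np.arange(n) + 0.5) * resolution_mm - half
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        occ = (x**2 + y**2 + z**2 <= radius_mm**2).astype(np.uint8)
        return VoxelGrid(occupancy=occ, resolution_mm=resolution_mm)

    return _make
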