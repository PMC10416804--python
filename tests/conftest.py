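import numpy as np
import pytest

from spheroquant import CellSpec, ImagingScenario, generate_volume
from spheroquant.volumes import LabeledMask


def rasterize_sphere(radius_um, center_um, grid_shape, spacing):
    """Independent voxel-center rasterization of a sphere (test-side oracle)."""
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    return ((Z - center_um[0]) ** 2 + (Y - center_um[1]) ** 2
            + (X - center_um[2]) ** 2) <= radius_um**2


def sphere_mask(radius_um, spacing=(1.0, 1.0, 1.0), pad=3):
    """LabeledMask containing a single rasterized sphere, centered."""
    half = [int(np.ceil(radius_um / s)) + pad for s in spacing]
    shape = tuple(2 * h + 1 for h in half)
    center = tuple(h * s for h, s in zip(half, spacing))
    binary = rasterize_sphere(radius_um, center, shape, spacing)
    return LabeledMask(binary.astype(np.int32), spacing)


@pytest.fixture(scope="session")
def two_sphere_scenario():
    """Noise-free spheroid + one detached cell, small enough for exact checks."""
    return ImagingScenario(
        grid_shape=(30, 50, 50),
        spheroid_center=(40.0, 50.0, 50.0),
        spheroid_radius=20.0,
        voxel_spacing=(3.0, 2.0, 2.0),
        cells=[CellSpec("sphere", (8.0, 8.0, 8.0), (28.0, 50.0, 86.0))],
        noise_sigma=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def two_sphere_volume(two_sphere_scenario):
    return generate_volume(two_sphere_scenario)


@pytest.fixture(scope="session")
def hemisphere_imaged_sphere():
    """Sphere of radius 90 μm with its top tangent to the imaging face.

    The analysis can only see down to the widest (equatorial) plane, exactly
    the hemispheroid situation of a confocal invasion assay.
    """
    R = 90.0
    scenario = ImagingScenario(
        grid_shape=(64, 112, 112),
        spheroid_center=(R, 111.0, 111.0),
        spheroid_radius=R,
        voxel_spacing=(3.0, 2.0, 2.0),
        noise_sigma=5.0,
        seed=11,
    )
    volume, truth = generate_volume(scenario)
    return scenario, volume, truth
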