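"""Shared fixtures: phantoms and derived products reused across the suite.

Everything is generated programmatically from fixed seeds; the heavier
volumes are session-scoped so each is built once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from sasmorph import enhance, phantom, pipeline
from sasmorph.grids import BinaryMask
from sasmorph.segment import build_segments


@pytest.fixture(scope="session")
def default_phantom():
    """Mixed-radius phantom with trabeculae and a septum (seed 3)."""
    spec = phantom.PhantomSpec(rng_seed=3)
    vol, truth = phantom.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def enhanced_default(default_phantom):
    spec, vol, truth = default_phantom
    return enhance.enhance_volume(vol, pipeline.default_bank())


@pytest.fixture(scope="session")
def clean_segments(default_phantom):
    """Segmentation of the default phantom from a noise-robust direct
    threshold at the half-intensity level (isolates the compartment logic
    from the enhancement stage)."""
    spec, vol, truth = default_phantom
    raw = BinaryMask(vol.data >= 0.5, voxel_size_um=spec.voxel_size_um)
    return build_segments(raw, closing_radius_um=24.0,
                          macro_opening_radius_um=10.0,
                          exclude_boundary_csf=True)


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Rotationally symmetric phantom: no trabeculae, no septa, no noise."""
    spec = phantom.PhantomSpec(rng_seed=0, trabecula_count=0, septum_count=0,
                               noise_sigma=0.0)
    vol, truth = phantom.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def symmetric_segments(symmetric_phantom):
    spec, vol, truth = symmetric_phantom
    raw = BinaryMask(vol.data >= 0.5, voxel_size_um=spec.voxel_size_um)
    return build_segments(raw, closing_radius_um=18.0,
                          macro_opening_radius_um=7.5,
                          exclude_boundary_csf=True)


@pytest.fixture(scope="session")
def stitch_phantom():
    """Smaller gradient-free phantom used for tiling/stitching checks."""
    spec = phantom.PhantomSpec(
        rng_seed=4, noise_sigma=0.0, grid_shape=(64, 144, 144),
        nerve_radius_um=24.0, dura_radius_um=46.0, dura_thickness_um=18.0)
    vol, truth = phantom.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def broadband_field():
    """Texture-rich random field for registration tests."""
    rng = np.random.default_rng(1)
    return ndimage.gaussian_filter(rng.normal(size=(90, 90, 90)), 1.2)


def random_blob_mask(seed: int, shape=(24, 24, 24), sigma: float = 2.0) -> BinaryMask:
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    return BinaryMask(field > 0)


def digitized_ball(radius: int, pad: int = 3) -> BinaryMask:
    """Ball of the given voxel radius centred on a voxel centre."""
    n = 2 * (radius + pad) + 1
    zz, yy, xx = np.indices((n, n, n))
    c = radius + pad
    return BinaryMask(((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius**2)


def off_lattice_ball(radius_um: float, voxel_size_um: float) -> BinaryMask:
    """Ball centred between voxel centres (generic digitization error)."""
    r_vox = radius_um / voxel_size_um
    n = 2 * int(np.ceil(r_vox)) + 10
    zz, yy, xx = np.indices((n, n, n))
    c = (n - 1) / 2  # half-voxel off-lattice for even offsets
    return BinaryMask(((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r_vox**2,
                      voxel_size_um=voxel_size_um)
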