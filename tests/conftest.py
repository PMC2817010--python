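"""Shared fixtures: small phantom volumes reused across test modules.

Expensive voxelisations are session-scoped; unit tests use a coarser grid
(0.23 mm) than the acceptance studies (0.115 mm) to keep the suite fast.
"""

import warnings

import numpy as np
import pytest

from lensmetry import phantom, volio
from lensmetry.pipeline import PipelineConfig

COARSE_VOXEL = 0.23


@pytest.fixture(scope="session")
def std_lens():
    return phantom.LensSpec(R_a=3.6, R_p=2.6, T=2.35)


@pytest.fixture(scope="session")
def kidney_lens():
    return phantom.LensSpec(R_a=3.6, R_p=2.6, T=2.35, depression_depth=0.4)


@pytest.fixture(scope="session")
def std_eye(std_lens):
    return phantom.make_eye(std_lens)


@pytest.fixture(scope="session")
def coarse_vol(std_eye):
    """Noisy phantom eye at 0.23 mm (fast unit-test workhorse)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return phantom.voxelize_eye(std_eye, COARSE_VOXEL, 3, snr=15, seed=11)


@pytest.fixture(scope="session")
def coarse_clean_vol(std_eye):
    """Noiseless phantom eye at 0.23 mm."""
    return phantom.voxelize_eye(std_eye, COARSE_VOXEL, 3, snr=None, seed=0)


@pytest.fixture(scope="session")
def coarse_cfg():
    return PipelineConfig(voxel_size_mm=COARSE_VOXEL)


@pytest.fixture(scope="session")
def fine_vol(std_eye):
    """Noisy phantom eye at the acquisition resolution (0.115 mm)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return phantom.voxelize_eye(std_eye, 0.115, 3, snr=15, seed=11)


@pytest.fixture(scope="session")
def coarse_mask(coarse_vol, coarse_cfg):
    from lensmetry import segment
    sm = volio.gaussian_smooth(coarse_vol, coarse_cfg.smooth_kernel_mm)
    seed = segment.auto_seed(sm)
    thr = segment.select_threshold(sm, seed, coarse_cfg.roi_radius_mm)
    mask = segment.flood_fill_lens(sm, seed, thr)
    return segment.repair_mask(mask), sm


@pytest.fixture(scope="session")
def coarse_mesh(coarse_mask):
    from lensmetry import meshfit
    mask, sm = coarse_mask
    wrapped = meshfit.shrink_wrap(mask, face_budget=8192, intensity=sm.data)
    return meshfit.smooth_vertices(wrapped, 10)


@pytest.fixture(scope="session")
def small_array():
    """Coarse 16-eye array volume plus its generating manifest."""
    specs, _ = phantom.sample_lens_specs(16, seed=3, biconvex=False)
    eyes = [phantom.make_eye(lens=sp, inverted=(i == 15))
            for i, sp in enumerate(specs)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vol, manifest = phantom.assemble_array(
            eyes, voxel_size_mm=0.4, supersample=1, snr=20, seed=3)
    return vol, manifest


def true_occupancy_mask(spec, vol):
    """Ground-truth lens occupancy rasterised on a volume's grid."""
    from lensmetry.segment import LensMask
    idx = np.indices(vol.shape).reshape(3, -1).T
    pts = vol.origin + vol.voxel_size * idx
    occ = phantom.lens_occupancy(spec, pts).reshape(vol.shape)
    return LensMask(occ, vol.voxel_size, vol.origin)
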