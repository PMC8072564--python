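"""Shared fixtures and independent checkers for the test suite."""

import numpy as np
import pytest
from scipy import ndimage

from neuritrace.calibration import Calibration
from neuritrace.preprocess import BinaryMask


@pytest.fixture
def printed_calibration() -> Calibration:
    """The reference frame geometry (1376x1038 px, 884.89 x 667.52 um)."""
    return Calibration()


def make_mask(raster: np.ndarray, scale_factor: int = 1) -> BinaryMask:
    """Wrap a boolean raster in a BinaryMask at the reference pixel size."""
    cal = Calibration().with_frame_shape(*raster.shape)
    return BinaryMask(np.asarray(raster, dtype=bool), cal, scale_factor)


def disk_union_reconstruction(coords, radii, shape) -> np.ndarray:
    """Union of maximal disks (independent of the skeletonizer)."""
    out = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (r, c), rad in zip(coords, radii):
        out |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
    return out


def reconstruction_hausdorff(shape_mask: np.ndarray, coords, radii) -> float:
    """sup over shape pixels of the distance to the union of maximal disks.

    The disks always lie inside the shape, so this one-sided supremum is the
    symmetric Hausdorff distance between shape and reconstruction.
    """
    recon = disk_union_reconstruction(coords, radii, shape_mask.shape)
    if not recon.any():
        return np.inf
    dist = ndimage.distance_transform_edt(~recon)
    return float(dist[shape_mask].max())


def draw_soma_arm_shape(rng: np.random.Generator, size: int = 170,
                        arm_steps=(55, 80), turn_sigma: float = 0.06):
    """Random soma + radiating curvilinear arms + 1-px boundary noise.

    Emulates the geometry the pipeline measures: a cell body with thin
    arborized projections, at the noise scale of a binarized micrograph.
    """
    H = W = size
    img = np.zeros((H, W), dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    r0 = H // 2 + rng.integers(-15, 16)
    c0 = W // 2 + rng.integers(-15, 16)
    rad = rng.integers(10, 16)
    img |= (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
    n_arms = rng.integers(2, 5)
    base_ang = rng.uniform(0, 2 * np.pi)
    for k in range(n_arms):
        ang = base_ang + 2 * np.pi * k / n_arms + rng.normal(0, 0.2)
        pos = np.array([r0, c0], float)
        for _ in range(rng.integers(*arm_steps)):
            ang += rng.normal(0, turn_sigma)
            pos = pos + np.array([np.sin(ang), np.cos(ang)])
            pos = np.clip(pos, 4, H - 5)
            rr, cc = int(pos[0]), int(pos[1])
            img[max(rr - 1, 0) : rr + 2, max(cc - 1, 0) : cc + 2] = True
    edge = ndimage.binary_dilation(img) & ~img
    er, ec = np.nonzero(edge)
    pick = rng.random(len(er)) < 0.15
    img[er[pick], ec[pick]] = True
    return img
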