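"""Lens segmentation: threshold selection, flood fill, and mask repair.

The lens is the bright phase on these (T2-weighted, fixed-tissue) images.
A threshold is chosen by Otsu's method inside a spherical region of
interest around a seed, the lens is extracted as the 26-connected
supra-threshold component containing the seed, and residual noise-induced
pinholes and unfilled slices are repaired by morphological closing plus
slice-wise 2D hole filling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .volio import VoxelVolume

__all__ = [
    "LensMask",
    "auto_seed",
    "select_threshold",
    "flood_fill_lens",
    "repair_mask",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LensMask:
    """Binary lens region aligned to a :class:`~lensmetry.volio.VoxelVolume`."""

    mask: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed: tuple = (0, 0, 0)
    threshold: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.mask.shape

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_size ** 3

    def centroid_mm(self) -> np.ndarray:
        c = np.asarray(ndimage.center_of_mass(self.mask))
        return self.origin + c * self.voxel_size


def auto_seed(vol: VoxelVolume) -> tuple[int, int, int]:
    """Default seed: a centroid-proximal voxel of the brightest structure.

    The lens is the brightest tissue on these images, so the provisional
    seed is the peak of a noise-suppressing Gaussian-filtered copy of the
    volume; the final seed is the voxel nearest the centroid of the bright
    connected component containing that peak, which keeps it central
    within the lens.  A user-supplied seed always takes precedence in the
    downstream operations.
    """
    sm = ndimage.gaussian_filter(vol.data.astype(float), 2.0)
    peak = np.unravel_index(np.argmax(sm), sm.shape)
    thr = 0.5 * (sm[peak] + np.median(sm))
    bw = sm > thr
    labels, _ = ndimage.label(bw, structure=_CONN26)
    comp = np.argwhere(labels == labels[peak])
    centroid = comp.mean(axis=0)
    seed = comp[np.argmin(((comp - centroid) ** 2).sum(axis=1))]
    return tuple(int(v) for v in seed)


def _roi_values(vol: VoxelVolume, seed, roi_radius_mm: float) -> np.ndarray:
    seed = np.asarray(seed, dtype=int)
    if np.any(seed < 0) or np.any(seed >= np.asarray(vol.shape)):
        raise ValueError("seed outside volume")
    r = max(1, int(round(roi_radius_mm / vol.voxel_size)))
    lo = np.maximum(seed - r, 0)
    hi = np.minimum(seed + r + 1, vol.shape)
    sub = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    gx, gy, gz = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    dist_sq = ((gx - seed[0]) ** 2 + (gy - seed[1]) ** 2
               + (gz - seed[2]) ** 2)
    return sub[dist_sq <= r * r]


def _is_bimodal(values: np.ndarray) -> bool:
    """Crude mode count on a smoothed 64-bin histogram."""
    hist, _ = np.histogram(values, bins=64)
    sm = ndimage.gaussian_filter1d(hist.astype(float), 2.0)
    peaks = 0
    for i in range(1, len(sm) - 1):
        if sm[i] >= sm[i - 1] and sm[i] > sm[i + 1] and sm[i] > 0.05 * sm.max():
            peaks += 1
    return peaks >= 2


def select_threshold(vol: VoxelVolume, seed, roi_radius_mm: float = 3.5,
                     mode: str = "local") -> float:
    """Otsu threshold inside a spherical ROI around the seed.

    ``mode='global'`` applies Otsu to the whole volume instead.  Degenerate
    or unimodal ROI histograms trigger a warning and a midpoint fallback.
    """
    if mode == "global":
        values = vol.data.ravel()
    elif mode == "local":
        values = _roi_values(vol, seed, roi_radius_mm)
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax - vmin < 1e-12 * max(abs(vmax), 1.0):
        warnings.warn("degenerate ROI (constant intensity); "
                      "falling back to the midpoint", stacklevel=2)
        return 0.5 * (vmin + vmax)
    if not _is_bimodal(values):
        warnings.warn("ROI histogram appears unimodal; "
                      "falling back to the midpoint", stacklevel=2)
        return 0.5 * (vmin + vmax)
    thr = float(threshold_otsu(values))
    if not vmin < thr < vmax:
        warnings.warn("Otsu threshold collapsed to the range boundary; "
                      "falling back to the midpoint", stacklevel=2)
        thr = 0.5 * (vmin + vmax)
    return thr


def flood_fill_lens(vol: VoxelVolume, seed, threshold: float,
                    polarity: str = "bright",
                    volume_bounds_mm3: tuple = (5.0, 60.0)) -> LensMask:
    """Extract the 26-connected thresholded component containing the seed.

    Raises if the seed is on the wrong side of the threshold or if the
    component touches the volume border (a clipped lens); warns when the
    component volume falls outside the plausibility bounds.
    """
    seed = tuple(int(v) for v in seed)
    if polarity == "bright":
        bw = vol.data >= threshold
    elif polarity == "dark":
        bw = vol.data <= threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if not bw[seed]:
        raise ValueError(
            f"seed intensity {vol.data[seed]:.4g} is below the threshold "
            f"{threshold:.4g}; reseed inside the lens")
    labels, _ = ndimage.label(bw, structure=_CONN26)
    comp = labels == labels[seed]
    border = (comp[0].any() or comp[-1].any() or comp[:, 0].any()
              or comp[:, -1].any() or comp[:, :, 0].any()
              or comp[:, :, -1].any())
    if border:
        raise ValueError("lens clipped: component touches the volume border")
    vol_mm3 = comp.sum() * vol.voxel_size ** 3
    if volume_bounds_mm3 is not None:
        lo, hi = volume_bounds_mm3
        if not lo <= vol_mm3 <= hi:
            warnings.warn(
                f"flood-filled volume {vol_mm3:.1f} mm^3 outside the "
                f"plausibility bounds [{lo}, {hi}] mm^3", stacklevel=2)
    return LensMask(comp, vol.voxel_size, vol.origin.copy(), seed,
                    float(threshold))


def _slice_fill(m: np.ndarray, axis: int) -> np.ndarray:
    filled = np.empty_like(m)
    for i in range(m.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = i
        filled[tuple(sl)] = ndimage.binary_fill_holes(m[tuple(sl)])
    return filled


def repair_mask(mask: LensMask, closing_radius_vox: int = 2) -> LensMask:
    """Automated stand-in for the manual per-slice checking step.

    Applies morphological closing (ball structuring element), slice-wise
    2D hole filling, a 3D hole fill, and keeps the single component
    containing the seed.  A voxel is added by the slice fill only when it
    is 2D-enclosed in at least two of the three slice orientations: a
    genuine interior void or tunnel is enclosed in several orientations,
    whereas the open bowl of an anterior (kidney) depression is enclosed
    only in slices perpendicular to the axis and must not be filled in.
    Idempotent.
    """
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    if closing_radius_vox > 0:
        r = closing_radius_vox
        padded = np.pad(m, r)
        padded = ndimage.binary_closing(padded, structure=ball(r))
        m = padded[r:-r, r:-r, r:-r]
    votes = sum(_slice_fill(m, axis).astype(np.uint8) for axis in range(3))
    m = m | (votes >= 2)
    m = ndimage.binary_fill_holes(m)
    labels, nlab = ndimage.label(m, structure=_CONN26)
    if nlab > 1:
        if m[mask.seed]:
            keep = labels[mask.seed]
        else:
            sizes = ndimage.sum_labels(m, labels,
                                       index=np.arange(1, nlab + 1))
            keep = int(np.argmax(sizes)) + 1
        m = labels == keep
    return LensMask(m, mask.voxel_size, mask.origin.copy(), mask.seed,
                    mask.threshold, dict(mask.meta))
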