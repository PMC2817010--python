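"""Volumetric image I/O, eye-array cropping and Gaussian pre-smoothing.

Volumes are held as :class:`VoxelVolume`: a 3D intensity grid with an
isotropic voxel size in millimetres.  World coordinates follow a
voxel-centre convention: the centre of voxel ``(i, j, k)`` lies at
``origin + voxel_size * (i, j, k)``.  Supported on-disk formats are
NIfTI-1 (``.nii`` / ``.nii.gz``) and Analyze 7.5 (``.hdr`` + ``.img``
pair, little-endian), both through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "VoxelVolume",
    "ArrayLayout",
    "VolumeFormatError",
    "AnisotropicVoxelError",
    "read_volume",
    "write_volume",
    "crop_eyes",
    "gaussian_smooth",
]

#: canonical raster order of the 2x2x4 grid: cell m = iz*4 + iy*2 + ix
GRID_SHAPE = (2, 2, 4)


class VolumeFormatError(ValueError):
    """Raised for unreadable, malformed or unsupported volume files."""


class AnisotropicVoxelError(VolumeFormatError):
    """Raised when a volume does not have isotropic voxels."""


@dataclass
class VoxelVolume:
    """A 3D intensity grid with isotropic voxel size (mm) and metadata."""

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise VolumeFormatError("volume must be a non-empty 3D grid")
        if not self.voxel_size > 0:
            raise VolumeFormatError("voxel_size must be positive (mm)")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def index_to_mm(self, index) -> np.ndarray:
        """World position (mm) of a (possibly fractional) voxel index."""
        return self.origin + self.voxel_size * np.asarray(index, dtype=float)

    def mm_to_index(self, pos_mm) -> np.ndarray:
        """Fractional voxel index of a world position (mm)."""
        return (np.asarray(pos_mm, dtype=float) - self.origin) / self.voxel_size

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.voxel_size,
                           self.origin.copy(), dict(self.meta))


@dataclass
class ArrayLayout:
    """Explicit 2x2x4 cropping layout for a 16-eye array volume.

    ``boxes`` are 0-based half-open voxel bounding boxes ``(lo, hi)`` listed
    in canonical raster order (z-layer major, then y, then x);
    ``inverted_index`` is the canonical cell index of the one inverted eye.
    """

    boxes: list
    inverted_index: int
    grid_shape: tuple = GRID_SHAPE

    def __post_init__(self) -> None:
        n = int(np.prod(self.grid_shape))
        if len(self.boxes) != n:
            raise ValueError(f"expected {n} boxes, got {len(self.boxes)}")
        if not 0 <= self.inverted_index < n:
            raise ValueError("inverted_index outside grid")
        for a, (lo_a, hi_a) in enumerate(self.boxes):
            lo_a, hi_a = np.asarray(lo_a), np.asarray(hi_a)
            if np.any(hi_a <= lo_a):
                raise ValueError(f"box {a} is empty")
            for b in range(a + 1, n):
                lo_b, hi_b = (np.asarray(x) for x in self.boxes[b])
                if np.all(np.maximum(lo_a, lo_b) < np.minimum(hi_a, hi_b)):
                    raise ValueError(f"boxes {a} and {b} overlap")


def _nifti_suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz") or name.endswith(".nii"):
        return "nifti"
    if name.endswith(".hdr") or name.endswith(".img"):
        return "analyze"
    raise VolumeFormatError(
        f"unsupported volume format for {path.name!r} "
        "(expected .nii, .nii.gz or an Analyze .hdr/.img pair)")


def read_volume(path) -> VoxelVolume:
    """Read a NIfTI-1 or Analyze 7.5 volume from disk.

    Raises :class:`AnisotropicVoxelError` when the stored voxel grid is not
    isotropic and :class:`VolumeFormatError` for malformed files or missing
    Analyze companions.
    """
    path = Path(path)
    fmt = _nifti_suffix(path)
    if fmt == "analyze" and path.suffix.lower() == ".img":
        path = path.with_suffix(".hdr")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except FileNotFoundError as exc:
        raise VolumeFormatError(f"missing volume file: {exc}") from exc
    except Exception as exc:  # nibabel raises several header error types
        raise VolumeFormatError(f"cannot read {path.name!r}: {exc}") from exc

    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(zooms <= 0):
        raise VolumeFormatError(f"{path.name!r} has non-positive voxel size")
    if np.ptp(zooms) > 1e-6 * zooms.mean():
        raise AnisotropicVoxelError(
            f"{path.name!r} has anisotropic voxels {tuple(zooms)}; "
            "this pipeline requires isotropic grids")
    voxel_size = float(zooms.mean())

    origin = np.zeros(3)
    if fmt == "nifti":
        origin = np.asarray(img.affine[:3, 3], dtype=float)
    return VoxelVolume(data, voxel_size, origin, {"format": fmt,
                                                  "path": str(path)})


def write_volume(vol: VoxelVolume, path) -> Path:
    """Write a volume as NIfTI-1 or Analyze 7.5 (chosen by file suffix).

    NIfTI round-trips intensities bit-exactly and preserves the origin;
    Analyze 7.5 has no origin field, so only intensities and voxel size
    survive an Analyze round trip.
    """
    path = Path(path)
    fmt = _nifti_suffix(path)
    data = np.asarray(vol.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag([vol.voxel_size] * 3 + [1.0])
    if fmt == "nifti":
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(data, affine)
    else:
        if path.suffix.lower() == ".img":
            path = path.with_suffix(".hdr")
        img = nib.AnalyzeImage(data, affine)
    img.header.set_zooms((vol.voxel_size,) * 3)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# cropping


def _canonical_cells(grid_shape=GRID_SHAPE):
    nx, ny, nz = grid_shape
    return [(ix, iy, iz) for iz in range(nz) for iy in range(ny)
            for ix in range(nx)]


def assign_eye_ids(inverted_index: int, n_cells: int = 16) -> list[int]:
    """Eye ids (1-based) per canonical cell, anchored on the inverted eye.

    The inverted eye always receives the highest id; the remaining ids
    follow the canonical raster order cyclically, so a shifted inverted
    cell rotates the whole assignment.
    """
    return [((m - inverted_index - 1) % n_cells) + 1 for m in range(n_cells)]


def _detect_globes(vol: VoxelVolume, n_expected: int = 16):
    """Threshold + connected components; returns labels and slices."""
    thr = threshold_otsu(vol.data)
    bw = vol.data > thr
    # a 1-voxel opening severs noise bridges across the agarose gaps
    bw = ndimage.binary_opening(bw, structure=np.ones((3, 3, 3)))
    labels, nlab = ndimage.label(bw, structure=np.ones((3, 3, 3)))
    if nlab == 0:
        raise ValueError("0 globes detected (expected 16)")
    sizes = ndimage.sum_labels(bw, labels, index=np.arange(1, nlab + 1))
    order = np.argsort(sizes)[::-1]
    sorted_sizes = sizes[order]
    # globes are similar-sized and far larger than shell fragments or
    # noise blobs: cut at the largest relative size gap
    kmax = min(nlab, 2 * n_expected)
    if nlab == 1:
        n_globes = 1
    else:
        ratios = sorted_sizes[:kmax - 1] / np.maximum(sorted_sizes[1:kmax],
                                                      1.0)
        n_globes = int(np.argmax(ratios)) + 1
        if ratios.max() < 2.0:
            n_globes = nlab  # no clear gap: everything is globe-scale
    if n_globes != n_expected:
        raise ValueError(
            f"{n_globes} globes detected (expected {n_expected})")
    keep = order[:n_globes] + 1
    return labels, keep, thr


def _lens_offset_sign(vol: VoxelVolume, labels, lab: int) -> float:
    """Axial (z) offset of the brightest lens-like core from the globe
    centroid; its sign encodes anterior orientation."""
    where = labels == lab
    vals = vol.data[where]
    bright_thr = 0.5 * (np.percentile(vals, 99.5) + np.median(vals))
    idx = np.argwhere(where)
    globe_c = idx.mean(axis=0)
    bright = vals >= bright_thr
    if not bright.any():
        return 0.0
    lens_c = idx[bright].mean(axis=0)
    return float(lens_c[2] - globe_c[2])


def crop_eyes(vol: VoxelVolume, layout: ArrayLayout | None = None,
              margin_mm: float = 1.0):
    """Crop the 16 eyes out of a 2x2x4 array scan.

    In auto mode the globes are found by Otsu thresholding and connected
    components, assigned to grid cells by position, and the single eye whose
    lens points opposite the majority is flagged as inverted, anchoring the
    id assignment.  Returns ``(crops, manifest)`` where ``crops`` is a list
    of 16 :class:`VoxelVolume` ordered by eye id and ``manifest`` maps grid
    cells to eye ids.
    """
    # +2 voxels compensate the detection's opening erosion and the
    # partial-volume shell that falls below the global threshold
    margin = max(0, int(round(margin_mm / vol.voxel_size))) + 2
    cells = _canonical_cells()

    if layout is None:
        labels, keep, _ = _detect_globes(vol)
        cents = np.asarray(ndimage.center_of_mass(
            vol.data, labels, index=keep))
        # order components into z-layers of 4, then y pairs, then x
        order = np.argsort(cents[:, 2], kind="stable")
        cell_of_comp = {}
        for iz in range(4):
            layer = order[4 * iz:4 * iz + 4]
            layer = layer[np.argsort(cents[layer, 1], kind="stable")]
            for iy in range(2):
                pair = layer[2 * iy:2 * iy + 2]
                pair = pair[np.argsort(cents[pair, 0], kind="stable")]
                for ix in range(2):
                    cell_of_comp[int(pair[ix])] = (ix, iy, iz)
        offsets = np.array([_lens_offset_sign(vol, labels, keep[i])
                            for i in range(16)])
        majority = np.sign(np.median(offsets)) or 1.0
        inverted_comp = int(np.argmin(offsets * majority))
        slices = ndimage.find_objects(labels)
        boxes_by_cell = {}
        for i in range(16):
            sl = slices[keep[i] - 1]
            lo = [max(0, s.start - margin) for s in sl]
            hi = [min(n, s.stop + margin)
                  for s, n in zip(sl, vol.shape)]
            boxes_by_cell[cell_of_comp[i]] = (lo, hi)
        inverted_cell = cell_of_comp[inverted_comp]
        inverted_index = cells.index(inverted_cell)
        boxes = [boxes_by_cell[c] for c in cells]
    else:
        boxes = [(np.asarray(lo), np.asarray(hi)) for lo, hi in layout.boxes]
        for lo, hi in boxes:
            if np.any(lo < 0) or np.any(hi > np.asarray(vol.shape)):
                raise ValueError("layout box outside volume bounds")
        inverted_index = layout.inverted_index

    ids = assign_eye_ids(inverted_index)
    manifest = {"grid_shape": list(GRID_SHAPE), "cells": []}
    crops_by_id = {}
    for m, cell in enumerate(cells):
        lo, hi = boxes[m]
        lo = np.asarray(lo, dtype=int)
        hi = np.asarray(hi, dtype=int)
        sub = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
        crop = VoxelVolume(sub, vol.voxel_size,
                           vol.origin + lo * vol.voxel_size,
                           {"eye_id": ids[m], "cell": list(cell),
                            "inverted": m == inverted_index})
        crops_by_id[ids[m]] = crop
        manifest["cells"].append({
            "cell": list(cell), "eye_id": ids[m],
            "inverted": m == inverted_index,
            "bbox_voxels": [lo.tolist(), hi.tolist()],
        })
    crops = [crops_by_id[i] for i in sorted(crops_by_id)]
    return crops, manifest


def gaussian_smooth(vol: VoxelVolume, kernel_mm: float = 0.1,
                    kernel_is_fwhm: bool = False) -> VoxelVolume:
    """Gaussian pre-smoothing with the kernel given in millimetres.

    The kernel size is read as the Gaussian sigma by default;
    ``kernel_is_fwhm=True`` converts from full width at half maximum.
    ``kernel_mm=0`` is the identity.
    """
    if kernel_mm < 0:
        raise ValueError("kernel_mm must be >= 0")
    if kernel_mm == 0:
        out = vol.copy()
        out.meta["smoothed_sigma_mm"] = 0.0
        return out
    sigma_mm = kernel_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
        if kernel_is_fwhm else kernel_mm
    sigma_vox = sigma_mm / vol.voxel_size
    sm = ndimage.gaussian_filter(vol.data.astype(float), sigma_vox,
                                 mode="nearest")
    meta = dict(vol.meta)
    meta["smoothed_sigma_mm"] = sigma_mm
    return VoxelVolume(sm, vol.voxel_size, vol.origin.copy(), meta)
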