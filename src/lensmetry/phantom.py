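"""Ground-truthed synthetic eyes, lenses, array volumes and bird cohorts.

The crystalline lens is modelled as a biconvex solid: the union of two
spherical caps (anterior radius ``R_a``, posterior radius ``R_p``) sharing
a base circle of radius ``r_e`` (half the equatorial diameter), with cap
heights ``h_a + h_p = T`` (axial thickness).  A fixation-shrinkage artifact
is modelled as a posterior displacement of the surface that is Gaussian in
the polar angle -- a smooth central dent in the anterior surface of depth
``D`` -- followed by an optional global isotropic shrink ``s`` about the
lens centre.  Phantom eyes embed the lens inside a spheroidal globe with a
scleral shell, are rasterised with partial-volume supersampling, and are
corrupted with Rician magnitude noise at a chosen signal-to-noise ratio.

Cohorts of birds are simulated with a Gaussian copula so that lens volume
and equatorial diameter co-vary with eye and body size while the dent
artifact carries a hatch-level (fixation-batch) random effect and no
scan-group effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import linalg, ndimage

from .volio import GRID_SHAPE, VoxelVolume, assign_eye_ids

__all__ = [
    "GeometryInfeasibleError",
    "BiconvexGeometry",
    "LensSpec",
    "IntensityLevels",
    "EyeSpec",
    "CohortSpec",
    "GroundTruth",
    "solve_biconvex_geometry",
    "lens_occupancy",
    "lens_ground_truth",
    "make_eye",
    "voxelize_eye",
    "assemble_array",
    "TRAIT_ORDER",
    "build_trait_correlation",
    "default_trait_correlation",
    "simulate_cohort",
    "sample_lens_specs",
]


class GeometryInfeasibleError(ValueError):
    """The two spherical caps cannot close into a biconvex solid."""


class BiconvexGeometry(NamedTuple):
    h_a: float      #: anterior cap height, mm
    h_p: float      #: posterior cap height, mm
    r_e: float      #: equatorial (base circle) radius, mm
    volume: float   #: analytic solid volume, mm^3


def solve_biconvex_geometry(R_a: float, R_p: float, T: float
                            ) -> BiconvexGeometry:
    """Solve the two-cap geometry for given surface radii and thickness.

    The caps share a base circle, so the heights satisfy ``h_a + h_p = T``
    and ``h_a (2 R_a - h_a) = h_p (2 R_p - h_p) = r_e**2``; expanding the
    shared-base equation makes it linear in ``h_a``.  The volume is the sum
    of the two cap volumes ``pi/3 * h**2 * (3R - h)``.

    Raises :class:`GeometryInfeasibleError` when no root with
    ``0 < h_a < T`` and caps no larger than hemispheres exists.
    """
    if not (R_a > 0 and R_p > 0 and T > 0):
        raise GeometryInfeasibleError("R_a, R_p and T must be positive")
    den = R_a + R_p - T
    if abs(den) < 1e-12 * max(R_a, R_p, T):
        # caps meet only in the degenerate full-sphere case R_a = R_p = T/2
        if abs(R_a - R_p) < 1e-9 and abs(R_a - T / 2) < 1e-9:
            h_a = h_p = T / 2.0
        else:
            raise GeometryInfeasibleError(
                f"caps cannot close for R_a={R_a}, R_p={R_p}, T={T}")
    else:
        h_a = T * (2.0 * R_p - T) / (2.0 * den)
        h_p = T - h_a
    if not (0.0 < h_a < T):
        raise GeometryInfeasibleError(
            f"no cap-height root in (0, T): h_a={h_a:.4g} for "
            f"R_a={R_a}, R_p={R_p}, T={T}")
    if h_a > R_a + 1e-9 or h_p > R_p + 1e-9:
        raise GeometryInfeasibleError(
            "cap exceeds hemisphere; equator would not be the widest section")
    r_e_sq = h_a * (2.0 * R_a - h_a)
    residual = abs(r_e_sq - h_p * (2.0 * R_p - h_p))
    if residual > 1e-10:
        raise GeometryInfeasibleError(
            f"shared-base residual {residual:.3g} mm^2 exceeds tolerance")
    if r_e_sq <= 0:
        raise GeometryInfeasibleError("degenerate base circle")
    volume = (np.pi / 3.0) * (h_a ** 2 * (3.0 * R_a - h_a)
                              + h_p ** 2 * (3.0 * R_p - h_p))
    return BiconvexGeometry(float(h_a), float(h_p),
                            float(np.sqrt(r_e_sq)), float(volume))


def _orthonormal_frame(axis: np.ndarray) -> np.ndarray:
    """3x3 matrix with columns (e1, e2, axis)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(a[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return np.column_stack([e1, e2, a])


@dataclass
class LensSpec:
    """Parameters of one phantom lens (all lengths in mm, angles radians).

    ``depression_depth`` is the dent depth ``D`` of the anterior-surface
    shrinkage artifact (0 = pristine biconvex); ``depression_width`` is the
    angular standard deviation of the Gaussian dent profile measured at the
    anterior centre of curvature, so the dent's lateral scale on the
    surface is about ``R_a * depression_width``; ``global_shrink`` is the
    isotropic scale applied about the lens centre (1 = no shrink).
    ``center`` is the centre of the equatorial base circle and ``axis``
    the unit anterior direction.
    """

    R_a: float = 3.6
    R_p: float = 2.6
    T: float = 2.35
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0., 0., 1.]))
    depression_depth: float = 0.0
    depression_width: float = 0.15
    global_shrink: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        self.axis = axis / np.linalg.norm(axis)
        if self.depression_depth < 0:
            raise ValueError("depression_depth must be >= 0")
        if self.depression_width <= 0:
            raise ValueError("depression_width must be > 0")
        if not 0 < self.global_shrink <= 1:
            raise ValueError("global_shrink must be in (0, 1]")
        geom = self.geometry  # validates feasibility
        if self.depression_depth >= 0.8 * geom.h_a * self.global_shrink:
            warnings.warn(
                "depression_depth >= 0.8 * h_a * s: the dent approaches the "
                "posterior cap and the surface may self-intersect",
                stacklevel=2)

    @property
    def geometry(self) -> BiconvexGeometry:
        return solve_biconvex_geometry(self.R_a, self.R_p, self.T)

    def bounding_radius(self) -> float:
        """Radius of a sphere about ``center`` containing the lens."""
        g = self.geometry
        return self.global_shrink * max(g.r_e, g.h_a, g.h_p)


def lens_occupancy(spec: LensSpec, points: np.ndarray) -> np.ndarray:
    """Boolean inside/outside test of the (deformed) lens at world points.

    The dent is applied by inverse mapping: a point lies inside the
    deformed solid iff un-shrinking it about the centre and pushing it
    anteriorly by the local dent displacement lands inside the pristine
    biconvex solid.  The dent profile is Gaussian in the polar angle of
    the anterior cap (measured at the anterior centre of curvature, so its
    lateral scale is ``R_a * depression_width``) and fades smoothly to
    zero at the equatorial plane so the posterior cap is untouched.  Along
    the axis the anterior pole is displaced posteriorly by exactly ``D``.
    """
    g = spec.geometry
    pts = np.asarray(points)
    if pts.dtype not in (np.float32, np.float64):
        pts = pts.astype(float)
    B = _orthonormal_frame(spec.axis).astype(pts.dtype)
    q = (pts.reshape(-1, 3) - spec.center.astype(pts.dtype)) @ B
    q /= spec.global_shrink
    qz = q[:, 2]
    za = g.h_a - spec.R_a   # anterior sphere centre (axial)
    zp = spec.R_p - g.h_p   # posterior sphere centre (axial)
    if spec.depression_depth > 0:
        rho = np.hypot(q[:, 0], q[:, 1])
        theta = np.arctan2(rho, qz - za)
        # smoothstep anterior taper: 1 well above the equator, 0 below it
        t = np.clip(qz / (0.25 * g.h_a), 0.0, 1.0)
        w = t * t * (3.0 - 2.0 * t)
        qz = qz + w * spec.depression_depth * np.exp(
            -theta ** 2 / (2.0 * spec.depression_width ** 2))
    rho_sq = q[:, 0] ** 2 + q[:, 1] ** 2
    anterior = (qz >= 0) & (rho_sq + (qz - za) ** 2 <= spec.R_a ** 2)
    posterior = (qz < 0) & (rho_sq + (qz - zp) ** 2 <= spec.R_p ** 2)
    out = anterior | posterior
    return out.reshape(np.asarray(points).shape[:-1])


def axial_extent(spec: LensSpec, n: int = 16001) -> float:
    """Pole-to-pole extent along the lens axis, evaluated numerically."""
    g = spec.geometry
    span = 1.2 * (g.h_a + g.h_p)
    t = np.linspace(-span, span, n)
    pts = spec.center + np.outer(t, spec.axis)
    inside = lens_occupancy(spec, pts)
    if not inside.any():
        return 0.0
    idx = np.flatnonzero(inside)
    return float(t[idx[-1]] - t[idx[0]])


@dataclass
class GroundTruth:
    """True per-eye biometry of a phantom lens.

    ``thickness`` and ``eq_diameter`` account for the dent and global
    shrink; ``volume`` is the analytic two-cap volume scaled by the shrink
    (for a dented lens it is the pre-dent value -- the dent removes a small
    additional amount of material).
    """

    T: float
    eq_diameter: float
    volume: float
    R_a: float
    R_p: float
    D: float
    hatch: int | None = None
    scan_group: int | None = None


def lens_ground_truth(spec: LensSpec) -> GroundTruth:
    g = spec.geometry
    s = spec.global_shrink
    d = spec.depression_depth
    # the dent displaces the anterior pole by exactly d; the posterior
    # pole is untouched (the deformation fades out at the equator)
    return GroundTruth(
        T=s * (spec.T - d),
        eq_diameter=s * 2.0 * g.r_e,
        volume=s ** 3 * g.volume,
        R_a=s * spec.R_a, R_p=s * spec.R_p, D=s * d)


@dataclass
class IntensityLevels:
    """Tissue intensity levels in arbitrary units (pairwise distinct)."""

    lens: float = 200.0
    humor: float = 60.0
    sclera: float = 90.0
    background: float = 30.0

    def __post_init__(self) -> None:
        vals = [self.lens, self.humor, self.sclera, self.background]
        if len(set(vals)) != 4:
            raise ValueError("intensity levels must be pairwise distinct")


@dataclass
class EyeSpec:
    """One phantom eye: a lens inside a spheroidal globe with sclera."""

    lens: LensSpec
    axial_length: float = 9.5
    eq_diameter: float = 10.5
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    levels: IntensityLevels = field(default_factory=IntensityLevels)
    sclera_thickness: float = 0.4
    inverted: bool = False

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        # lens must fit inside the inner (humor) spheroid
        off = self.lens.center - self.center
        a = self.axial_length / 2.0 - self.sclera_thickness
        b = self.eq_diameter / 2.0 - self.sclera_thickness
        r = self.lens.bounding_radius()
        ax = self.lens.axis
        off_ax = abs(off @ ax)
        off_perp = np.linalg.norm(off - (off @ ax) * ax)
        if (off_ax + r) / a > 1.0 or (off_perp + r) / b > 1.0:
            raise ValueError("lens does not fit inside the globe")

    @property
    def axis(self) -> np.ndarray:
        return self.lens.axis


def make_eye(lens: LensSpec | None = None, center=(0.0, 0.0, 0.0),
             axis=(0.0, 0.0, 1.0), inverted: bool = False,
             axial_length: float = 9.5, eq_diameter: float = 10.5,
             levels: IntensityLevels | None = None,
             lens_offset_frac: float = 0.18) -> EyeSpec:
    """Place a lens in a globe with the anterior pole toward ``axis``.

    ``inverted=True`` flips the whole eye.  The lens base circle sits
    ``lens_offset_frac * axial_length`` anterior of the globe centre,
    matching the anterior position of the real lens.
    """
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if inverted:
        axis = -axis
    if lens is None:
        lens = LensSpec()
    lens = replace(lens, center=center + lens_offset_frac * axial_length * axis,
                   axis=axis)
    return EyeSpec(lens=lens, axial_length=axial_length,
                   eq_diameter=eq_diameter, center=center,
                   levels=levels or IntensityLevels(), inverted=inverted)


def _eye_intensity(eye: EyeSpec, pts: np.ndarray) -> np.ndarray:
    """Noise-free tissue intensity at world points (flat N x 3)."""
    lv = eye.levels
    out = np.full(pts.shape[0], lv.background, dtype=float)
    B = _orthonormal_frame(eye.axis).astype(pts.dtype)
    q = (pts - eye.center.astype(pts.dtype)) @ B
    a_out = eye.axial_length / 2.0
    b_out = eye.eq_diameter / 2.0
    rho_sq = q[:, 0] ** 2 + q[:, 1] ** 2
    m_out = rho_sq / b_out ** 2 + q[:, 2] ** 2 / a_out ** 2 <= 1.0
    out[m_out] = lv.sclera
    a_in = a_out - eye.sclera_thickness
    b_in = b_out - eye.sclera_thickness
    m_in = rho_sq / b_in ** 2 + q[:, 2] ** 2 / a_in ** 2 <= 1.0
    out[m_in] = lv.humor
    if m_in.any():
        inside = lens_occupancy(eye.lens, pts[m_in])
        sub = out[m_in]
        sub[inside] = lv.lens
        out[m_in] = sub
    return out


def _rician(signal: np.ndarray, sigma: float,
            rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI (Rician) noise with Gaussian channel noise sigma."""
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def _supersample_offsets(supersample: int) -> np.ndarray:
    """Sub-voxel sample offsets (voxel units, centred)."""
    k = np.arange(supersample)
    return (k + 0.5) / supersample - 0.5


def _rasterize(intensity_fn, shape, origin, voxel_size, supersample,
               chunk: int = 2_000_000) -> np.ndarray:
    """Partial-volume rasterisation by supersampled occupancy averaging.

    Tissue intensity is piecewise constant, so supersampling only matters
    where a voxel straddles a boundary: the grid is first sampled at voxel
    centres, then every voxel whose 6-neighbourhood is not uniform is
    re-evaluated with ``supersample**3`` sub-voxel samples and averaged.
    """
    nx, ny, nz = shape
    origin = np.asarray(origin, dtype=float)

    def evaluate(pts):
        out = np.empty(pts.shape[0])
        for i in range(0, pts.shape[0], chunk):
            out[i:i + chunk] = intensity_fn(pts[i:i + chunk])
        return out

    centers = np.empty((nx, ny, nz, 3), dtype=np.float32)
    centers[..., 0] = (origin[0]
                       + voxel_size * np.arange(nx))[:, None, None]
    centers[..., 1] = (origin[1]
                       + voxel_size * np.arange(ny))[None, :, None]
    centers[..., 2] = (origin[2]
                       + voxel_size * np.arange(nz))[None, None, :]
    base = evaluate(centers.reshape(-1, 3)).reshape(shape)
    if supersample == 1:
        return base

    near_edge = (ndimage.maximum_filter(base, size=3)
                 != ndimage.minimum_filter(base, size=3))
    edge_idx = np.argwhere(near_edge)
    if len(edge_idx) == 0:
        return base
    off = _supersample_offsets(supersample)
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    pts = ((origin + voxel_size * edge_idx)[:, None, :]
           + voxel_size * offsets[None, :, :]).astype(np.float32)
    vals = evaluate(pts.reshape(-1, 3)).reshape(len(edge_idx), -1).mean(axis=1)
    out = base.copy()
    out[near_edge] = vals
    return out


def voxelize_eye(eye: EyeSpec, voxel_size_mm: float = 0.115,
                 supersample: int = 3, snr: float | None = 15.0,
                 seed: int = 0, fov_margin_mm: float = 1.0,
                 fov_mm: float | None = None) -> VoxelVolume:
    """Rasterise a phantom eye onto an isotropic voxel grid.

    Partial-volume intensities come from ``supersample**3`` occupancy
    averaging; Rician noise is added at the stated SNR (defined as the
    lens intensity divided by the channel noise sigma).  ``snr=None``
    gives a noiseless volume.  Deterministic for a fixed seed.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be > 0")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    half = (fov_mm / 2.0 if fov_mm is not None
            else max(eye.axial_length, eye.eq_diameter) / 2.0 + fov_margin_mm)
    n = int(np.ceil(2.0 * half / voxel_size_mm))
    origin = eye.center - voxel_size_mm * (n - 1) / 2.0
    lens_reach = (np.abs(eye.lens.center - eye.center).max()
                  + eye.lens.bounding_radius())
    if lens_reach > half:
        raise ValueError("lens exceeds the field of view")
    data = _rasterize(lambda p: _eye_intensity(eye, p), (n, n, n),
                      origin, voxel_size_mm, supersample)
    if snr is not None and np.isfinite(snr):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
        data = _rician(data, eye.levels.lens / snr, rng)
    meta = {"snr": snr, "seed": int(seed), "supersample": supersample,
            "inverted": eye.inverted,
            "anterior_axis": eye.axis.tolist(),
            "lens_center_mm": eye.lens.center.tolist()}
    return VoxelVolume(data, voxel_size_mm, origin, meta)


def assemble_array(eyes, voxel_size_mm: float = 0.115, supersample: int = 1,
                   snr: float | None = None, seed: int = 0,
                   cylinder_diameter_mm: float = 38.0,
                   gap_mm: float = 1.5):
    """Embed 16 eyes in a 2x2x4 agarose-filled cylinder and rasterise.

    Eyes are placed in canonical raster order (z-layer major); exactly one
    must be inverted.  Returns ``(volume, manifest)`` where the manifest
    maps grid cells to eye ids and orientations.
    """
    eyes = list(eyes)
    if len(eyes) != 16:
        raise ValueError(f"expected 16 eyes, got {len(eyes)}")
    n_inv = sum(e.inverted for e in eyes)
    if n_inv != 1:
        raise ValueError(f"exactly one eye must be inverted, got {n_inv}")

    w = max(e.eq_diameter for e in eyes)
    h = max(e.axial_length for e in eyes)
    pitch_xy = w + gap_mm
    pitch_z = h + gap_mm
    cyl_r = cylinder_diameter_mm / 2.0
    reach = pitch_xy / 2.0 * np.sqrt(2.0) + w / 2.0
    if reach > cyl_r - 0.25:
        raise ValueError("eye placement falls outside the agarose cylinder")

    placed = []
    cells = [(ix, iy, iz) for iz in range(4) for iy in range(2)
             for ix in range(2)]
    for eye, (ix, iy, iz) in zip(eyes, cells):
        pos = np.array([(ix - 0.5) * pitch_xy, (iy - 0.5) * pitch_xy,
                        (iz - 1.5) * pitch_z])
        axis = np.array([0.0, 0.0, 1.0])
        placed.append(make_eye(lens=replace(eye.lens), center=pos, axis=axis,
                               inverted=eye.inverted,
                               axial_length=eye.axial_length,
                               eq_diameter=eye.eq_diameter,
                               levels=eye.levels))
    # non-overlap audit on axis-aligned bounding boxes
    for a in range(16):
        for b in range(a + 1, 16):
            ca, cb = placed[a].center, placed[b].center
            half = np.array([w, w, h]) / 2.0
            if np.all(np.abs(ca - cb) < 2 * half - 1e-9):
                raise ValueError(f"eyes {a} and {b} overlap")

    half_xy = cyl_r
    half_z = 2.0 * pitch_z + gap_mm
    nx = ny = int(np.ceil(2 * half_xy / voxel_size_mm))
    nz = int(np.ceil(2 * half_z / voxel_size_mm))
    origin = np.array([-voxel_size_mm * (nx - 1) / 2.0,
                       -voxel_size_mm * (ny - 1) / 2.0,
                       -voxel_size_mm * (nz - 1) / 2.0])
    bg = placed[0].levels.background

    def intensity(pts):
        out = np.full(pts.shape[0], 0.0)
        inside_cyl = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= cyl_r ** 2
        out[inside_cyl] = bg
        for eye in placed:
            r = max(eye.axial_length, eye.eq_diameter) / 2.0 + 0.5
            near = np.all(np.abs(pts - eye.center) <= r, axis=1)
            if near.any():
                out[near] = _eye_intensity(eye, pts[near])
        return out

    data = _rasterize(intensity, (nx, ny, nz), origin, voxel_size_mm,
                      supersample)
    if snr is not None and np.isfinite(snr):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
        data = _rician(data, placed[0].levels.lens / snr, rng)
    vol = VoxelVolume(data, voxel_size_mm, origin,
                      {"snr": snr, "seed": int(seed)})

    inverted_index = next(i for i, e in enumerate(placed) if e.inverted)
    ids = assign_eye_ids(inverted_index)
    manifest = {"grid_shape": list(GRID_SHAPE), "cells": []}
    for m, (eye, cell) in enumerate(zip(placed, cells)):
        lo = vol.mm_to_index(eye.center - np.array([w, w, h]) / 2.0)
        hi = vol.mm_to_index(eye.center + np.array([w, w, h]) / 2.0)
        manifest["cells"].append({
            "cell": list(cell),
            "eye_id": ids[m],
            "input_index": m,
            "inverted": bool(eye.inverted),
            "center_mm": eye.center.tolist(),
            "anterior_axis": eye.axis.tolist(),
            "bbox_voxels": [np.floor(lo).astype(int).tolist(),
                            np.ceil(hi).astype(int).tolist()],
        })
    return vol, manifest


# ---------------------------------------------------------------------------
# cohort simulation

#: trait order of the target rank-correlation matrix
TRAIT_ORDER = [
    "lens_volume", "lens_eq_diam", "lens_thickness", "axial_length",
    "corneal_radius", "eye_weight", "eye_eq_diam", "body_mass",
    "body_length",
]

DEFAULT_TRAIT_MEANS = {
    "lens_volume": 22.7, "lens_eq_diam": 4.70, "lens_thickness": 2.35,
    "axial_length": 9.5, "corneal_radius": 3.40, "eye_weight": 1.60,
    "eye_eq_diam": 14.0, "body_mass": 450.0, "body_length": 180.0,
}

DEFAULT_TRAIT_SDS = {
    "lens_volume": 1.5, "lens_eq_diam": 0.18, "lens_thickness": 0.08,
    "axial_length": 0.35, "corneal_radius": 0.15, "eye_weight": 0.15,
    "eye_eq_diam": 0.5, "body_mass": 60.0, "body_length": 12.0,
}

#: loadings of each trait on a common size factor
DEFAULT_SIZE_LOADINGS = {
    "lens_eq_diam": 0.60, "lens_thickness": 0.18, "axial_length": 0.75,
    "corneal_radius": 0.60, "eye_weight": 0.80, "eye_eq_diam": 0.72,
    "body_mass": 0.80, "body_length": 0.70,
}


def build_trait_correlation(size_loadings: dict | None = None,
                            volume_on_diam: float = 0.95,
                            volume_on_thickness: float = 0.27
                            ) -> np.ndarray:
    """Construct a coherent positive-semidefinite trait correlation matrix.

    Every trait loads on a single latent size factor; lens volume is a
    mixture of the diameter and thickness latents plus an independent
    residual, which encodes the near-deterministic dependence of a biconvex
    lens's volume on its diameter and thickness.  Being a Gram matrix of
    unit vectors, the result is positive semidefinite by construction.
    """
    lam = dict(DEFAULT_SIZE_LOADINGS)
    if size_loadings:
        lam.update(size_loadings)
    base = [t for t in TRAIT_ORDER if t != "lens_volume"]
    dim = 1 + len(base) + 1  # size factor, per-trait residuals, volume resid
    vecs = {}
    for i, t in enumerate(base):
        v = np.zeros(dim)
        v[0] = lam[t]
        v[1 + i] = np.sqrt(1.0 - lam[t] ** 2)
        vecs[t] = v
    v_vol = (volume_on_diam * vecs["lens_eq_diam"]
             + volume_on_thickness * vecs["lens_thickness"])
    resid = 1.0 - v_vol @ v_vol
    v = np.zeros(dim)
    v[-1] = np.sqrt(max(resid, 0.0))
    vecs["lens_volume"] = v_vol + v
    vecs["lens_volume"] /= np.linalg.norm(vecs["lens_volume"])
    mat = np.array([[vecs[a] @ vecs[b] for b in TRAIT_ORDER]
                    for a in TRAIT_ORDER])
    np.fill_diagonal(mat, 1.0)
    return mat


def default_trait_correlation() -> np.ndarray:
    return build_trait_correlation()


@dataclass
class CohortSpec:
    """Design of a simulated bird cohort.

    Birds arrive in hatches (fixation batches) of about ``hatch_size``;
    the dent artifact depth ``D`` carries a hatch-level random effect drawn
    from a two-component mixture (most hatches nearly unaffected, a
    fraction strongly affected), while MRI scan groups of 16 are assigned
    in randomized order and carry no effect.
    """

    n_hatches: int = 25
    hatch_size: int = 20
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SDS))
    target_spearman: np.ndarray = field(
        default_factory=default_trait_correlation)
    p_affected_hatch: float = 0.30
    affected_mean_D: float = 0.38
    affected_sd_D: float = 0.08
    unaffected_sd_D: float = 0.02
    bird_sd_D: float = 0.07
    max_D: float = 0.60
    global_shrink: float = 1.0
    depression_width: float = 0.15
    us_noise_sd: float = 0.03
    scan_group_size: int = 16
    max_R_a: float = 6.5
    seed: int = 0

    @property
    def n_birds(self) -> int:
        return self.n_hatches * self.hatch_size


def _validate_correlation(mat: np.ndarray) -> None:
    mat = np.asarray(mat, dtype=float)
    k = len(TRAIT_ORDER)
    if mat.shape != (k, k):
        raise ValueError(f"target matrix must be {k}x{k}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("target correlation matrix is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValueError("target correlation matrix diagonal must be 1")
    w = linalg.eigvalsh(mat)
    if w.min() < -1e-10:
        raise ValueError(
            "target correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {w.min():.3g})")


def _copula_sample(target_spearman: np.ndarray, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Latent standard-normal draws whose rank correlations match target."""
    # Gaussian-copula identity: rho_spearman = (6/pi) asin(r/2)
    r = 2.0 * np.sin(np.pi * np.asarray(target_spearman) / 6.0)
    np.fill_diagonal(r, 1.0)
    w, v = linalg.eigh(r)
    w = np.clip(w, 1e-12, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((n, r.shape[0]))
    return z @ root.T


def _solve_asymmetry(A_target: np.ndarray, T: np.ndarray,
                     r_e: np.ndarray, max_R_a: float) -> np.ndarray:
    """Solve h_a from the cap-cubes sum A = h_a^3 + h_p^3 (vectorised).

    ``A`` is monotone decreasing in ``h_a`` on ``(h_min, T/2]``; values are
    clipped into the feasible window, whose lower end is the symmetric lens
    and whose upper end caps the anterior radius at ``max_R_a``.
    """
    disc = max_R_a ** 2 - r_e ** 2
    h_min = np.where(disc > 0, max_R_a - np.sqrt(np.clip(disc, 0, None)),
                     0.25 * T)
    h_min = np.clip(h_min, 0.05 * T, 0.49 * T)
    lo_A = 2.0 * (T / 2.0) ** 3
    hi_A = h_min ** 3 + (T - h_min) ** 3
    A = np.clip(A_target, lo_A * (1 + 1e-9), hi_A)
    lo, hi = h_min.copy(), T / 2.0
    for _ in range(60):  # bisection on a monotone decreasing function
        mid = 0.5 * (lo + hi)
        val = mid ** 3 + (T - mid) ** 3
        too_big = val > A
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    return 0.5 * (lo + hi)


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort of birds with correlated traits and hatch-level
    shrinkage artifacts.

    Returns ``(table, lenses)``: a DataFrame with one row per bird (in vivo
    traits, labels and ground-truth lens parameters) and the matching list
    of :class:`LensSpec` phantom lenses.  The in vivo ultrasound lens
    thickness is the pre-shrinkage thickness plus measurement noise, so the
    correlation between it and the post-shrinkage (MRI) thickness degrades
    as the shrinkage variance grows.
    """
    _validate_correlation(spec.target_spearman)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed)]))
    n = spec.n_birds
    z = _copula_sample(spec.target_spearman, n, rng)
    traits = {}
    for j, name in enumerate(TRAIT_ORDER):
        traits[name] = spec.trait_means[name] + spec.trait_sds[name] * z[:, j]

    T = np.clip(traits["lens_thickness"], 0.5, None)
    r_e = np.clip(traits["lens_eq_diam"], 1.0, None) / 2.0
    V = traits["lens_volume"]
    # invert V = pi/6 (3 r_e^2 T + h_a^3 + h_p^3) for the cap asymmetry
    A_target = 6.0 * V / np.pi - 3.0 * r_e ** 2 * T
    h_a = _solve_asymmetry(A_target, T, r_e, spec.max_R_a)
    h_p = T - h_a
    R_a = (r_e ** 2 + h_a ** 2) / (2.0 * h_a)
    R_p = (r_e ** 2 + h_p ** 2) / (2.0 * h_p)
    V_geom = (np.pi / 3.0) * (h_a ** 2 * (3 * R_a - h_a)
                              + h_p ** 2 * (3 * R_p - h_p))

    hatch = np.repeat(np.arange(1, spec.n_hatches + 1), spec.hatch_size)
    affected = rng.random(spec.n_hatches) < spec.p_affected_hatch
    hatch_mean_D = np.where(
        affected,
        np.clip(rng.normal(spec.affected_mean_D, spec.affected_sd_D,
                           spec.n_hatches), 0.0, None),
        np.abs(rng.normal(0.0, spec.unaffected_sd_D, spec.n_hatches)))
    D = hatch_mean_D[hatch - 1] + rng.normal(0.0, spec.bird_sd_D, n)
    D = np.clip(D, 0.0, np.minimum(spec.max_D, 0.75 * h_a))

    order = rng.permutation(n)
    scan_group = np.empty(n, dtype=int)
    scan_group[order] = np.arange(n) // spec.scan_group_size + 1
    sex = rng.integers(0, 2, n)

    us_thickness = T + rng.normal(0.0, spec.us_noise_sd, n)

    table = pd.DataFrame({
        "bird_id": np.arange(1, n + 1),
        "hatch": hatch,
        "scan_group": scan_group,
        "sex": np.where(sex == 0, "F", "M"),
        "body_mass_g": traits["body_mass"],
        "body_length_mm": traits["body_length"],
        "eye_weight_g": traits["eye_weight"],
        "eye_eq_diam_mm": traits["eye_eq_diam"],
        "axial_length_mm": traits["axial_length"],
        "corneal_radius_mm": traits["corneal_radius"],
        "us_lens_thickness_mm": us_thickness,
        "true_T_mm": T,
        "true_eq_diam_mm": 2.0 * r_e,
        "true_volume_mm3": V_geom,
        "true_Ra_mm": R_a,
        "true_Rp_mm": R_p,
        "true_D_mm": D,
    })
    lenses = [
        LensSpec(R_a=R_a[i], R_p=R_p[i], T=T[i],
                 depression_depth=D[i],
                 depression_width=spec.depression_width,
                 global_shrink=spec.global_shrink)
        for i in range(n)
    ]
    return table, lenses


def sample_lens_specs(n: int, seed: int = 0, biconvex: bool = True,
                      depression_depth: float | None = None):
    """Draw ``n`` lens specs from the cohort trait distribution.

    Convenience for phantom studies: ``biconvex=True`` forces ``D = 0``;
    a fixed ``depression_depth`` overrides the hatch-mixture artifact.
    Returns ``(specs, truths)``.
    """
    cs = CohortSpec(n_hatches=1, hatch_size=n, seed=seed)
    _, lenses = simulate_cohort(cs)
    out = []
    for lens in lenses:
        if biconvex:
            lens = replace(lens, depression_depth=0.0)
        elif depression_depth is not None:
            lens = replace(lens, depression_depth=depression_depth)
        out.append(lens)
    truths = [lens_ground_truth(sp) for sp in out]
    return out, truths
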