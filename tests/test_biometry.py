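"""Mesh biometry: axis, thickness, diameter, volume, sphere fits, kidney
classification."""

import warnings

import numpy as np
import pytest
import trimesh

from conftest import true_occupancy_mask
from lensmetry import biometry, meshfit, phantom
from lensmetry.biometry import (LensAxis, classify_kidney, define_axis,
                                axial_thickness, equatorial_diameter,
                                fit_surface_sphere, measure_lens,
                                mesh_volume)


@pytest.fixture(scope="module")
def sphere_mesh():
    m = meshfit.init_mesh(8192)
    return trimesh.Trimesh(vertices=3.0 * np.asarray(m.vertices),
                           faces=m.faces, process=False)


@pytest.fixture(scope="module")
def biconvex_mesh(std_lens):
    """Mesh wrapped onto the true occupancy of the standard lens."""
    eye = phantom.make_eye(std_lens)
    vol = phantom.voxelize_eye(eye, 0.115, 3, snr=None)
    mask = true_occupancy_mask(eye.lens, vol)
    wrapped = meshfit.shrink_wrap(mask, intensity=vol.data)
    return meshfit.smooth_vertices(wrapped, 10), eye


@pytest.fixture(scope="module")
def kidney_mesh(kidney_lens):
    eye = phantom.make_eye(kidney_lens)
    vol = phantom.voxelize_eye(eye, 0.115, 3, snr=None)
    mask = true_occupancy_mask(eye.lens, vol)
    wrapped = meshfit.shrink_wrap(mask, intensity=vol.data)
    return meshfit.smooth_vertices(wrapped, 10), eye


class TestDefineAxis:
    def test_sphere_thickness_independent_of_anchor(self, sphere_mesh):
        rng = np.random.default_rng(0)
        for _ in range(3):
            idx = rng.integers(len(sphere_mesh.vertices))
            ax = define_axis(sphere_mesh,
                             anterior_point=sphere_mesh.vertices[idx])
            assert axial_thickness(sphere_mesh, ax) == pytest.approx(
                6.0, abs=0.01)

    def test_recovers_generating_axis(self, biconvex_mesh):
        mesh, eye = biconvex_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        assert abs(ax.direction @ eye.axis) > np.cos(np.deg2rad(1.0))

    def test_off_surface_point_rejected(self, biconvex_mesh):
        mesh, eye = biconvex_mesh
        with pytest.raises(ValueError, match="from the surface"):
            define_axis(mesh, anterior_point=eye.lens.center + 10.0)

    def test_explicit_anterior_point_defines_direction(self, biconvex_mesh):
        mesh, eye = biconvex_mesh
        pole = mesh.vertices[np.argmax(mesh.vertices @ eye.axis)]
        ax = define_axis(mesh, anterior_point=pole)
        assert ax.direction @ eye.axis > 0.99


class TestAxialThickness:
    def test_sphere_diameter(self, sphere_mesh):
        ax = LensAxis(np.array([0, 0, 1.0]), np.zeros(3),
                      np.array([0, 0, 3.0]))
        assert axial_thickness(sphere_mesh, ax) == pytest.approx(6.0,
                                                                 abs=0.01)

    def test_biconvex_ground_truth(self, biconvex_mesh, std_lens):
        mesh, eye = biconvex_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        assert axial_thickness(mesh, ax) == pytest.approx(std_lens.T,
                                                          abs=0.05)

    def test_kidney_thickness_reduced_by_depth(self, kidney_mesh,
                                               kidney_lens):
        mesh, eye = kidney_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        want = kidney_lens.T - kidney_lens.depression_depth
        assert axial_thickness(mesh, ax) == pytest.approx(want, abs=0.05)


class TestEquatorialDiameter:
    def test_sphere(self, sphere_mesh):
        ax = LensAxis(np.array([0, 0, 1.0]), np.zeros(3),
                      np.array([0, 0, 3.0]))
        assert equatorial_diameter(sphere_mesh, ax) == pytest.approx(
            6.0, abs=0.02)

    def test_biconvex_matches_analytic_base_circle(self, biconvex_mesh,
                                                   std_lens):
        mesh, eye = biconvex_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        want = 2.0 * std_lens.geometry.r_e
        assert equatorial_diameter(mesh, ax) == pytest.approx(want,
                                                              abs=0.23)


class TestMeshVolume:
    def test_unit_sphere_closed_form(self):
        m = meshfit.init_mesh(32768)
        assert mesh_volume(m) == pytest.approx(4 * np.pi / 3, rel=1e-3)

    def test_inward_winding_detected_and_corrected(self, sphere_mesh):
        flipped = trimesh.Trimesh(vertices=sphere_mesh.vertices,
                                  faces=sphere_mesh.faces[:, ::-1],
                                  process=False)
        with pytest.warns(UserWarning, match="inward"):
            v = mesh_volume(flipped)
        assert v == pytest.approx(mesh_volume(sphere_mesh), rel=1e-12)

    def test_translation_invariance(self, sphere_mesh):
        moved = trimesh.Trimesh(
            vertices=sphere_mesh.vertices + np.array([137.0, -55.0, 9.0]),
            faces=sphere_mesh.faces, process=False)
        assert mesh_volume(moved) == pytest.approx(
            mesh_volume(sphere_mesh), rel=1e-9)

    def test_open_mesh_rejected(self, sphere_mesh):
        open_mesh = trimesh.Trimesh(vertices=sphere_mesh.vertices,
                                    faces=sphere_mesh.faces[:-10],
                                    process=False)
        with pytest.raises(ValueError, match="closed"):
            mesh_volume(open_mesh)

    def test_biconvex_analytic_volume(self, biconvex_mesh, std_lens):
        mesh, _ = biconvex_mesh
        assert mesh_volume(mesh) == pytest.approx(
            std_lens.geometry.volume, rel=0.02)


class TestSphereFit:
    def test_exact_sphere_both_surfaces(self, sphere_mesh):
        ax = LensAxis(np.array([0, 0, 1.0]), np.zeros(3),
                      np.array([0, 0, 3.0]))
        for side in ("anterior", "posterior"):
            fit = fit_surface_sphere(sphere_mesh, ax, side)
            assert fit.radius == pytest.approx(3.0, abs=0.05)

    def test_biconvex_recovers_both_radii(self, biconvex_mesh, std_lens):
        mesh, eye = biconvex_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        ant = fit_surface_sphere(mesh, ax, "anterior")
        post = fit_surface_sphere(mesh, ax, "posterior")
        assert ant.radius == pytest.approx(std_lens.R_a, abs=0.1)
        assert post.radius == pytest.approx(std_lens.R_p, abs=0.1)

    def test_powell_matches_dense_grid_search(self, biconvex_mesh):
        """Powell optimum vs a zooming 2-parameter grid search."""
        mesh, eye = biconvex_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        fit = fit_surface_sphere(mesh, ax, "anterior")
        pts = biometry._cone_vertices(mesh, ax, "anterior", 30.0)
        f = biometry._sphere_objective(pts, ax)
        t_powell = float((fit.center - ax.point) @ ax.direction)
        x = np.array([t_powell, fit.radius])
        f_powell = f(x)
        center, width = x.copy(), 0.2
        f_grid = np.inf
        for _ in range(5):  # zooming grid: final spacing ~2e-6 mm
            ts = np.linspace(center[0] - width, center[0] + width, 41)
            rs = np.linspace(center[1] - width, center[1] + width, 41)
            vals = np.array([[f([t, r]) for r in rs] for t in ts])
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            f_grid = vals[i, j]
            center = np.array([ts[i], rs[j]])
            width /= 10.0
        assert abs(f_powell - f_grid) < 1e-8

    def test_free_center_matches_constrained_on_symmetric_lens(
            self, biconvex_mesh, std_lens):
        mesh, eye = biconvex_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        free = fit_surface_sphere(mesh, ax, "anterior", free_center=True)
        assert free.radius == pytest.approx(std_lens.R_a, abs=0.1)

    def test_too_few_cone_vertices_rejected(self):
        m = meshfit.init_mesh(128)  # only 66 vertices in total
        coarse = trimesh.Trimesh(vertices=3.0 * np.asarray(m.vertices),
                                 faces=m.faces, process=False)
        ax = LensAxis(np.array([0, 0, 1.0]), np.zeros(3),
                      np.array([0, 0, 3.0]))
        with pytest.raises(ValueError, match="cone"):
            fit_surface_sphere(coarse, ax, "anterior")


class TestClassifyKidney:
    def test_biconvex_is_not_kidney(self, biconvex_mesh):
        mesh, eye = biconvex_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        ant = fit_surface_sphere(mesh, ax, "anterior")
        kidney, depth, _ = classify_kidney(mesh, ax, ant)
        assert not kidney
        assert depth < 0.05

    def test_dented_lens_depth_recovered(self, kidney_mesh, kidney_lens):
        mesh, eye = kidney_mesh
        ax = define_axis(mesh, anterior_hint=eye.axis)
        ant = fit_surface_sphere(mesh, ax, "anterior")
        kidney, depth, _ = classify_kidney(mesh, ax, ant)
        assert kidney
        assert depth == pytest.approx(kidney_lens.depression_depth,
                                      abs=0.1)

    def test_depth_monotone_in_generated_depth(self, std_lens):
        depths = []
        for D in (0.0, 0.15, 0.3, 0.45):
            sp = phantom.LensSpec(R_a=std_lens.R_a, R_p=std_lens.R_p,
                                  T=std_lens.T, depression_depth=D)
            eye = phantom.make_eye(sp)
            vol = phantom.voxelize_eye(eye, 0.115, 3, snr=None)
            mask = true_occupancy_mask(eye.lens, vol)
            mesh = meshfit.smooth_vertices(
                meshfit.shrink_wrap(mask, face_budget=8192), 10)
            ax = define_axis(mesh, anterior_hint=eye.axis)
            ant = fit_surface_sphere(mesh, ax, "anterior")
            depths.append(classify_kidney(mesh, ax, ant)[1])
        assert all(b >= a for a, b in zip(depths, depths[1:]))
        assert depths[-1] - depths[0] > 0.3


class TestMeasureLens:
    def test_full_biometry_consistent(self, biconvex_mesh, std_lens):
        mesh, eye = biconvex_mesh
        res = measure_lens(mesh, anterior_hint=eye.axis)
        assert res.axial_thickness == pytest.approx(std_lens.T, abs=0.05)
        assert res.volume == pytest.approx(std_lens.geometry.volume,
                                           rel=0.02)
        assert not res.kidney

    def test_rigid_motion_equivariance(self, std_lens):
        """Measurements are invariant (to voxel tolerance) under a rigid
        transform of the phantom before voxelisation."""
        rng = np.random.default_rng(5)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        results = []
        for ax_dir, shift in [((0, 0, 1.0), (0, 0, 0)),
                              (axis, (0.31, -0.17, 0.23))]:
            eye = phantom.make_eye(std_lens, center=shift, axis=ax_dir)
            vol = phantom.voxelize_eye(eye, 0.23, 3, snr=None)
            mask = true_occupancy_mask(eye.lens, vol)
            mesh = meshfit.smooth_vertices(
                meshfit.shrink_wrap(mask, face_budget=8192), 10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results.append(measure_lens(mesh, anterior_hint=ax_dir))
        a, b = results
        tol = 0.23
        assert abs(a.axial_thickness - b.axial_thickness) < tol
        assert abs(a.equatorial_diameter - b.equatorial_diameter) < tol
        assert abs(a.r_anterior - b.r_anterior) < tol
        assert abs(a.volume - b.volume) / a.volume < 0.03
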