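"""Phantom generator: cap geometry, dent deformation, voxelisation, array
assembly and cohort simulation."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from lensmetry import phantom
from lensmetry.phantom import (CohortSpec, GeometryInfeasibleError, LensSpec,
                               assemble_array, lens_ground_truth,
                               lens_occupancy, make_eye,
                               sample_lens_specs, simulate_cohort,
                               solve_biconvex_geometry, voxelize_eye)


def mc_biconvex_volume(R_a, R_p, T, n=2_000_000, seed=0):
    """Independent Monte-Carlo volume of the two-cap solid.

    Rejection sampling in the bounding box with the cap inequalities
    written out locally (not via the package's occupancy function).
    """
    g = solve_biconvex_geometry(R_a, R_p, T)
    rng = np.random.default_rng(seed)
    za, zp = g.h_a - R_a, R_p - g.h_p
    inside = 0
    chunk = 1_000_000
    done = 0
    while done < n:
        m = min(chunk, n - done)
        x = rng.uniform(-g.r_e, g.r_e, m)
        y = rng.uniform(-g.r_e, g.r_e, m)
        z = rng.uniform(-g.h_p, g.h_a, m)
        r2 = x * x + y * y
        hit = np.where(z >= 0, r2 + (z - za) ** 2 <= R_a ** 2,
                       r2 + (z - zp) ** 2 <= R_p ** 2)
        inside += int(hit.sum())
        done += m
    box = (2 * g.r_e) ** 2 * (g.h_a + g.h_p)
    return box * inside / n


class TestBiconvexGeometry:
    def test_degenerate_full_sphere(self):
        g = solve_biconvex_geometry(2.0, 2.0, 4.0)
        assert g.h_a == g.h_p == 2.0
        assert g.r_e == pytest.approx(2.0)
        assert g.volume == pytest.approx(4.0 / 3.0 * np.pi * 8.0, rel=1e-12)

    @pytest.mark.parametrize("R,T", [(3.0, 2.0), (2.5, 2.4), (4.0, 1.5)])
    def test_mirror_symmetry(self, R, T):
        g = solve_biconvex_geometry(R, R, T)
        assert g.h_a == pytest.approx(T / 2)
        assert g.h_p == pytest.approx(T / 2)

    def test_shared_base_residual(self):
        g = solve_biconvex_geometry(3.0, 3.5, 2.4)
        assert abs(g.h_a * (2 * 3.0 - g.h_a)
                   - g.h_p * (2 * 3.5 - g.h_p)) < 1e-10

    def test_volume_against_monte_carlo(self):
        g = solve_biconvex_geometry(3.0, 3.5, 2.4)
        mc = mc_biconvex_volume(3.0, 3.5, 2.4)
        assert abs(mc - g.volume) / g.volume < 0.005

    @pytest.mark.parametrize("R_a,R_p,T", [
        (1.0, 1.0, 3.0),     # caps thinner than the solid: no closing root
        (0.5, 3.0, 2.4),     # anterior cap would exceed a hemisphere
        (-1.0, 2.0, 1.0),    # invalid sign
    ])
    def test_infeasible_geometry_rejected(self, R_a, R_p, T):
        with pytest.raises(GeometryInfeasibleError):
            solve_biconvex_geometry(R_a, R_p, T)

    def test_random_feasible_lenses_match_monte_carlo(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            R_a = rng.uniform(2.8, 4.5)
            R_p = rng.uniform(2.2, 3.2)
            T = rng.uniform(2.0, 2.7)
            g = solve_biconvex_geometry(R_a, R_p, T)
            mc = mc_biconvex_volume(R_a, R_p, T, n=1_000_000,
                                    seed=rng.integers(2 ** 31))
            assert abs(mc - g.volume) / g.volume < 0.01


class TestKidneyDeformation:
    def test_identity_when_depth_zero(self, std_lens):
        assert phantom.axial_extent(std_lens) == pytest.approx(
            std_lens.T, abs=2e-3)

    def test_pole_displaced_by_depth(self):
        sp = LensSpec(R_a=3.0, R_p=3.5, T=2.4, depression_depth=0.4,
                      depression_width=0.5)
        assert phantom.axial_extent(sp) == pytest.approx(2.0, abs=3e-3)

    def test_global_shrink_scales_extent(self):
        sp = LensSpec(R_a=3.0, R_p=3.5, T=2.4, depression_depth=0.4,
                      depression_width=0.5, global_shrink=0.95)
        assert phantom.axial_extent(sp) == pytest.approx(0.95 * 2.0,
                                                         abs=3e-3)

    def test_dent_is_anterior_only(self, kidney_lens):
        """Posterior surface must be untouched by the anterior dent."""
        g = kidney_lens.geometry
        z = np.linspace(-1.5 * g.h_p, 0.0, 2000)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        pristine = LensSpec(R_a=kidney_lens.R_a, R_p=kidney_lens.R_p,
                            T=kidney_lens.T)
        assert np.array_equal(lens_occupancy(kidney_lens, pts),
                              lens_occupancy(pristine, pts))

    def test_deep_dent_warns(self):
        with pytest.warns(UserWarning, match="dent"):
            LensSpec(R_a=3.6, R_p=2.6, T=2.35, depression_depth=0.75)


class TestVoxelize:
    def test_noiseless_sphere_volume(self):
        sphere = LensSpec(R_a=3.0, R_p=3.0, T=6.0)
        eye = make_eye(sphere, lens_offset_frac=0.0)
        vol = voxelize_eye(eye, 0.23, 3, snr=None)
        lv = eye.levels
        mid = 0.5 * (lv.lens + lv.humor)
        occ_vol = (vol.data > mid).sum() * vol.voxel_size ** 3
        analytic = 4.0 / 3.0 * np.pi * 27.0
        shell = 4.0 * np.pi * 9.0 * vol.voxel_size  # one voxel-shell
        assert abs(occ_vol - analytic) < shell

    def test_paper_resolution_grid(self, std_eye):
        vol = voxelize_eye(std_eye, 0.115, 1, snr=None)
        assert vol.voxel_size == pytest.approx(0.115)

    def test_deterministic_under_seed(self, std_eye):
        a = voxelize_eye(std_eye, 0.4, 2, snr=10, seed=99)
        b = voxelize_eye(std_eye, 0.4, 2, snr=10, seed=99)
        assert np.array_equal(a.data, b.data)
        c = voxelize_eye(std_eye, 0.4, 2, snr=10, seed=100)
        assert not np.array_equal(a.data, c.data)

    def test_voxel_conservation_converges(self, std_lens):
        """Noiseless occupancy volume approaches the analytic volume as the
        voxel size shrinks: each error sits inside a half-voxel-shell bound
        that itself decreases with voxel size."""
        g = std_lens.geometry
        truth = g.volume
        area = 2 * np.pi * (std_lens.R_a * g.h_a + std_lens.R_p * g.h_p)
        for vs in (0.46, 0.23, 0.115):
            eye = make_eye(std_lens)
            vol = voxelize_eye(eye, vs, 3, snr=None)
            lv = eye.levels
            mid = 0.5 * (lv.lens + lv.humor)
            occ = (vol.data > mid).sum() * vs ** 3
            assert abs(occ - truth) < 0.5 * area * vs
        assert abs(occ - truth) / truth < 0.01  # finest grid within 1%

    def test_lens_outside_fov_rejected(self, std_lens):
        eye = make_eye(std_lens)
        with pytest.raises(ValueError, match="field of view"):
            voxelize_eye(eye, 0.23, 1, snr=None, fov_mm=4.0)


class TestAssembleArray:
    def test_sixteen_disjoint_lens_components(self, small_array):
        from scipy import ndimage
        vol, _ = small_array
        bright = vol.data > 150.0  # lens phase only
        labels, n = ndimage.label(bright, structure=np.ones((3, 3, 3)))
        sizes = ndimage.sum_labels(bright, labels,
                                   index=np.arange(1, n + 1))
        assert (sizes > 50).sum() == 16

    def test_manifest_marks_inverted_cell(self, small_array):
        _, manifest = small_array
        inv = [c for c in manifest["cells"] if c["inverted"]]
        assert len(inv) == 1
        assert inv[0]["eye_id"] == 16
        assert inv[0]["anterior_axis"][2] == -1.0

    def test_wrong_eye_count_rejected(self):
        specs, _ = sample_lens_specs(15, seed=0)
        eyes = [make_eye(lens=sp) for sp in specs]
        with pytest.raises(ValueError, match="16 eyes"):
            assemble_array(eyes)

    def test_exactly_one_inverted_required(self):
        specs, _ = sample_lens_specs(16, seed=0)
        eyes = [make_eye(lens=sp) for sp in specs]  # none inverted
        with pytest.raises(ValueError, match="inverted"):
            assemble_array(eyes)


class TestCohort:
    def test_copula_recovers_target_rank_correlations(self):
        spec = CohortSpec(seed=5)
        table, _ = simulate_cohort(spec)
        cols = ["true_volume_mm3", "true_eq_diam_mm", "true_T_mm",
                "axial_length_mm", "corneal_radius_mm", "eye_weight_g",
                "eye_eq_diam_mm", "body_mass_g", "body_length_mm"]
        rho = sps.spearmanr(table[cols].to_numpy()).statistic
        target = spec.target_spearman
        tol = 3.0 / np.sqrt(len(table) - 3)  # 3 SE of a null Spearman
        assert np.abs(rho - target).max() < tol

    def test_custom_volume_eyeweight_correlation(self):
        """A coherent target with rho(volume, eye weight) ~ 0.6 is
        reproduced by the sampled cohort within 2 SE-scale slack."""
        target = phantom.build_trait_correlation(
            size_loadings={"lens_eq_diam": 0.72, "eye_weight": 0.82})
        iv, ie = (phantom.TRAIT_ORDER.index("lens_volume"),
                  phantom.TRAIT_ORDER.index("eye_weight"))
        assert target[iv, ie] == pytest.approx(0.6, abs=0.02)
        spec = CohortSpec(seed=2, target_spearman=target)
        table, _ = simulate_cohort(spec)
        got = sps.spearmanr(table["true_volume_mm3"],
                            table["eye_weight_g"]).statistic
        assert abs(got - target[iv, ie]) < 0.08

    def test_zero_shrinkage_limit(self):
        spec = CohortSpec(seed=3, p_affected_hatch=0.0,
                          unaffected_sd_D=0.0, bird_sd_D=0.0)
        table, lenses = simulate_cohort(spec)
        assert (table["true_D_mm"] == 0).all()
        assert all(sp.depression_depth == 0 for sp in lenses)
        rho = sps.spearmanr(table["true_T_mm"],
                            table["us_lens_thickness_mm"]).statistic
        assert rho > 0.9  # only ultrasound measurement noise remains

    def test_cohort_size_from_hatches(self):
        table, lenses = simulate_cohort(CohortSpec(n_hatches=25,
                                                   hatch_size=20, seed=0))
        assert len(table) == 500 == len(lenses)
        assert table["hatch"].nunique() == 25

    def test_non_psd_matrix_rejected(self):
        bad = phantom.default_trait_correlation().copy()
        bad[0, 1] = bad[1, 0] = -0.99  # contradicts the rest of the matrix
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_cohort(CohortSpec(target_spearman=bad))

    def test_deterministic_under_seed(self):
        t1, _ = simulate_cohort(CohortSpec(n_hatches=4, hatch_size=10,
                                           seed=9))
        t2, _ = simulate_cohort(CohortSpec(n_hatches=4, hatch_size=10,
                                           seed=9))
        assert t1.equals(t2)

    def test_ground_truth_consistent_with_cap_geometry(self):
        table, lenses = simulate_cohort(CohortSpec(n_hatches=2,
                                                   hatch_size=10, seed=1))
        for i, sp in enumerate(lenses[:5]):
            g = sp.geometry
            assert table.loc[i, "true_eq_diam_mm"] == pytest.approx(
                2 * g.r_e, rel=1e-9)
            assert table.loc[i, "true_volume_mm3"] == pytest.approx(
                g.volume, rel=1e-9)

    def test_kidney_prevalence_near_one_third(self):
        table, _ = simulate_cohort(CohortSpec(seed=1))
        prev = (table["true_D_mm"] > 0.15).mean()
        assert 0.2 < prev < 0.45


def test_ground_truth_accounts_for_dent_and_shrink():
    sp = LensSpec(R_a=3.6, R_p=2.6, T=2.35, depression_depth=0.3,
                  global_shrink=0.9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gt = lens_ground_truth(sp)
    assert gt.T == pytest.approx(0.9 * (2.35 - 0.3))
    assert gt.eq_diameter == pytest.approx(0.9 * 2 * sp.geometry.r_e)
    assert gt.D == pytest.approx(0.9 * 0.3)
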