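import numpy as np
import pingouin as pg
import pytest

from somitekit.io import VoxelGeometry
from somitekit.synth import (
    ROUNDED_DIAMETER_UM,
    MotionModel,
    TissueModel,
    export_ground_truth,
    generate_cell_packing,
    load_ground_truth,
    render_membrane_frame,
    render_membrane_plane,
    simulate_divisions,
    simulate_motion,
    simulate_movie,
    stage_preset,
)


class TestModels:
    def test_sink_required_exactly_for_directed(self):
        with pytest.raises(ValueError, match="sink"):
            MotionModel(mode="directed", sink=None)
        with pytest.raises(ValueError, match="sink"):
            MotionModel(mode="random", sink=(1.0, 1.0))
        MotionModel(mode="directed", sink=(5.0, 5.0))  # ok

    def test_tissue_validation(self):
        with pytest.raises(ValueError):
            TissueModel(n_cells=0)
        with pytest.raises(ValueError):
            TissueModel(division_rate_per_hr=-1)
        assert TissueModel().division_duration_min == 25.0


class TestPacking:
    def test_two_disjoint_spheres(self):
        tissue = TissueModel(domain_um=(50, 50, 50), n_cells=2, radius_mean_um=3.0)
        centres, radii = generate_cell_packing(tissue, seed=0)
        assert len(centres) == 2
        gap = np.linalg.norm(centres[0] - centres[1])
        assert gap >= 0.9 * (radii[0] + radii[1])

    def test_mid_stage_lateral_domain_packing(self):
        # the study's mid-stage lateral-domain census: 212 cells in a
        # 32 x 41 x 20 µm box
        tissue = TissueModel(domain_um=(32, 41, 20), n_cells=212, radius_mean_um=1.5)
        centres, radii = generate_cell_packing(tissue, seed=3)
        assert centres.shape == (212, 3)
        assert np.all(centres >= radii[:, None] - 1e-9)
        assert np.all(centres <= np.array([32, 41, 20]) - radii[:, None] + 1e-9)

    def test_deterministic_per_seed(self):
        tissue = TissueModel(domain_um=(40, 40, 20), n_cells=50)
        a = generate_cell_packing(tissue, seed=7)
        b = generate_cell_packing(tissue, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_infeasible_packing_raises(self):
        tissue = TissueModel(domain_um=(10, 10, 10), n_cells=200, radius_mean_um=2.5)
        with pytest.raises(RuntimeError, match="infeasible"):
            generate_cell_packing(tissue, seed=0, max_tries_per_cell=50)


class TestMotion:
    domain = (100.0, 100.0, 10.0)

    def test_zero_speed_is_stationary(self):
        centres = np.array([[10.0, 10.0, 5.0], [50.0, 60.0, 5.0]])
        motion = MotionModel(mode="random", mean_speed=0.0, speed_sd=0.0)
        pos = simulate_motion(centres, motion, 5, self.domain, 20.0, seed=0)
        for t in range(5):
            np.testing.assert_array_equal(pos[t], centres)

    def test_full_drift_points_exactly_at_sink(self):
        centres = np.array([[10.0, 10.0, 5.0], [80.0, 20.0, 5.0]])
        motion = MotionModel(
            mode="directed", mean_speed=0.2, speed_sd=0.05, sink=(50.0, 50.0),
            drift_weight=1.0,
        )
        pos = simulate_motion(centres, motion, 4, self.domain, 20.0, seed=1)
        for t in range(1, 4):
            step = pos[t, :, :2] - pos[t - 1, :, :2]
            to_sink = np.array([50.0, 50.0]) - pos[t - 1, :, :2]
            cos = np.sum(step * to_sink, axis=1) / (
                np.linalg.norm(step, axis=1) * np.linalg.norm(to_sink, axis=1)
            )
            np.testing.assert_allclose(cos, 1.0, atol=1e-9)

    def test_random_mode_step_angles_uniform(self):
        """Rayleigh circular-uniformity oracle on pooled step headings."""
        centres = np.column_stack(
            [
                np.random.default_rng(0).uniform(20, 80, 500),
                np.random.default_rng(1).uniform(20, 80, 500),
                np.full(500, 5.0),
            ]
        )
        motion = MotionModel(mode="random", mean_speed=0.1, speed_sd=0.02)
        pos = simulate_motion(centres, motion, 10, self.domain, 20.0, seed=5)
        steps = np.diff(pos[:, :, :2], axis=0).reshape(-1, 2)
        angles = np.arctan2(steps[:, 1], steps[:, 0])
        z, p = pg.circ_rayleigh(angles)
        assert p > 0.01

    def test_reflection_keeps_cells_inside(self):
        centres = np.array([[1.0, 1.0, 5.0], [99.0, 99.0, 5.0]])
        motion = MotionModel(mode="random", mean_speed=0.5, speed_sd=0.2)
        pos = simulate_motion(centres, motion, 20, self.domain, 20.0, seed=2)
        assert np.all(pos[:, :, 0] >= 0) and np.all(pos[:, :, 0] <= 100)
        assert np.all(pos[:, :, 1] >= 0) and np.all(pos[:, :, 1] <= 100)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            simulate_motion(np.zeros((1, 3)), MotionModel(), 1, self.domain, 20.0, 0)


class TestDivisions:
    def test_zero_rate_empty_schedule(self):
        sched = simulate_divisions(100, 0.0, 25.0, 180.0, seed=0)
        assert len(sched) == 0

    def test_poisson_mean_recovers_mid_stage_rate(self):
        """4.4 events/hr over 180 min -> mean 13.2 events (Poisson oracle)."""
        counts = [
            len(simulate_divisions(300, 4.4, 25.0, 180.0, seed=s)) for s in range(200)
        ]
        assert np.mean(counts) == pytest.approx(13.2, abs=0.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_divisions(10, -1.0, 25.0, 180.0, seed=0)

    def test_daughters_conserve_parent_volume(self, geometry):
        tissue = TissueModel(
            domain_um=(60, 60, 4),
            n_cells=20,
            radius_mean_um=3.0,
            division_rate_per_hr=6.0,
            growth_rate_um3_per_hr=0.0,
        )
        motion = MotionModel(mode="random", mean_speed=0.0, speed_sd=0.0)
        _, gt = simulate_movie(tissue, motion, 10, geometry, seed=4, render=None)
        assert len(gt.divisions) > 0
        totals = gt.frame_volumes["total_volume_um3"].to_numpy()
        np.testing.assert_allclose(totals, totals[0], rtol=1e-9)


class TestRendering:
    def test_zero_cells_is_pure_noise(self, geometry):
        img = render_membrane_frame(
            np.empty((0, 3)), np.empty(0), (10, 10, 5), geometry, noise={"snr": 10},
            seed=0,
        )
        assert img.shape == (int(round(5 / 0.51)), 40, 40)
        assert img.max() < 0.5  # no structure, only noise

    def test_single_sphere_shell_radius(self, geometry):
        """Maximal intensity sits on a shell of the true radius ±1 voxel."""
        r = 5.0
        img = render_membrane_frame(
            np.array([[15.0, 15.0, 10.0]]), np.array([r]), (30, 30, 20), geometry,
            psf_sigma_um=0.2, noise=None, seed=0,
        )
        zc = int(round(10 / geometry.dz))
        sl = img[zc]
        yy, xx = np.mgrid[: sl.shape[0], : sl.shape[1]]
        rad_um = np.hypot(
            (yy - 15 / geometry.dy) * geometry.dy, (xx - 15 / geometry.dx) * geometry.dx
        )
        bright = rad_um[sl > 0.8 * sl.max()]
        assert abs(np.median(bright) - r) < max(geometry.dx, geometry.dz)

    def test_noise_and_blur_off_gives_binary_shell(self, geometry):
        img = render_membrane_plane(
            np.array([[10.0, 10.0]]), np.array([3.0]), (20, 20), geometry,
            psf_sigma_um=0.0, noise=None, seed=0,
        )
        assert set(np.unique(img)) <= {0.0, 1.0}
        assert img.sum() > 0

    def test_rounded_cell_rendered_as_large_filled_disk(self, geometry):
        img = render_membrane_plane(
            np.array([[20.0, 20.0]]), np.array([3.0]), (40, 40), geometry,
            rounded=np.array([True]), psf_sigma_um=0.0, noise=None, seed=0,
        )
        # filled area ≈ π(D/2)² for the rounded diameter
        area_um2 = img.sum() * geometry.dx * geometry.dy
        expected = np.pi * (ROUNDED_DIAMETER_UM / 2) ** 2
        assert area_um2 == pytest.approx(expected, rel=0.1)

    def test_deterministic_per_seed(self, geometry):
        kw = dict(noise={"snr": 5}, seed=11)
        a = render_membrane_plane(
            np.array([[10.0, 10.0]]), np.array([3.0]), (20, 20), geometry, **kw
        )
        b = render_membrane_plane(
            np.array([[10.0, 10.0]]), np.array([3.0]), (20, 20), geometry, **kw
        )
        np.testing.assert_array_equal(a, b)


class TestMovieAndGroundTruth:
    def test_movie_determinism(self, geometry):
        tissue = TissueModel(domain_um=(40, 40, 4), n_cells=10, radius_mean_um=3.0)
        motion = MotionModel(mode="random", mean_speed=0.1, speed_sd=0.05)
        s1, g1 = simulate_movie(tissue, motion, 4, geometry, seed=9, noise={"snr": 8})
        s2, g2 = simulate_movie(tissue, motion, 4, geometry, seed=9, noise={"snr": 8})
        np.testing.assert_array_equal(s1.data, s2.data)
        assert g1.tracks.equals(g2.tracks)

    def test_linear_volume_growth(self, geometry):
        """Total true volume follows V0 + g·t within 2%."""
        g_rate = 60.0  # µm³/hr
        tissue = TissueModel(
            domain_um=(60, 60, 4), n_cells=30, radius_mean_um=3.0,
            growth_rate_um3_per_hr=g_rate,
        )
        motion = MotionModel(mode="random", mean_speed=0.05, speed_sd=0.02)
        _, gt = simulate_movie(tissue, motion, 10, geometry, seed=2, render=None)
        v = gt.frame_volumes["total_volume_um3"].to_numpy()
        t_hr = gt.frame_volumes["t_min"].to_numpy() / 60.0
        expected = v[0] + g_rate * t_hr
        np.testing.assert_allclose(v, expected, rtol=0.02)

    def test_directed_net_displacement_aligns_with_sink(self, geometry):
        tissue = TissueModel(domain_um=(200, 200, 4), n_cells=40, radius_mean_um=3.0)
        motion = MotionModel(
            mode="directed", mean_speed=0.2, speed_sd=0.05, sink=(600.0, 600.0),
            drift_weight=0.9,
        )
        _, gt = simulate_movie(tissue, motion, 10, geometry, seed=3, render=None)
        start = gt.tracks.query("frame == 0").set_index("track_id")
        end = gt.tracks.query("frame == 9").set_index("track_id")
        delta = end[["x_um", "y_um"]] - start[["x_um", "y_um"]]
        mean_angle = np.degrees(np.arctan2(delta["y_um"].mean(), delta["x_um"].mean()))
        assert abs(mean_angle - 45.0) < 10.0  # sink bearing is 45°

    def test_every_true_cell_appears_in_every_frame(self, geometry):
        tissue = TissueModel(domain_um=(40, 40, 4), n_cells=15, radius_mean_um=3.0)
        motion = MotionModel(mode="random", mean_speed=0.1, speed_sd=0.05)
        _, gt = simulate_movie(tissue, motion, 5, geometry, seed=6, render=None)
        per_frame = gt.tracks.groupby("frame")["track_id"].count()
        assert (per_frame >= 15).all()

    def test_ground_truth_round_trip(self, geometry, tmp_path):
        tissue = TissueModel(
            domain_um=(40, 40, 4), n_cells=10, radius_mean_um=3.0,
            division_rate_per_hr=3.0,
        )
        motion = MotionModel(mode="random", mean_speed=0.1, speed_sd=0.05)
        _, gt = simulate_movie(tissue, motion, 6, geometry, seed=8, render=None)
        export_ground_truth(gt, tmp_path)
        back = load_ground_truth(tmp_path)
        assert back.tracks.equals(gt.tracks)
        np.testing.assert_allclose(
            back.frame_volumes["total_volume_um3"],
            gt.frame_volumes["total_volume_um3"],
        )
        assert back.seed == gt.seed


class TestStagePresets:
    def test_reported_speeds_and_rates(self):
        dom = (100.0, 100.0, 4.0)
        early = stage_preset("early", dom)
        mid = stage_preset("mid", dom)
        late = stage_preset("late", dom)
        assert (early["motion"].mean_speed, early["motion"].speed_sd) == (0.14, 0.08)
        assert (mid["motion"].mean_speed, mid["motion"].speed_sd) == (0.21, 0.11)
        assert (late["motion"].mean_speed, late["motion"].speed_sd) == (0.06, 0.03)
        assert early["division_rate_per_hr"] == 1.7
        assert mid["division_rate_per_hr"] == 4.4
        assert late["division_rate_per_hr"] == 0.3

    def test_unknown_stage(self):
        with pytest.raises(ValueError):
            stage_preset("ancient", (10, 10, 10))
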