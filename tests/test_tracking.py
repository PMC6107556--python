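import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somitekit.io import ImageSequence, VoxelGeometry
from somitekit.synth import render_membrane_plane
from somitekit.tracking import (
    CellTrack,
    Spot,
    angle_distribution,
    detect_spots,
    directionality_index,
    link_spots_lap,
    preprocess_for_tracking,
    track_metrics,
    tracks_to_table,
)


def _spots(frame, pts):
    return [Spot(frame, float(x), float(y)) for x, y in pts]


def _track(pts, t0=0):
    return CellTrack(_spots_seq(pts, t0))


def _spots_seq(pts, t0=0):
    return [Spot(t0 + i, float(x), float(y)) for i, (x, y) in enumerate(pts)]


def brute_force_links(src, dst, max_dist):
    """Exhaustive optimal partial matching: minimizes the summed squared
    link distances plus max_dist² per unlinked spot on either side."""
    n, m = len(src), len(dst)
    alt = max_dist**2
    best_cost, best_links = n * alt + m * alt, []
    for k in range(0, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                d2 = [
                    (src[i][0] - dst[j][0]) ** 2 + (src[i][1] - dst[j][1]) ** 2
                    for i, j in zip(rows, cols)
                ]
                if any(c > alt for c in d2):
                    continue
                cost = sum(d2) + (n - k) * alt + (m - k) * alt
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_links = sorted(zip(rows, cols))
    return best_links


def _lap_links_from_tracks(spots_by_frame, tracks):
    """Recover per-frame-pair link sets from linked tracks."""
    index = {}
    for f, spots in enumerate(spots_by_frame):
        for j, s in enumerate(spots):
            index[id(s)] = (f, j)
    links = set()
    for tr in tracks:
        for a, b in zip(tr.spots[:-1], tr.spots[1:]):
            fa, ia = index[id(a)]
            fb, ib = index[id(b)]
            links.add((fa, ia, ib))
    return links


class TestPreprocess:
    def test_constant_movie_maps_to_zero(self, geometry):
        seq = ImageSequence(np.full((3, 1, 64, 64), 7.0), geometry)
        out = preprocess_for_tracking(seq)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_gradient_background_removed_blob_kept(self, geometry):
        yy, xx = np.mgrid[:128, :128]
        gradient = 0.5 + 0.4 * xx / 128
        blob = np.exp(-((yy - 64.0) ** 2 + (xx - 64.0) ** 2) / (2 * 6.0**2))
        img = np.clip(gradient - 0.45 * blob, 0, None)  # dark blob on gradient
        seq = ImageSequence(img[None, None], geometry)
        out = preprocess_for_tracking(seq).data[0, 0]
        peak = out[50:78, 50:78].max()
        assert peak > 0
        # background residual well below the blob's response
        corners = max(out[:20, :20].max(), out[:20, -20:].max(), out[-20:, -20:].max())
        assert corners < 0.1 * peak

    def test_inversion_turns_dark_nuclei_into_detected_spots(self, geometry):
        img = np.full((96, 96), 1.0)
        yy, xx = np.mgrid[:96, :96]
        img[np.hypot(yy - 48, xx - 48) < 8] = 0.1  # dark nucleus
        seq = ImageSequence(img[None, None], geometry)
        out = preprocess_for_tracking(seq).data[0, 0]
        spots = detect_spots(out, geometry, 0, expected_diameter_um=4.0)
        assert len(spots) >= 1
        assert np.hypot(spots[0].x_um - 12.0, spots[0].y_um - 12.0) < 1.0

    def test_invalid_radius(self, geometry):
        seq = ImageSequence(np.zeros((2, 1, 8, 8)), geometry)
        with pytest.raises(ValueError):
            preprocess_for_tracking(seq, rolling_ball_radius_px=0)


class TestDetectSpots:
    def test_five_blobs_localized_within_half_micron(self, geometry):
        truth = np.array([[10.0, 10.0], [30.0, 12.0], [12.0, 30.0], [32.0, 32.0], [21.0, 20.0]])
        img = np.zeros((160, 160))
        yy, xx = np.mgrid[:160, :160]
        for x, y in truth:
            img += np.exp(
                -((yy - y / 0.25) ** 2 + (xx - x / 0.25) ** 2) / (2 * 6.0**2)
            )
        spots = detect_spots(img, geometry, 0, expected_diameter_um=5.0)
        assert len(spots) == 5
        found = np.array([(s.x_um, s.y_um) for s in spots])
        for x, y in truth:
            assert np.min(np.hypot(found[:, 0] - x, found[:, 1] - y)) < 0.5

    def test_blank_frame_no_spots(self, geometry):
        assert detect_spots(np.zeros((64, 64)), geometry, 0) == []

    def test_infinite_threshold_no_spots(self, geometry, rng):
        img = rng.random((64, 64))
        assert detect_spots(img, geometry, 0, quality_threshold=np.inf) == []


class TestLAPLinking:
    def test_two_persistent_spots_two_tracks(self):
        frames = [_spots(f, [(0.0, 0.0), (30.0, 30.0)]) for f in range(5)]
        # nudge positions slightly per frame
        frames = [
            _spots(f, [(0.0 + 0.1 * f, 0.0), (30.0, 30.0 + 0.1 * f)])
            for f in range(5)
        ]
        tracks = link_spots_lap(frames, max_link_distance_um=5.0)
        assert sorted(len(t) for t in tracks) == [5, 5]

    def test_jump_beyond_gate_splits_track(self):
        frames = [
            _spots(0, [(0.0, 0.0)]),
            _spots(1, [(1.0, 0.0)]),
            _spots(2, [(20.0, 0.0)]),  # jump > 5 µm
            _spots(3, [(21.0, 0.0)]),
        ]
        tracks = link_spots_lap(frames, max_link_distance_um=5.0)
        assert sorted(len(t) for t in tracks) == [2, 2]

    def test_gap_closing_bridges_single_missing_frame(self):
        frames = [
            _spots(0, [(0.0, 0.0)]),
            _spots(1, [(1.0, 0.0)]),
            _spots(2, []),
            _spots(3, [(3.0, 0.0)]),
            _spots(4, [(4.0, 0.0)]),
        ]
        assert len(link_spots_lap(frames, 5.0, allow_gap=0)) == 2
        assert len(link_spots_lap(frames, 5.0, allow_gap=1)) == 1

    def test_matches_brute_force_on_fixed_scenes(self, rng):
        """LAP equals exhaustive optimal assignment, ≤6 spots/frame."""
        for trial in range(20):
            frames = []
            for f in range(4):
                k = int(rng.integers(0, 7))
                frames.append(_spots(f, rng.uniform(0, 30, size=(k, 2))))
            tracks = link_spots_lap(frames, max_link_distance_um=8.0)
            got = _lap_links_from_tracks(frames, tracks)
            want = set()
            for f in range(3):
                src = [(s.x_um, s.y_um) for s in frames[f]]
                dst = [(s.x_um, s.y_um) for s in frames[f + 1]]
                for i, j in brute_force_links(src, dst, 8.0):
                    want.add((f, i, j))
            assert got == want

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 7), st.integers(0, 7), st.integers(0, 10**6))
    def test_matches_brute_force_property(self, n, m, seed):
        rng = np.random.default_rng(seed)
        src = rng.uniform(0, 25, size=(n, 2))
        dst = rng.uniform(0, 25, size=(m, 2))
        frames = [_spots(0, src), _spots(1, dst)]
        tracks = link_spots_lap(frames, max_link_distance_um=10.0)
        got = {
            (i, j)
            for (f, i, j) in _lap_links_from_tracks(frames, tracks)
        }
        want = set(brute_force_links([tuple(p) for p in src], [tuple(p) for p in dst], 10.0))
        assert got == want

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            link_spots_lap([], max_link_distance_um=-1.0)


class TestTrackMetrics:
    def test_straight_track_along_x(self):
        tr = _track([(0, 0), (4, 0), (8, 0), (12, 0)])
        theta, net, path, speed = track_metrics(tr, dt_min=20.0)
        assert theta == pytest.approx(0.0)
        assert net == pytest.approx(12.0)
        assert path == pytest.approx(12.0)
        assert speed == pytest.approx(0.2)

    def test_circular_mean_of_symmetric_steps(self):
        # +45° then −45° steps of equal length average to 0°
        tr = _track([(0, 0), (1, 1), (2, 0)])
        theta, *_ = track_metrics(tr, 20.0)
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_wraparound_headings(self):
        # headings 359° and 1° must average to 0°, not 180°
        a = np.radians(359.0)
        b = np.radians(1.0)
        tr = _track([(0.0, 0.0), (np.cos(a), np.sin(a)), (np.cos(a) + np.cos(b), np.sin(a) + np.sin(b))])
        theta, *_ = track_metrics(tr, 20.0)
        assert theta == pytest.approx(0.0, abs=1e-6)

    def test_path_at_least_net(self, rng):
        pts = rng.uniform(0, 10, size=(6, 2))
        _, net, path, _ = track_metrics(_track(pts), 20.0)
        assert path >= net - 1e-12

    def test_requires_two_spots(self):
        with pytest.raises(ValueError):
            track_metrics(_track([(0, 0)]), 20.0)


class TestDirectionality:
    def test_identical_headings_give_one(self):
        tracks = [
            _track([(0, 0), (np.cos(np.radians(37)), np.sin(np.radians(37))),
                    (2 * np.cos(np.radians(37)), 2 * np.sin(np.radians(37)))])
            for _ in range(5)
        ]
        res = directionality_index(tracks, min_track_len=3)
        assert res.resultant_length == pytest.approx(1.0, abs=1e-9)
        assert res.mean_angle_deg == pytest.approx(37.0, abs=1e-6)

    def test_opposite_tracks_cancel(self):
        right = _track([(0, 0), (1, 0), (2, 0)])
        left = _track([(10, 0), (9, 0), (8, 0)])
        res = directionality_index([right, left], min_track_len=3)
        assert res.resultant_length == pytest.approx(0.0, abs=1e-9)

    def test_uniform_angles_expected_resultant(self, rng):
        """E[R] ≈ 0.886/√N for N uniform angles (Monte-Carlo oracle)."""
        n = 100
        draws = []
        for _ in range(1000):
            ang = rng.uniform(-np.pi, np.pi, n)
            draws.append(abs(np.exp(1j * ang).mean()))
        assert np.mean(draws) == pytest.approx(np.sqrt(np.pi) / 2 / np.sqrt(n), abs=0.01)

    def test_short_tracks_excluded(self):
        long = _track([(0, 0), (1, 0), (2, 0)])
        short = _track([(0, 0), (0, 1)])
        res = directionality_index([long, short], min_track_len=3)
        assert res.n_tracks == 1

    def test_no_valid_tracks_rejected(self):
        with pytest.raises(ValueError):
            directionality_index([_track([(0, 0), (1, 0)])], min_track_len=3)


class TestAngleDistribution:
    def test_single_heading_occupies_one_bin(self):
        counts, _ = angle_distribution(np.zeros(7), n_bins=16)
        assert counts.sum() == 7
        assert (counts > 0).sum() == 1

    def test_counts_sum_to_n(self, rng):
        ang = rng.uniform(-180, 180, 333)
        counts, edges = angle_distribution(ang, n_bins=16)
        assert counts.sum() == 333
        assert len(edges) == 17

    def test_uniform_angles_fill_bins_evenly(self, rng):
        from scipy import stats as sps

        ang = rng.uniform(-180, 180, 16000)
        counts, _ = angle_distribution(ang, n_bins=16)
        _, p = sps.chisquare(counts)
        assert p > 0.01

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            angle_distribution(np.zeros(3), n_bins=1)


class TestEndToEnd:
    def test_directed_stage_stands_out_from_random(self, three_stage_scenario):
        """Directed mid-stage movies yield far higher R than random-motion
        early/late movies, and the recovered mean angle points at the
        rostro-medial sink (45°) within 15°."""
        stages = three_stage_scenario["stages"]
        assert stages["mid"]["resultant_length"] > 2 * stages["early"]["resultant_length"]
        assert stages["mid"]["resultant_length"] > 2 * stages["late"]["resultant_length"]
        assert abs(stages["mid"]["mean_angle_deg"] - 45.0) < 15.0

    def test_tracks_round_trip_through_table(self):
        tracks = [_track([(0, 0), (1, 1), (2, 2)]), _track([(5, 5), (6, 5)], t0=2)]
        table = tracks_to_table(tracks)
        assert table["track_id"].nunique() == 2
        assert len(table) == 5
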