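"""Filtering, change-point scoring, anomaly classification, downsampling,
time-offset refinement and GNSS repair."""

import numpy as np
import pytest

from wayfam.preprocess import (
    AnomalyMask,
    MultiRateChannel,
    MultiRateImu,
    PreprocessConfig,
    classify_undesired,
    downsample_imu,
    drop_undesired,
    estimate_time_offset,
    lowpass_filter,
    merge_intervals,
    preprocess_recording,
    project_to_route,
    smooth_gnss,
    sst_change_scores,
)
from wayfam.synthetic_data import GnssTrack


# ---------------------------------------------------------------------------
# low-pass filter


class TestLowpass:
    def test_dc_signal_unchanged(self):
        out = lowpass_filter(np.full(500, 3.7), cutoff_hz=5.0, fs_hz=100.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    def test_stopband_tone_attenuated(self):
        t = np.arange(0, 10, 0.01)
        tone = np.sin(2 * np.pi * 40 * t)
        out = lowpass_filter(tone, cutoff_hz=5.0, fs_hz=100.0)
        mid = slice(100, 900)
        rms = lambda s: np.sqrt(np.mean(s[mid] ** 2))
        assert rms(out) < 0.01 * rms(tone)

    def test_passband_component_preserved(self):
        t = np.arange(0, 10, 0.01)
        slow = np.sin(2 * np.pi * 1 * t)
        out = lowpass_filter(slow + np.sin(2 * np.pi * 40 * t), 5.0, 100.0)
        r = np.corrcoef(out[100:900], slow[100:900])[0, 1]
        assert r > 0.99

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), cutoff_hz=60.0, fs_hz=100.0)


# ---------------------------------------------------------------------------
# SST change scores


class TestSst:
    def test_stationary_sinusoid_scores_low(self):
        t = np.arange(0, 20, 0.01)
        s = np.sin(2 * np.pi * 1.5 * t)
        scores = sst_change_scores(s, window_len=50, lag=25, n_components=2)
        assert scores.max() < 0.1

    def test_step_change_localized(self):
        # band-limited baseline (as after low-pass filtering) + mean step
        t = np.arange(1000) / 100.0
        s = np.sin(2 * np.pi * 1.0 * t)
        t_star = 500
        s[t_star:] += 5.0
        scores = sst_change_scores(s, window_len=50, lag=25, n_components=2)
        assert abs(int(np.argmax(scores)) - t_star) <= 50

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=600)
        a = sst_change_scores(s, window_len=40, lag=20)
        b = sst_change_scores(s + 123.4, window_len=40, lag=20)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sst_change_scores(np.zeros(100), window_len=50, lag=25)


# ---------------------------------------------------------------------------
# undesired classification


def _burst_signal(n=2000, fs=100.0, burst=(10.0, 10.5), peak=15.0):
    t = np.arange(n) / fs
    facc = np.zeros((n, 3))
    sel = (t >= burst[0]) & (t < burst[1])
    facc[sel, 0] = peak * np.sin(np.pi * (t[sel] - burst[0]) / (burst[1] - burst[0]))
    scores = np.zeros(n)
    scores[sel] = 0.5
    return t, facc, scores


class TestClassifyUndesired:
    def test_below_threshold_empty(self):
        t = np.arange(1000) / 100.0
        facc = np.full((1000, 3), 9.0)
        mask = classify_undesired(t, facc, None, threshold_mps2=10.0)
        assert mask.intervals == []
        assert not mask.undesired.any()

    def test_burst_marked_undesired(self):
        t, facc, scores = _burst_signal()
        mask = classify_undesired(t, facc, scores, threshold_mps2=10.0)
        assert len(mask.intervals) == 1
        t0, t1 = mask.intervals[0]
        assert t0 <= 10.0 + 0.05 and t1 >= 10.5 - 0.05
        assert mask.undesired[(t >= 10.1) & (t <= 10.4)].all()

    def test_infinite_threshold_empty(self):
        t, facc, scores = _burst_signal()
        mask = classify_undesired(t, facc, scores, threshold_mps2=np.inf)
        assert mask.intervals == []

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        t = np.arange(3000) / 100.0
        facc = rng.normal(0, 6, (3000, 3))
        lo = classify_undesired(t, facc, None, threshold_mps2=12.0)
        hi = classify_undesired(t, facc, None, threshold_mps2=16.0)
        # raising the threshold never adds undesired samples
        assert not (hi.undesired & ~lo.undesired).any()

    def test_sst_gate_suppresses_flat_score_regions(self):
        t, facc, _ = _burst_signal()
        mask = classify_undesired(t, facc, np.zeros(t.size), threshold_mps2=10.0)
        assert mask.intervals == []


class TestDropUndesired:
    def test_empty_mask_identity(self, recording):
        mask = AnomalyMask(
            t=recording.imu.t, undesired=np.zeros(recording.imu.t.size, bool)
        )
        out = drop_undesired(recording, mask)
        assert out is recording

    def test_interval_removed_from_imu_and_gaze(self, recording):
        mask = AnomalyMask(
            t=recording.imu.t,
            undesired=np.zeros(recording.imu.t.size, bool),
            intervals=[(10.0, 12.0)],
        )
        out = drop_undesired(recording, mask)
        assert not ((out.imu.t >= 10.0) & (out.imu.t <= 12.0)).any()
        assert not ((out.gaze.t >= 10.0) & (out.gaze.t <= 12.0)).any()
        assert out.gnss.t.size == recording.gnss.t.size  # GNSS untouched
        assert (10.0, 12.0) in out.exclusion_intervals

    def test_retained_duration_bookkeeping(self, recording):
        intervals = [(5.0, 7.5), (20.0, 21.0)]
        mask = AnomalyMask(
            t=recording.imu.t,
            undesired=np.zeros(recording.imu.t.size, bool),
            intervals=intervals,
        )
        out = drop_undesired(recording, mask)
        fs = 100.0
        removed = recording.imu.t.size - out.imu.t.size
        expected = sum(t1 - t0 for t0, t1 in intervals) * fs
        assert abs(removed - expected) <= len(intervals) * 2 + 1

    def test_idempotence(self, recording):
        mask = AnomalyMask(
            t=recording.imu.t,
            undesired=np.zeros(recording.imu.t.size, bool),
            intervals=[(3.0, 4.0)],
        )
        once = drop_undesired(recording, mask)
        twice = drop_undesired(once, mask)
        np.testing.assert_array_equal(once.imu.t, twice.imu.t)
        np.testing.assert_array_equal(once.gaze.t, twice.gaze.t)
        assert once.exclusion_intervals == twice.exclusion_intervals


def test_merge_intervals_sorts_and_merges():
    assert merge_intervals([(5, 6), (1, 2), (1.5, 3)]) == [(1, 3), (5, 6)]


# ---------------------------------------------------------------------------
# downsampling


class TestDownsample:
    def _raw(self, acc_values, acc_fs=400.0, rot_fs=100.0, duration=2.0):
        t_rot = np.arange(0, duration, 1 / rot_fs)
        t_acc = np.arange(0, duration, 1 / acc_fs)
        zeros = np.zeros_like(t_rot)
        return MultiRateImu(
            rotation_t=t_rot,
            roll=zeros,
            pitch=zeros,
            yaw=zeros,
            inertial={
                name: MultiRateChannel(t_acc, acc_values(t_acc))
                for name in ("acc_x", "acc_y", "acc_z", "facc_x", "facc_y", "facc_z")
            },
        ), t_rot

    def test_output_on_rotation_timestamps(self):
        raw, t_rot = self._raw(lambda t: np.sin(t))
        out = downsample_imu(raw)
        np.testing.assert_array_equal(out.t, t_rot)

    def test_constant_channel_stays_constant(self):
        raw, _ = self._raw(lambda t: np.full_like(t, 2.5))
        out = downsample_imu(raw)
        np.testing.assert_array_equal(out.acc_x, 2.5)

    def test_linear_ramp_nearest_neighbour_bound(self):
        slope = 4.0
        raw, t_rot = self._raw(lambda t: slope * t)
        out = downsample_imu(raw)
        err = np.abs(out.acc_z - slope * t_rot)
        assert err.max() <= slope * (1 / 800.0) + 1e-12

    def test_empty_rotation_rejected(self):
        raw, _ = self._raw(lambda t: t)
        raw.rotation_t = np.array([])
        with pytest.raises(ValueError):
            downsample_imu(raw)


# ---------------------------------------------------------------------------
# time-offset estimation


class TestTimeOffset:
    def _yaw_with_peak(self, peak_at, fs=100.0, duration=10.0, peak_deg=30.0):
        t = np.arange(0, duration, 1 / fs)
        yaw = np.zeros_like(t)
        yaw += peak_deg * np.exp(-(((t - peak_at) / 0.05) ** 2))
        return t, yaw

    def test_peak_at_t_a_gives_zero(self):
        t, yaw = self._yaw_with_peak(5.0)
        est = estimate_time_offset(t, yaw, t_A=5.0)
        assert est.delta_t == pytest.approx(0.0, abs=1e-9)
        assert est.reliable

    def test_injected_offset_recovered(self):
        t, yaw = self._yaw_with_peak(5.37)
        est = estimate_time_offset(t, yaw, t_A=5.0)
        assert abs(est.delta_t - 0.37) <= 0.01

    def test_flat_yaw_flagged_unreliable(self):
        t = np.arange(0, 10, 0.01)
        est = estimate_time_offset(t, np.full_like(t, 2.0), t_A=5.0)
        assert not est.reliable

    def test_uncovered_window_rejected(self):
        t, yaw = self._yaw_with_peak(5.0)
        with pytest.raises(ValueError):
            estimate_time_offset(t, yaw, t_A=9.8)


# ---------------------------------------------------------------------------
# GNSS repair


def _straight_track(n=60, speed=1.4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    east = speed * t + rng.normal(0, noise, n)
    north = rng.normal(0, noise, n)
    quality = np.array(["ok"] * n, dtype=object)
    return GnssTrack(t=t, east=east, north=north, quality=quality)


class TestSmoothGnss:
    def test_no_flags_identity(self):
        track = _straight_track()
        out = smooth_gnss(track)
        np.testing.assert_array_equal(out.east, track.east)

    def test_collinear_neighbours_stay_on_line(self):
        track = _straight_track()
        track.quality[30] = "inaccurate"
        track.east[30] += 50.0
        out = smooth_gnss(track)
        # equally spaced collinear neighbours -> weighted mean lies on the line
        assert out.east[30] == pytest.approx(1.4 * 30.0, abs=1e-9)
        assert out.north[30] == pytest.approx(0.0, abs=1e-9)

    def test_outlier_repaired_under_two_meters(self):
        track = _straight_track(noise=0.3, seed=3)
        track.quality[25] = "inaccurate"
        track.east[25] += 50.0
        out = smooth_gnss(track)
        residual = np.hypot(out.east[25] - 1.4 * 25.0, out.north[25])
        assert residual < 2.0

    def test_edge_flag_left_unchanged(self):
        track = _straight_track()
        track.quality[0] = "inaccurate"
        track.east[0] += 50.0
        out = smooth_gnss(track)
        assert out.east[0] == track.east[0]


class TestProjectToRoute:
    polyline = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 80.0]])

    def test_point_on_polyline_unchanged(self):
        track = GnssTrack(
            t=[0.0], east=[50.0], north=[0.0], quality=np.array(["ok"], object)
        )
        out = project_to_route(track, self.polyline)
        assert out.east[0] == pytest.approx(50.0)
        assert out.north[0] == pytest.approx(0.0)

    def test_perpendicular_foot(self):
        track = GnssTrack(
            t=[0.0], east=[50.0], north=[5.0], quality=np.array(["ok"], object)
        )
        out = project_to_route(track, self.polyline)
        assert out.east[0] == pytest.approx(50.0)
        assert out.north[0] == pytest.approx(0.0)

    def test_noisy_walk_projects_monotonically(self):
        rng = np.random.default_rng(4)
        t = np.arange(120.0)
        s = 1.4 * t  # arc length along the two legs
        east = np.minimum(s, 100.0) + rng.normal(0, 0.2, t.size)
        north = np.maximum(s - 100.0, 0.0) + rng.normal(0, 0.2, t.size)
        track = GnssTrack(
            t=t, east=east, north=north, quality=np.array(["ok"] * t.size, object)
        )
        out = project_to_route(track, self.polyline)
        from shapely.geometry import LineString, Point

        line = LineString(self.polyline)
        arc = np.array([line.project(Point(e, n)) for e, n in zip(out.east, out.north)])
        frac_nondecreasing = np.mean(np.diff(arc) >= -1e-9)
        assert frac_nondecreasing >= 0.99


# ---------------------------------------------------------------------------
# pipeline composition


def test_preprocess_pipeline_removes_injected_bursts(short_route):
    from dataclasses import replace
    from wayfam.synthetic_data import EffectConfig, generate_recording

    effect = replace(EffectConfig(), anomaly_rate=4.0)
    rec = generate_recording("P0", "familiar", effect, route=short_route, seed=9)
    assert rec.injected_artifacts
    out = preprocess_recording(rec)
    mag = np.max(
        [np.abs(out.imu.facc_x), np.abs(out.imu.facc_y), np.abs(out.imu.facc_z)],
        axis=0,
    )
    # the retained free acceleration no longer carries the burst peaks
    assert mag.max() < effect.anomaly_peak_facc
    assert out.exclusion_intervals


def test_preprocess_matches_manual_composition(recording):
    """preprocess_recording is exactly lowpass -> SST -> classify -> drop
    followed by GNSS smoothing and projection."""
    cfg = PreprocessConfig()
    auto = preprocess_recording(recording, cfg)

    imu = recording.imu
    fs = 1.0 / float(np.median(np.diff(imu.t)))
    facc = np.column_stack([imu.facc_x, imu.facc_y, imu.facc_z])
    filtered = np.column_stack(
        [lowpass_filter(facc[:, j], cfg.lowpass_cutoff_hz, fs) for j in range(3)]
    )
    scores = np.max(
        [
            sst_change_scores(
                filtered[:, j], cfg.sst_window_len, cfg.sst_lag,
                cfg.sst_n_components, step=cfg.sst_step,
            )
            for j in range(3)
        ],
        axis=0,
    )
    mask = classify_undesired(
        imu.t, filtered, scores, cfg.facc_threshold_mps2,
        score_floor=cfg.sst_score_floor, dilate_s=cfg.dilate_s,
    )
    manual = drop_undesired(recording, mask)
    manual_gnss = project_to_route(smooth_gnss(manual.gnss), manual.route.polyline)
    np.testing.assert_array_equal(auto.imu.t, manual.imu.t)
    np.testing.assert_array_equal(auto.gaze.t, manual.gaze.t)
    np.testing.assert_allclose(auto.gnss.east, manual_gnss.east)
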