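"""Stream cleaning and alignment.

The anomaly-removal path follows a fixed order: zero-phase low-pass filtering
of the free-acceleration channels, singular-spectrum-transformation (SST)
change-point scoring, threshold classification of the signal into desired and
undesired parts (default 10 m/s² on the filtered free-acceleration magnitude,
gated by SST score peaks), and removal of the undesired intervals from both
the IMU and the gaze streams. GNSS repair (weighted-average smoothing of
flagged samples, projection onto the route polyline) and multirate IMU
downsampling live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from shapely.geometry import LineString, Point

from .synthetic_data import GnssTrack, ImuStream, Recording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# multirate container + downsampling


@dataclass
class MultiRateChannel:
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class MultiRateImu:
    """Raw IMU output: rotation channels on a 100 Hz clock, inertial channels
    at their native (>= 100 Hz) rates."""

    rotation_t: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    inertial: dict[str, MultiRateChannel]


def _nearest_indices(source_t: np.ndarray, target_t: np.ndarray) -> np.ndarray:
    """Index of the nearest source sample for each target timestamp."""
    idx = np.searchsorted(source_t, target_t)
    idx = np.clip(idx, 1, source_t.size - 1)
    left = source_t[idx - 1]
    right = source_t[idx]
    idx -= (target_t - left) < (right - target_t)
    return idx


def downsample_imu(raw: MultiRateImu) -> ImuStream:
    """Reduce all inertial channels to the rotation clock: each output row
    takes the nearest-in-time raw sample (sample matching, not
    interpolation)."""
    t = np.asarray(raw.rotation_t, dtype=float)
    if t.size == 0:
        raise ValueError("rotation channel is empty")
    cols: dict[str, np.ndarray] = {}
    for name, ch in raw.inertial.items():
        if ch.t.size == 0:
            raise ValueError(f"inertial channel {name!r} is empty")
        cols[name] = ch.values[_nearest_indices(ch.t, t)]
    return ImuStream(
        t=t,
        roll=np.asarray(raw.roll, dtype=float),
        pitch=np.asarray(raw.pitch, dtype=float),
        yaw=np.asarray(raw.yaw, dtype=float),
        **cols,
    )


# ---------------------------------------------------------------------------
# filtering


def lowpass_filter(
    series: np.ndarray, cutoff_hz: float, fs_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; same length as the input."""
    if not 0.0 < cutoff_hz < fs_hz / 2.0:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, dtype=float))


# ---------------------------------------------------------------------------
# singular spectrum transformation


def _trajectory_basis(
    segment: np.ndarray, window_len: int, n_components: int, center: float
):
    """Left singular vectors of the Hankel (trajectory) matrix built from
    ``segment``; columns are lagged subseries of length ``window_len``.

    ``center`` is subtracted before the SVD; past and future matrices share
    one centering constant so the scores are invariant to a constant offset
    of the series while a step in the mean still separates the subspaces.
    """
    n_cols = segment.size - window_len + 1
    idx = np.arange(window_len)[:, None] + np.arange(n_cols)[None, :]
    hankel = segment[idx] - center
    u, _, _ = np.linalg.svd(hankel, full_matrices=False)
    return u[:, :n_components]


def sst_change_scores(
    series: np.ndarray,
    window_len: int = 50,
    lag: int = 25,
    n_components: int = 2,
    step: int = 1,
) -> np.ndarray:
    """Singular-spectrum-transformation change scores.

    At each evaluation point t the past trajectory matrix (subseries ending
    at t) and the future one (starting at t + lag) are compared through their
    principal ``n_components``-dimensional subspaces; the score is 1 minus
    the largest singular value of the product of the two bases — 0 for a
    stationary signal, approaching 1 across a structural change. Scores are
    evaluated every ``step`` samples and held constant in between; the
    returned series matches the input length, with zeros where the past or
    future matrix does not fit.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    span = 2 * window_len - 1  # samples per trajectory matrix segment
    if n <= 2 * span + lag:
        raise ValueError("series too short for the requested SST windows")
    scores = np.zeros(n)
    eval_points = np.arange(span, n - span - lag, max(1, step))
    vals = np.empty(eval_points.size)
    for k, t in enumerate(eval_points):
        past = x[t - span : t + 1]
        future = x[t + lag : t + lag + span + 1]
        center = float(x[t - span : t + lag + span + 1].mean())
        u_p = _trajectory_basis(past, window_len, n_components, center)
        u_f = _trajectory_basis(future, window_len, n_components, center)
        s = np.linalg.svd(u_p.T @ u_f, compute_uv=False)
        # mean alignment of the two principal subspaces (cos² of the
        # canonical angles); 1 when identical, 0 when orthogonal
        overlap = float(np.sum(np.square(s)) / n_components)
        vals[k] = 1.0 - min(overlap, 1.0)
    if eval_points.size:
        # hold each score until the next evaluation point
        full_idx = np.arange(n)
        pos = np.searchsorted(eval_points, full_idx, side="right") - 1
        inside = (full_idx >= eval_points[0]) & (full_idx < n - span - lag)
        scores[inside] = vals[np.clip(pos[inside], 0, vals.size - 1)]
    return scores


# ---------------------------------------------------------------------------
# undesired-interval classification


@dataclass
class AnomalyMask:
    """Desired/undesired classification of an IMU stream."""

    t: np.ndarray
    undesired: np.ndarray  # boolean, True = undesired
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.undesired = np.asarray(self.undesired, dtype=bool)
        if self.t.size != self.undesired.size:
            raise ValueError("mask length must equal stream length")


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs (half-open) of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def merge_intervals(
    intervals: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for t0, t1 in sorted(intervals):
        if out and t0 <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], t1))
        else:
            out.append((t0, t1))
    return out


def classify_undesired(
    t: np.ndarray,
    facc_filtered: np.ndarray,
    scores: np.ndarray | None,
    threshold_mps2: float = 10.0,
    *,
    score_floor: float = 0.05,
    dilate_s: float = 0.25,
) -> AnomalyMask:
    """Mark as undesired the intervals where the per-sample maximum over the
    three filtered free-acceleration channels exceeds ``threshold_mps2`` and
    the SST score shows a contemporaneous peak.

    ``facc_filtered`` is (n, 3); ``scores`` aligned per-sample SST scores or
    None to skip the gating. Intervals are dilated by ``dilate_s`` on each
    side to cover burst shoulders.
    """
    t = np.asarray(t, dtype=float)
    facc = np.atleast_2d(np.asarray(facc_filtered, dtype=float))
    if facc.shape[0] == 3 and facc.shape[1] != 3:
        facc = facc.T
    if facc.shape[0] != t.size:
        raise ValueError("facc channels not aligned with timestamps")
    if scores is not None and len(scores) != t.size:
        raise ValueError("SST scores not aligned with timestamps")
    mag = np.abs(facc).max(axis=1)
    exceed = mag > threshold_mps2
    undesired = np.zeros(t.size, dtype=bool)
    intervals: list[tuple[float, float]] = []
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    guard = int(round(dilate_s * fs))
    for i0, i1 in _bool_runs(exceed):
        if scores is not None:
            lo = max(0, i0 - guard)
            hi = min(t.size, i1 + guard)
            if np.max(scores[lo:hi]) < score_floor:
                continue
        t0 = t[max(0, i0 - guard)]
        t1 = t[min(t.size - 1, i1 - 1 + guard)]
        intervals.append((float(t0), float(t1)))
    intervals = merge_intervals(intervals)
    for t0, t1 in intervals:
        undesired |= (t >= t0) & (t <= t1)
    return AnomalyMask(t=t, undesired=undesired, intervals=intervals)


def drop_undesired(recording: Recording, mask: AnomalyMask) -> Recording:
    """Remove IMU and gaze samples inside the undesired intervals and extend
    the recording's exclusion intervals; GNSS is left untouched."""
    if not mask.intervals:
        return recording

    def keep(ts: np.ndarray) -> np.ndarray:
        k = np.ones(ts.size, dtype=bool)
        for t0, t1 in mask.intervals:
            k &= ~((ts >= t0) & (ts <= t1))
        return k

    imu = recording.imu
    k_imu = keep(imu.t)
    new_imu = ImuStream(
        t=imu.t[k_imu],
        **{ch: getattr(imu, ch)[k_imu] for ch in ImuStream.CHANNELS},
    )
    gaze = recording.gaze
    k_gaze = keep(gaze.t)
    new_gaze = dc_replace(
        gaze, t=gaze.t[k_gaze], x=gaze.x[k_gaze], y=gaze.y[k_gaze]
    )
    exclusions = merge_intervals(
        list(recording.exclusion_intervals) + list(mask.intervals)
    )
    return Recording(
        participant_id=recording.participant_id,
        condition=recording.condition,
        gaze=new_gaze,
        imu=new_imu,
        gnss=recording.gnss,
        route=recording.route,
        events=list(recording.events),
        exclusion_intervals=exclusions,
        injected_artifacts=list(recording.injected_artifacts),
    )


# ---------------------------------------------------------------------------
# time-offset estimation


@dataclass(frozen=True)
class TimeOffsetEstimate:
    """Refinement of a coarse (1 s precision) event time against the yaw
    series: delta_t = t_B - t_A where t_B is the yaw extremum."""

    delta_t: float
    t_A: float
    t_B: float
    reliable: bool = True


def estimate_time_offset(
    yaw_t: np.ndarray,
    yaw: np.ndarray,
    t_A: float,
    *,
    window_s: float = 1.0,
    min_prominence_deg: float = 5.0,
) -> TimeOffsetEstimate:
    """Locate the yaw extremum (max |yaw - local median|) within
    [t_A - window_s, t_A + window_s]; flagged unreliable when the extremum
    prominence is below ``min_prominence_deg``."""
    yaw_t = np.asarray(yaw_t, dtype=float)
    yaw = np.asarray(yaw, dtype=float)
    if yaw_t.size == 0 or yaw_t[0] > t_A - window_s or yaw_t[-1] < t_A + window_s:
        raise ValueError("yaw series does not cover the search window")
    sel = (yaw_t >= t_A - window_s) & (yaw_t <= t_A + window_s)
    seg_t = yaw_t[sel]
    seg = yaw[sel]
    dev = np.abs(seg - np.median(seg))
    i = int(np.argmax(dev))
    t_B = float(seg_t[i])
    reliable = bool(dev[i] >= min_prominence_deg)
    return TimeOffsetEstimate(
        delta_t=t_B - t_A, t_A=float(t_A), t_B=t_B, reliable=reliable
    )


# ---------------------------------------------------------------------------
# GNSS repair


SMOOTH_WEIGHTS = np.array([1.0, 2.0, 2.0, 1.0]) / 6.0  # two-before/two-after


def smooth_gnss(track: GnssTrack) -> GnssTrack:
    """Replace each "inaccurate"-flagged position by the weighted mean of its
    two predecessors and two successors (nearer neighbours weighted double).
    Flagged samples within two samples of the track ends are left unchanged
    with a warning."""
    pos = track.positions.copy()
    flagged = np.flatnonzero(track.quality == "inaccurate")
    for i in flagged:
        if i < 2 or i > track.t.size - 3:
            logger.warning(
                "flagged GNSS sample at t=%.1f too close to track end; left as is",
                track.t[i],
            )
            continue
        neigh = track.positions[[i - 2, i - 1, i + 1, i + 2]]
        pos[i] = SMOOTH_WEIGHTS @ neigh
    quality = track.quality.copy()
    return GnssTrack(
        t=track.t.copy(), east=pos[:, 0], north=pos[:, 1], quality=quality
    )


def project_to_route(track: GnssTrack, polyline: np.ndarray) -> GnssTrack:
    """Snap every position to its nearest point on the route polyline."""
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[0] < 2:
        raise ValueError("polyline needs at least 2 vertices")
    line = LineString(polyline)
    pts = [
        line.interpolate(line.project(Point(e, n)))
        for e, n in zip(track.east, track.north)
    ]
    return GnssTrack(
        t=track.t.copy(),
        east=np.array([p.x for p in pts]),
        north=np.array([p.y for p in pts]),
        quality=track.quality.copy(),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PreprocessConfig:
    lowpass_cutoff_hz: float = 5.0
    lowpass_order: int = 4
    sst_window_len: int = 50
    sst_lag: int = 25
    sst_n_components: int = 2
    sst_step: int = 10
    facc_threshold_mps2: float = 10.0
    sst_score_floor: float = 0.05
    dilate_s: float = 0.25


def preprocess_recording(
    recording: Recording, config: PreprocessConfig | None = None
) -> Recording:
    """Full cleaning pass in the fixed order lowpass → SST → classify →
    drop, then GNSS smoothing and route projection.

    Multirate inputs are assumed already reduced to the rotation clock (the
    generator and the readers both emit single-rate streams); the downsample
    step is therefore the identity here.
    """
    cfg = config or PreprocessConfig()
    imu = recording.imu
    fs = 1.0 / float(np.median(np.diff(imu.t)))
    facc = np.column_stack([imu.facc_x, imu.facc_y, imu.facc_z])
    filtered = np.column_stack(
        [
            lowpass_filter(facc[:, j], cfg.lowpass_cutoff_hz, fs, cfg.lowpass_order)
            for j in range(3)
        ]
    )
    span = 2 * cfg.sst_window_len - 1
    if imu.t.size > 2 * span + cfg.sst_lag:
        # SST scores are only consulted where the threshold is exceeded, so
        # evaluate them locally around each exceedance run
        exceed = np.abs(filtered).max(axis=1) > cfg.facc_threshold_mps2
        scores = np.zeros(imu.t.size)
        margin = 2 * span + cfg.sst_lag + int(round(cfg.dilate_s * fs))
        for i0, i1 in _bool_runs(exceed):
            lo = max(0, i0 - margin)
            hi = min(imu.t.size, i1 + margin)
            if hi - lo <= 2 * span + cfg.sst_lag:
                lo, hi = 0, imu.t.size
            local = np.max(
                [
                    sst_change_scores(
                        filtered[lo:hi, j],
                        cfg.sst_window_len,
                        cfg.sst_lag,
                        cfg.sst_n_components,
                        step=cfg.sst_step,
                    )
                    for j in range(3)
                ],
                axis=0,
            )
            scores[lo:hi] = np.maximum(scores[lo:hi], local)
    else:
        scores = None
    mask = classify_undesired(
        imu.t,
        filtered,
        scores,
        cfg.facc_threshold_mps2,
        score_floor=cfg.sst_score_floor,
        dilate_s=cfg.dilate_s,
    )
    cleaned = drop_undesired(recording, mask)
    smoothed = smooth_gnss(cleaned.gnss)
    projected = project_to_route(smoothed, cleaned.route.polyline)
    cleaned.gnss = projected
    return cleaned
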