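"""Synthetic pedestrian-wayfinding sessions.

Generates per-recording sensor streams — 200 Hz gaze positions, head-mounted
IMU (acceleration, free acceleration, roll/pitch/yaw), a 1 Hz GNSS track,
instruction-request events and a route polyline — whose statistical structure
mirrors an in-situ wayfinding study: gait-band accelerations, slow yaw
scanning, a fixation–saccade renewal process for gaze, GNSS noise, and
occasional cap-touch artifact bursts in free acceleration.

The familiar/unfamiliar contrast is injected through four independently
configurable channels (yaw-oscillation amplitude, acceleration noise,
fixation-dispersion jitter, saccade amplitude), so downstream feature families
can be probed separately. Identical per-condition parameters produce zero
class signal by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CONDITIONS = ("familiar", "unfamiliar")

GAZE_RATE_HZ = 200.0
ROTATION_RATE_HZ = 100.0
ACC_RATE_HZ = 400.0
GNSS_RATE_HZ = 1.0


@dataclass(frozen=True)
class PerCondition:
    """A scalar parameter with one value per familiarity condition."""

    familiar: float
    unfamiliar: float

    def __getitem__(self, condition: str) -> float:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return getattr(self, condition)

    @classmethod
    def both(cls, value: float) -> "PerCondition":
        return cls(familiar=value, unfamiliar=value)


@dataclass(frozen=True)
class EffectConfig:
    """Condition-dependent effect sizes and shared signal parameters.

    Units: angles in degrees, accelerations in m/s², durations in ms,
    gaze dispersion/amplitude in normalized scene units, rates in Hz or
    events per minute as named.
    """

    yaw_osc_amplitude_deg: PerCondition = PerCondition(familiar=10.0, unfamiliar=15.0)
    yaw_osc_freq_hz: PerCondition = PerCondition.both(0.3)
    acc_noise_sd: PerCondition = PerCondition(familiar=0.85, unfamiliar=1.0)
    fixation_dispersion_scale: PerCondition = PerCondition(
        familiar=0.0011, unfamiliar=0.0014
    )
    saccade_amplitude_shape: PerCondition = PerCondition.both(2.0)
    saccade_amplitude_scale: PerCondition = PerCondition(
        familiar=0.055, unfamiliar=0.070
    )
    gait_step_freq_hz: float = 1.8
    fixation_duration_mean_ms: float = 250.0
    fixation_duration_sd_ms: float = 100.0
    walking_speed_mps: float = 1.3
    anomaly_rate: float = 0.5  # artifact bursts per minute
    anomaly_peak_facc: float = 15.0  # m/s², burst peak in free acceleration
    gnss_noise_sd_m: float = 1.5
    gnss_jump_prob: float = 0.02  # per-sample probability of a flagged jump
    gnss_jump_sd_m: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gait_step_freq_hz",
            "fixation_duration_mean_ms",
            "fixation_duration_sd_ms",
            "walking_speed_mps",
            "anomaly_rate",
            "anomaly_peak_facc",
            "gnss_noise_sd_m",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "yaw_osc_amplitude_deg",
            "yaw_osc_freq_hz",
            "acc_noise_sd",
            "fixation_dispersion_scale",
            "saccade_amplitude_shape",
            "saccade_amplitude_scale",
        ):
            pc: PerCondition = getattr(self, name)
            if pc.familiar < 0 or pc.unfamiliar < 0:
                raise ValueError(f"{name} must be >= 0 for both conditions")

    def null_effect(self) -> "EffectConfig":
        """A copy in which both conditions share every parameter (no class
        signal)."""
        out = self
        for name in (
            "yaw_osc_amplitude_deg",
            "yaw_osc_freq_hz",
            "acc_noise_sd",
            "fixation_dispersion_scale",
            "saccade_amplitude_shape",
            "saccade_amplitude_scale",
        ):
            pc: PerCondition = getattr(out, name)
            out = replace(out, **{name: PerCondition.both(pc.familiar)})
        return out


@dataclass
class GazeStream:
    """Gaze positions in normalized scene coordinates (origin top-left,
    x right, y down), nominally 200 Hz."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)


@dataclass
class ImuStream:
    """Head IMU channels on the 100 Hz rotation clock.

    acc_* are raw accelerations (gravity included on z), facc_* are free
    (gravity-removed) accelerations, all m/s²; roll/pitch/yaw in degrees,
    yaw wrapped to (-180, 180].
    """

    t: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    facc_x: np.ndarray
    facc_y: np.ndarray
    facc_z: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray

    CHANNELS = (
        "acc_x", "acc_y", "acc_z",
        "facc_x", "facc_y", "facc_z",
        "roll", "pitch", "yaw",
    )

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in self.CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass
class GnssTrack:
    """1 Hz GNSS positions in planar local coordinates (east, north; meters)
    with a per-sample quality flag in {"ok", "inaccurate"}."""

    t: np.ndarray
    east: np.ndarray
    north: np.ndarray
    quality: np.ndarray  # array of str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.east = np.asarray(self.east, dtype=float)
        self.north = np.asarray(self.north, dtype=float)
        self.quality = np.asarray(self.quality, dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.east, self.north])


@dataclass(frozen=True)
class DecisionPoint:
    vertex_index: int
    junction_id: str
    is_turn: bool


@dataclass(frozen=True)
class RouteGeometry:
    """Route polyline (planar meters) with decision points on its vertices."""

    polyline: np.ndarray  # (n, 2)
    decision_points: tuple[DecisionPoint, ...]
    decision_radius_m: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "polyline", np.asarray(self.polyline, dtype=float)
        )
        object.__setattr__(self, "decision_points", tuple(self.decision_points))
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2:
            raise ValueError("route polyline needs at least 2 vertices")
        for dp in self.decision_points:
            if not 0 <= dp.vertex_index < self.polyline.shape[0]:
                raise ValueError(f"decision point {dp.junction_id} off polyline")

    def junction_position(self, junction_id: str) -> np.ndarray:
        for dp in self.decision_points:
            if dp.junction_id == junction_id:
                return self.polyline[dp.vertex_index]
        raise KeyError(f"unknown junction {junction_id!r}")

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.diff(self.polyline, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    @property
    def length_m(self) -> float:
        return float(self.arc_lengths[-1])


@dataclass(frozen=True)
class InstructionEvent:
    t_request: float
    junction_id: str


@dataclass
class Recording:
    """One participant × one condition: all streams plus route and events."""

    participant_id: str
    condition: str
    gaze: GazeStream
    imu: ImuStream
    gnss: GnssTrack
    route: RouteGeometry
    events: list[InstructionEvent]
    exclusion_intervals: list[tuple[float, float]] = field(default_factory=list)
    #: ground-truth artifact-burst intervals (synthetic recordings only)
    injected_artifacts: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def recording_id(self) -> str:
        return f"{self.participant_id}_{self.condition}"


def default_route(variant: int = 0) -> RouteGeometry:
    """A ~250 m urban-block route with four turn junctions.

    ``variant`` mirrors the study's use of distinct physical routes per
    condition; it rotates the block layout without changing leg lengths.
    """
    legs = [(60.0, 0.0), (0.0, 50.0), (55.0, 0.0), (0.0, -45.0), (50.0, 0.0)]
    if variant % 2 == 1:
        legs = [(dy, dx) for dx, dy in legs]
    pts = [np.zeros(2)]
    for dx, dy in legs:
        pts.append(pts[-1] + np.array([dx, dy]))
    poly = np.array(pts)
    dps = tuple(
        DecisionPoint(vertex_index=i, junction_id=f"J{i}", is_turn=True)
        for i in range(1, len(pts) - 1)
    )
    return RouteGeometry(polyline=poly, decision_points=dps)


def _nominal_walk(route: RouteGeometry, speed: float, rate_hz: float):
    """Noise-free positions along the polyline at constant speed; returns
    (t, positions, arrival_time_by_junction)."""
    arcs = route.arc_lengths
    duration = route.length_m / speed
    t = np.arange(0.0, duration, 1.0 / rate_hz)
    s = t * speed
    east = np.interp(s, arcs, route.polyline[:, 0])
    north = np.interp(s, arcs, route.polyline[:, 1])
    arrivals = {
        dp.junction_id: arcs[dp.vertex_index] / speed
        for dp in route.decision_points
    }
    return t, np.column_stack([east, north]), arrivals


def wrap_degrees(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    wrapped = np.mod(-np.asarray(angle) + 180.0, 360.0)
    return -(wrapped - 180.0)


def _gen_gaze(
    rng: np.random.Generator,
    duration: float,
    effect: EffectConfig,
    condition: str,
) -> GazeStream:
    """Fixation–saccade renewal process: log-normal fixation durations,
    Gaussian within-fixation jitter, gamma saccade amplitudes with
    main-sequence-like durations."""
    mean = effect.fixation_duration_mean_ms
    sd = effect.fixation_duration_sd_ms
    # log-normal parameterized by its own mean/sd
    sigma2 = math.log(1.0 + (sd / mean) ** 2) if mean > 0 else 0.0
    mu = math.log(mean) - sigma2 / 2.0 if mean > 0 else 0.0
    disp = effect.fixation_dispersion_scale[condition]
    amp_shape = effect.saccade_amplitude_shape[condition]
    amp_scale = effect.saccade_amplitude_scale[condition]

    t = np.arange(0.0, duration, 1.0 / GAZE_RATE_HZ)
    x = np.empty_like(t)
    y = np.empty_like(t)
    pos = np.array([0.5, 0.5])
    i = 0
    n = t.size
    while i < n:
        fix_ms = rng.lognormal(mu, math.sqrt(sigma2)) if mean > 0 else 200.0
        n_fix = max(1, int(round(fix_ms / 1000.0 * GAZE_RATE_HZ)))
        j = min(n, i + n_fix)
        x[i:j] = pos[0] + rng.normal(0.0, disp, j - i)
        y[i:j] = pos[1] + rng.normal(0.0, disp, j - i)
        i = j
        if i >= n:
            break
        amp = rng.gamma(amp_shape, amp_scale) if amp_shape > 0 else 0.0
        theta = rng.uniform(0.0, 2.0 * math.pi)
        target = pos + amp * np.array([math.cos(theta), math.sin(theta)])
        target = np.clip(target, 0.05, 0.95)
        # main-sequence-like saccade duration: ~2.2 ms per degree + 21 ms,
        # with ~41 normalized-unit-to-degree scene scale
        sac_ms = 21.0 + 2.2 * amp * 41.0
        n_sac = max(1, int(round(sac_ms / 1000.0 * GAZE_RATE_HZ)))
        k = min(n, i + n_sac)
        frac = np.linspace(0.0, 1.0, k - i, endpoint=False) + 1.0 / max(1, k - i)
        x[i:k] = pos[0] + frac * (target[0] - pos[0])
        y[i:k] = pos[1] + frac * (target[1] - pos[1])
        pos = target
        i = k
    return GazeStream(t=t, x=x, y=y)


def _gen_imu(
    rng: np.random.Generator,
    duration: float,
    effect: EffectConfig,
    condition: str,
    yaw_baseline_deg: float,
    gait_freq_hz: float,
) -> tuple[ImuStream, list[tuple[float, float]]]:
    """IMU channels: gait sinusoid on acc_z, slow yaw scanning oscillation,
    Poisson-placed free-acceleration artifact bursts. Acceleration is
    synthesized at 400 Hz and reduced to the 100 Hz rotation clock by
    nearest-timestamp matching."""
    from .preprocess import MultiRateChannel, MultiRateImu, downsample_imu

    t_rot = np.arange(0.0, duration, 1.0 / ROTATION_RATE_HZ)
    t_acc = np.arange(0.0, duration, 1.0 / ACC_RATE_HZ)
    noise_sd = effect.acc_noise_sd[condition]

    gait = 1.5 * np.sin(2.0 * math.pi * gait_freq_hz * t_acc)
    sway = 0.5 * np.sin(2.0 * math.pi * gait_freq_hz / 2.0 * t_acc)
    bob = 0.4 * np.sin(2.0 * math.pi * 2.0 * gait_freq_hz * t_acc + 0.7)
    facc_x = sway + rng.normal(0.0, noise_sd, t_acc.size)
    facc_y = bob + rng.normal(0.0, noise_sd, t_acc.size)
    facc_z = gait + rng.normal(0.0, noise_sd, t_acc.size)

    # Poisson artifact bursts (cap touches): half-sine pushes |facc| past the
    # configured peak on all three axes.
    n_bursts = rng.poisson(effect.anomaly_rate * duration / 60.0)
    burst_intervals: list[tuple[float, float]] = []
    for _ in range(n_bursts):
        t0 = rng.uniform(0.0, max(duration - 0.5, 0.0))
        width = rng.uniform(0.15, 0.35)
        burst_intervals.append((t0, t0 + width))
        sel = (t_acc >= t0) & (t_acc < t0 + width)
        if not sel.any():
            continue
        phase = (t_acc[sel] - t0) / width
        bump = (effect.anomaly_peak_facc * 1.15) * np.sin(math.pi * phase)
        sign = rng.choice([-1.0, 1.0])
        facc_x[sel] += sign * bump
        facc_y[sel] += sign * bump * 0.8
        facc_z[sel] += sign * bump

    acc_x = facc_x + 0.0
    acc_y = facc_y + 0.0
    acc_z = facc_z + 9.81

    amp = effect.yaw_osc_amplitude_deg[condition]
    freq = effect.yaw_osc_freq_hz[condition]
    phase0 = rng.uniform(0.0, 2.0 * math.pi)
    yaw = (
        yaw_baseline_deg
        + amp * np.sin(2.0 * math.pi * freq * t_rot + phase0)
        + rng.normal(0.0, 1.5, t_rot.size)
    )
    roll = 2.0 * np.sin(2.0 * math.pi * gait_freq_hz / 2.0 * t_rot) + rng.normal(
        0.0, 0.8, t_rot.size
    )
    pitch = -4.0 + 1.5 * np.sin(
        2.0 * math.pi * gait_freq_hz * t_rot + 1.3
    ) + rng.normal(0.0, 0.8, t_rot.size)

    raw = MultiRateImu(
        rotation_t=t_rot,
        roll=roll,
        pitch=pitch,
        yaw=wrap_degrees(yaw),
        inertial={
            "acc_x": MultiRateChannel(t_acc, acc_x),
            "acc_y": MultiRateChannel(t_acc, acc_y),
            "acc_z": MultiRateChannel(t_acc, acc_z),
            "facc_x": MultiRateChannel(t_acc, facc_x),
            "facc_y": MultiRateChannel(t_acc, facc_y),
            "facc_z": MultiRateChannel(t_acc, facc_z),
        },
    )
    return downsample_imu(raw), burst_intervals


def _gen_gnss(
    rng: np.random.Generator,
    route: RouteGeometry,
    effect: EffectConfig,
) -> tuple[GnssTrack, dict[str, float]]:
    t, pos, arrivals = _nominal_walk(route, effect.walking_speed_mps, GNSS_RATE_HZ)
    noisy = pos + rng.normal(0.0, effect.gnss_noise_sd_m, pos.shape)
    quality = np.array(["ok"] * t.size, dtype=object)
    # flagged sudden inaccuracies away from track ends (so smoothing has
    # two neighbours on each side)
    for i in range(2, t.size - 2):
        if rng.uniform() < effect.gnss_jump_prob:
            noisy[i] += rng.normal(0.0, effect.gnss_jump_sd_m, 2)
            quality[i] = "inaccurate"
    track = GnssTrack(t=t, east=noisy[:, 0], north=noisy[:, 1], quality=quality)
    return track, arrivals


def _gen_events(
    rng: np.random.Generator,
    route: RouteGeometry,
    arrivals: dict[str, float],
) -> list[InstructionEvent]:
    """One instruction request per turn decision point, 15–30 s before the
    nominal arrival (clipped to stay after the previous junction)."""
    events = []
    prev_arrival = 0.0
    for dp in route.decision_points:
        if not dp.is_turn:
            continue
        t_arr = arrivals[dp.junction_id]
        lead = rng.uniform(15.0, 30.0)
        t_req = max(t_arr - lead, prev_arrival + 1.0, 0.0)
        if t_req < t_arr:
            events.append(InstructionEvent(t_request=t_req, junction_id=dp.junction_id))
        prev_arrival = t_arr
    return events


def generate_recording(
    participant_id: str,
    condition: str,
    effect: EffectConfig,
    route: RouteGeometry | None = None,
    seed: int | None = None,
    *,
    yaw_baseline_deg: float = 0.0,
    gait_freq_hz: float | None = None,
) -> Recording:
    """Generate one synthetic walk.

    Fully reproducible given ``seed`` (falls back to ``effect.seed``).
    ``yaw_baseline_deg`` and ``gait_freq_hz`` carry participant-level random
    effects when called from :func:`generate_cohort`.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if route is None:
        route = default_route()
    if not any(dp.is_turn for dp in route.decision_points):
        raise ValueError("route has no turn decision point")
    if seed is None:
        seed = effect.seed
    rng = np.random.default_rng(seed)
    if gait_freq_hz is None:
        gait_freq_hz = effect.gait_step_freq_hz

    gnss, arrivals = _gen_gnss(rng, route, effect)
    duration = float(gnss.t[-1]) + 1.0
    imu, bursts = _gen_imu(
        rng, duration, effect, condition, yaw_baseline_deg, gait_freq_hz
    )
    gaze = _gen_gaze(rng, duration, effect, condition)
    events = _gen_events(rng, route, arrivals)
    return Recording(
        participant_id=participant_id,
        condition=condition,
        gaze=gaze,
        imu=imu,
        gnss=gnss,
        route=route,
        events=events,
        injected_artifacts=bursts,
    )


def generate_cohort(
    n_participants: int,
    effect: EffectConfig,
    route_pool: Sequence[RouteGeometry] | None = None,
    seed: int | None = None,
) -> list[Recording]:
    """Two recordings per participant (one per condition), with
    participant-level random effects — baseline yaw offset and gait-frequency
    jitter — shared across that participant's pair."""
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if route_pool is None:
        route_pool = [default_route(0), default_route(1)]
    if not route_pool:
        raise ValueError("route_pool must be non-empty")
    if seed is None:
        seed = effect.seed
    master = np.random.default_rng(seed)
    recordings: list[Recording] = []
    for p in range(n_participants):
        pid = f"P{p:03d}"
        yaw_base = float(master.normal(0.0, 15.0))
        gait = float(
            np.clip(effect.gait_step_freq_hz + master.normal(0.0, 0.08), 0.5, None)
        )
        for c, condition in enumerate(CONDITIONS):
            rec_seed = int(master.integers(0, 2**31 - 1))
            route = route_pool[(2 * p + c) % len(route_pool)]
            recordings.append(
                generate_recording(
                    pid,
                    condition,
                    effect,
                    route=route,
                    seed=rec_seed,
                    yaw_baseline_deg=yaw_base,
                    gait_freq_hz=gait,
                )
            )
    return recordings
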