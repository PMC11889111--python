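"""Fixation/saccade detection and window-level gaze descriptors.

Fixations are detected with the dispersion-threshold algorithm (I-DT):
a candidate window must span at least the duration threshold (default
100 ms) and keep its dispersion — (max x − min x) + (max y − min y) in
normalized scene units — at or below the dispersion threshold (default
0.02); the window is then greedily extended sample by sample. Velocity-based
detection is deliberately not offered: at a 200 Hz gaze rate outdoors it is
unreliable.

Saccade amplitudes are compensated for head rotation using the IMU
orientation change across the inter-fixation gap, mapped to normalized scene
units through a configurable degrees-per-scene-unit calibration (default
from a nominal 82°-field-of-view scene camera). The per-window feature row
carries the 28 descriptors used for familiarity classification: sixteen
fixation statistics, fixation frequency, eight saccade statistics, saccade
amplitude skewness, saccade frequency and the long/short-saccade (g-l)
ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .synthetic_data import GazeStream, ImuStream

DISPERSION_THRESHOLD = 0.02  # normalized scene units
DURATION_THRESHOLD_MS = 100.0
#: degrees of head rotation per normalized scene unit (82° horizontal FOV)
DEG_PER_UNIT = (82.0, 82.0)


@dataclass(frozen=True)
class Fixation:
    t_start: float
    t_end: float
    centroid_x: float
    centroid_y: float
    dispersion: float
    dispersion_x: float
    dispersion_y: float

    @property
    def duration_ms(self) -> float:
        return (self.t_end - self.t_start) * 1000.0


@dataclass(frozen=True)
class Saccade:
    t_start: float
    t_end: float
    amplitude: float  # normalized units, head-rotation compensated
    compensated: bool = True

    @property
    def duration_ms(self) -> float:
        return (self.t_end - self.t_start) * 1000.0


def detect_fixations_idt(
    gaze: GazeStream,
    dispersion_threshold: float = DISPERSION_THRESHOLD,
    duration_threshold_ms: float = DURATION_THRESHOLD_MS,
) -> list[Fixation]:
    """Greedy left-to-right I-DT scan.

    From each start index, the smallest window spanning the duration
    threshold is formed; if its dispersion is within the threshold the window
    grows while dispersion stays within, a fixation is emitted (centroid =
    mean point), and the scan resumes after it; otherwise the start advances
    one sample.
    """
    t, x, y = gaze.t, gaze.x, gaze.y
    n = t.size
    dur_s = duration_threshold_ms / 1000.0
    out: list[Fixation] = []
    i = 0
    while i < n:
        # smallest j with t[j] - t[i] >= dur_s (difference form, so the
        # result is exact under floating-point rounding)
        j = int(np.searchsorted(t, t[i] + dur_s, side="left"))
        while j - 1 > i and t[j - 1] - t[i] >= dur_s:
            j -= 1
        while j < n and t[j] - t[i] < dur_s:
            j += 1
        if j >= n:
            break
        xmin = x[i : j + 1].min()
        xmax = x[i : j + 1].max()
        ymin = y[i : j + 1].min()
        ymax = y[i : j + 1].max()
        if (xmax - xmin) + (ymax - ymin) > dispersion_threshold:
            i += 1
            continue
        while j + 1 < n:
            nxmin = min(xmin, x[j + 1])
            nxmax = max(xmax, x[j + 1])
            nymin = min(ymin, y[j + 1])
            nymax = max(ymax, y[j + 1])
            if (nxmax - nxmin) + (nymax - nymin) > dispersion_threshold:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        out.append(
            Fixation(
                t_start=float(t[i]),
                t_end=float(t[j]),
                centroid_x=float(x[i : j + 1].mean()),
                centroid_y=float(y[i : j + 1].mean()),
                dispersion=float((xmax - xmin) + (ymax - ymin)),
                dispersion_x=float(xmax - xmin),
                dispersion_y=float(ymax - ymin),
            )
        )
        i = j + 1
    return out


def compensate_saccade(
    fix_prev: Fixation,
    fix_next: Fixation,
    imu: ImuStream | None,
    deg_per_unit: tuple[float, float] = DEG_PER_UNIT,
) -> Saccade:
    """Saccade between two consecutive fixations, with the gaze shift
    predicted from the head-orientation change subtracted.

    A head yaw to the right moves a world-fixed target left in scene
    coordinates (x decreases), a pitch up moves it down (y increases, y-down
    convention); the predicted shift is (-Δyaw/deg_x, +Δpitch/deg_y).
    Missing IMU coverage of the gap yields the uncompensated amplitude,
    flagged.
    """
    dx = fix_next.centroid_x - fix_prev.centroid_x
    dy = fix_next.centroid_y - fix_prev.centroid_y
    t0, t1 = fix_prev.t_end, fix_next.t_start
    pred_x = pred_y = 0.0
    compensated = False
    if imu is not None and imu.t.size >= 2 and imu.t[0] <= t0 and imu.t[-1] >= t1:
        i0 = int(np.searchsorted(imu.t, t0, side="left"))
        i1 = min(int(np.searchsorted(imu.t, t1, side="right")), imu.t.size) - 1
        if i1 > i0:
            d_yaw = float(imu.yaw[i1] - imu.yaw[i0])
            d_pitch = float(imu.pitch[i1] - imu.pitch[i0])
            if deg_per_unit[0] > 0:
                pred_x = -d_yaw / deg_per_unit[0]
            if deg_per_unit[1] > 0:
                pred_y = d_pitch / deg_per_unit[1]
            compensated = True
    amplitude = math.hypot(dx - pred_x, dy - pred_y)
    return Saccade(
        t_start=t0, t_end=t1, amplitude=amplitude, compensated=compensated
    )


GAZE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"fix_{q}_{s}"
    for q in ("dur", "disp", "disp_x", "disp_y")
    for s in ("mean", "min", "max", "var")
) + ("fix_freq",) + tuple(
    f"sac_{q}_{s}" for q in ("ampl", "dur") for s in ("mean", "min", "max", "var")
) + ("sac_ampl_skew", "sac_freq", "gl_ratio")


def _stats4(values: np.ndarray) -> tuple[float, float, float, float]:
    """mean/min/max/sample-variance; variance is NaN below 2 events."""
    if values.size == 0:
        return (math.nan,) * 4
    var = float(np.var(values, ddof=1)) if values.size >= 2 else math.nan
    return float(values.mean()), float(values.min()), float(values.max()), var


def gaze_feature_row(
    window_duration_s: float,
    fixations: list[Fixation],
    saccades: list[Saccade],
    amplitude_split: float | None = None,
) -> dict[str, float]:
    """The 28 named gaze descriptors for one window.

    ``amplitude_split`` is the long/short saccade boundary for the g-l ratio
    (per-recording median amplitude); frequencies are events per second.
    Statistics that need at least two events are NaN in sparser windows.
    """
    row: dict[str, float] = {}
    dur = np.array([f.duration_ms for f in fixations])
    disp = np.array([f.dispersion for f in fixations])
    disp_x = np.array([f.dispersion_x for f in fixations])
    disp_y = np.array([f.dispersion_y for f in fixations])
    for name, vals in (
        ("dur", dur), ("disp", disp), ("disp_x", disp_x), ("disp_y", disp_y)
    ):
        m, lo, hi, var = _stats4(vals)
        row[f"fix_{name}_mean"] = m
        row[f"fix_{name}_min"] = lo
        row[f"fix_{name}_max"] = hi
        row[f"fix_{name}_var"] = var
    row["fix_freq"] = len(fixations) / window_duration_s

    amp = np.array([s.amplitude for s in saccades])
    sdur = np.array([s.duration_ms for s in saccades])
    for name, vals in (("ampl", amp), ("dur", sdur)):
        m, lo, hi, var = _stats4(vals)
        row[f"sac_{name}_mean"] = m
        row[f"sac_{name}_min"] = lo
        row[f"sac_{name}_max"] = hi
        row[f"sac_{name}_var"] = var
    row["sac_ampl_skew"] = (
        float(spstats.skew(amp, bias=False)) if amp.size >= 3 else math.nan
    )
    row["sac_freq"] = len(saccades) / window_duration_s

    if amplitude_split is None or amp.size == 0:
        row["gl_ratio"] = math.nan
    else:
        n_short = int(np.sum(amp <= amplitude_split))
        n_long = int(np.sum(amp > amplitude_split))
        row["gl_ratio"] = n_long / n_short if n_short > 0 else math.nan
    assert tuple(row) == GAZE_FEATURE_NAMES
    return row


def extract_gaze_windows(
    gaze: GazeStream,
    imu: ImuStream | None,
    windows,
    dispersion_threshold: float = DISPERSION_THRESHOLD,
    duration_threshold_ms: float = DURATION_THRESHOLD_MS,
    deg_per_unit: tuple[float, float] = DEG_PER_UNIT,
) -> list[dict[str, float]]:
    """Per-window gaze feature rows for a recording.

    Fixations are detected once over the whole recording, saccades built
    between consecutive fixations, the g-l split set to the recording's
    median saccade amplitude, and events assigned to the windows containing
    them (a fixation belongs to the window containing its midpoint).
    """
    fixations = detect_fixations_idt(gaze, dispersion_threshold, duration_threshold_ms)
    saccades = [
        compensate_saccade(a, b, imu, deg_per_unit)
        for a, b in zip(fixations, fixations[1:])
    ]
    split = (
        float(np.median([s.amplitude for s in saccades])) if saccades else None
    )
    rows = []
    for w in windows:
        fx = [
            f for f in fixations
            if w.t0 <= 0.5 * (f.t_start + f.t_end) < w.t1
        ]
        sc = [
            s for s in saccades
            if w.t0 <= 0.5 * (s.t_start + s.t_end) < w.t1
        ]
        rows.append(gaze_feature_row(w.duration, fx, sc, split))
    return rows
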