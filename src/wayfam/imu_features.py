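"""The 99-feature IMU descriptor bank per 3-s window.

Six families, computed on the 100 Hz head-IMU channels:

a. basic statistics (31): min/max/mean/variance of the *relative*
   (per-recording mean-centered) acceleration and orientation channels,
   yaw frequency change (zero-crossing rate of the centered yaw, in Hz),
   and point-to-point amplitudes of acceleration and free acceleration;
b. cepstral coefficients (50): real cepstrum of the acceleration-magnitude
   signal — inverse transform of the log power spectrum — first 50
   coefficients, c0 included;
c. time-domain measures (5): std, energy (time integral of the squared
   signal), min/max/peak-to-peak amplitude of the acceleration magnitude;
d. fundamental period (1): smallest interval between successive amplitude
   peaks, a step-cadence proxy;
e. movement measures (8): movement-intensity mean/variance, signal magnitude
   area, per-axis energy, Shannon entropy of the movement-intensity
   histogram, movement variation;
f. spectral/music measures (4): zero-crossing rate, spectral centroid,
   spectral rolloff (85% energy), chroma-bin mean over 12 log-spaced
   frequency bins.

Relative (mean-centered) channels are used because the device's position and
alignment on the head differ between trials; the centering reference is the
whole recording, applied by the extraction driver before windowing.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps

FS_HZ = 100.0
N_CEPSTRAL = 50
CEPSTRUM_EPS = 1e-12
ENTROPY_BINS = 16
ROLLOFF_FRAC = 0.85
CHROMA_BINS = 12
CHROMA_F_LO = 0.5  # Hz


def _names_stats(prefix: str) -> list[str]:
    return [f"{prefix}_{s}" for s in ("min", "max", "mean", "var")]


BASIC_NAMES: tuple[str, ...] = tuple(
    n
    for ch in ("acc_x", "acc_y", "acc_z", "roll", "pitch", "yaw")
    for n in _names_stats(f"rel_{ch}")
) + ("yaw_freq_change",) + tuple(
    f"p2p_{ch}" for ch in ("acc_x", "acc_y", "acc_z", "facc_x", "facc_y", "facc_z")
)
CEPSTRAL_NAMES: tuple[str, ...] = tuple(f"cep_{i}" for i in range(N_CEPSTRAL))
TDM_NAMES: tuple[str, ...] = (
    "acc_magn_std", "acc_magn_energy", "acc_magn_min", "acc_magn_max",
    "acc_magn_p2p",
)
FP_NAMES: tuple[str, ...] = ("fundamental_period",)
MOVEMENT_NAMES: tuple[str, ...] = (
    "mi_mean", "mi_var", "sma", "energy_x", "energy_y", "energy_z",
    "entropy", "mv",
)
SPECTRAL_NAMES: tuple[str, ...] = (
    "zero_crossing_rate", "spectral_centroid", "spectral_rolloff",
    "chroma_mean",
)

IMU_FEATURE_NAMES: tuple[str, ...] = (
    BASIC_NAMES + CEPSTRAL_NAMES + TDM_NAMES + FP_NAMES + MOVEMENT_NAMES
    + SPECTRAL_NAMES
)
assert len(IMU_FEATURE_NAMES) == 99


def acc_magnitude(acc_x: np.ndarray, acc_y: np.ndarray, acc_z: np.ndarray) -> np.ndarray:
    return np.sqrt(
        np.square(np.asarray(acc_x, float))
        + np.square(np.asarray(acc_y, float))
        + np.square(np.asarray(acc_z, float))
    )


def zero_crossing_count(series: np.ndarray) -> int:
    """Sign changes between consecutive samples (zeros carry the previous
    sign)."""
    s = np.sign(np.asarray(series, dtype=float))
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


def basic_stats(
    rel: dict[str, np.ndarray],
    facc: dict[str, np.ndarray],
    fs: float = FS_HZ,
) -> dict[str, float]:
    """31 basic statistics.

    ``rel`` holds the recording-mean-centered acc_x/y/z, roll, pitch, yaw
    channels; ``facc`` the free-acceleration channels (used only for their
    point-to-point amplitude). Yaw frequency change is the zero-crossing
    rate of the centered yaw in crossings per second.
    """
    out: dict[str, float] = {}
    for ch in ("acc_x", "acc_y", "acc_z", "roll", "pitch", "yaw"):
        v = np.asarray(rel[ch], dtype=float)
        if v.size < 2:
            raise ValueError("basic stats need at least 2 samples")
        out[f"rel_{ch}_min"] = float(v.min())
        out[f"rel_{ch}_max"] = float(v.max())
        out[f"rel_{ch}_mean"] = float(v.mean())
        out[f"rel_{ch}_var"] = float(np.var(v, ddof=1))
    yaw = np.asarray(rel["yaw"], dtype=float)
    duration = (yaw.size - 1) / fs
    out["yaw_freq_change"] = zero_crossing_count(yaw - yaw.mean()) / duration
    for ch in ("acc_x", "acc_y", "acc_z"):
        v = np.asarray(rel[ch], dtype=float)
        out[f"p2p_{ch}"] = float(v.max() - v.min())
    for ch in ("facc_x", "facc_y", "facc_z"):
        v = np.asarray(facc[ch], dtype=float)
        out[f"p2p_{ch}"] = float(v.max() - v.min())
    return out


def cepstral_coeffs(
    acc_mag: np.ndarray, fs: float = FS_HZ, n: int = N_CEPSTRAL
) -> np.ndarray:
    """First ``n`` real-cepstrum coefficients: irfft(log(|rfft(s)|² + ε))."""
    s = np.asarray(acc_mag, dtype=float)
    if s.size < 2 * n:
        raise ValueError(f"window too short for {n} cepstral coefficients")
    spectrum = np.abs(np.fft.rfft(s)) ** 2
    return np.fft.irfft(np.log(spectrum + CEPSTRUM_EPS), n=s.size)[:n]


def time_domain_measures(acc_mag: np.ndarray, fs: float = FS_HZ) -> dict[str, float]:
    s = np.asarray(acc_mag, dtype=float)
    return {
        "acc_magn_std": float(s.std(ddof=0)),
        "acc_magn_energy": float(np.sum(s**2) / fs),
        "acc_magn_min": float(s.min()),
        "acc_magn_max": float(s.max()),
        "acc_magn_p2p": float(s.max() - s.min()),
    }


def fundamental_period(
    acc_mag: np.ndarray,
    fs: float = FS_HZ,
    prominence_scale: float = 0.5,
    smooth_cutoff_hz: float = 5.0,
) -> float:
    """Smallest interval (s) between successive amplitude peaks; peaks must
    clear a prominence of ``prominence_scale`` × window std. NaN below two
    peaks.

    The signal is band-limited (zero-phase Butterworth, default 5 Hz — the
    same gait-band-preserving cutoff used in preprocessing) before peak
    picking, so sample-level noise wiggles do not register as amplitude
    peaks; human step cadence sits well below the cutoff.
    """
    s = np.asarray(acc_mag, dtype=float)
    if smooth_cutoff_hz and 0.0 < smooth_cutoff_hz < fs / 2.0 and s.size > 15:
        sos = sps.butter(2, smooth_cutoff_hz, btype="low", fs=fs, output="sos")
        s = sps.sosfiltfilt(sos, s)
    prom = prominence_scale * float(s.std(ddof=0))
    if prom == 0.0:
        return math.nan
    peaks, _ = sps.find_peaks(s, prominence=prom)
    if peaks.size < 2:
        return math.nan
    return float(np.min(np.diff(peaks)) / fs)


def movement_measures(
    acc_x: np.ndarray, acc_y: np.ndarray, acc_z: np.ndarray, fs: float = FS_HZ
) -> dict[str, float]:
    ax = np.asarray(acc_x, dtype=float)
    ay = np.asarray(acc_y, dtype=float)
    az = np.asarray(acc_z, dtype=float)
    n = ax.size
    mi = acc_magnitude(ax, ay, az)
    duration = n / fs
    sma = float(np.sum(np.abs(ax) + np.abs(ay) + np.abs(az)) * (1.0 / fs) / duration)
    counts, _ = np.histogram(mi, bins=ENTROPY_BINS)
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    mv = float(
        np.sum(np.abs(np.diff(ax)) + np.abs(np.diff(ay)) + np.abs(np.diff(az))) / n
    )
    return {
        "mi_mean": float(mi.mean()),
        "mi_var": float(np.var(mi, ddof=0)),
        "sma": sma,
        "energy_x": float(np.sum(ax**2) / n),
        "energy_y": float(np.sum(ay**2) / n),
        "energy_z": float(np.sum(az**2) / n),
        "entropy": entropy,
        "mv": mv,
    }


def spectral_music_measures(
    acc_mag: np.ndarray, fs: float = FS_HZ, rolloff_frac: float = ROLLOFF_FRAC
) -> dict[str, float]:
    s = np.asarray(acc_mag, dtype=float)
    n = s.size
    centered = s - s.mean()
    zcr = zero_crossing_count(centered) / max(n - 1, 1)
    mag = np.abs(np.fft.rfft(centered))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    total = mag.sum()
    centroid = float((freqs * mag).sum() / total) if total > 0 else math.nan
    energy = mag**2
    etot = energy.sum()
    if etot > 0:
        cum = np.cumsum(energy)
        rolloff = float(freqs[np.searchsorted(cum, rolloff_frac * etot)])
    else:
        rolloff = math.nan
    edges = np.logspace(
        math.log10(CHROMA_F_LO), math.log10(fs / 2.0), CHROMA_BINS + 1
    )
    bin_mag = np.array(
        [mag[(freqs >= lo) & (freqs < hi)].sum() for lo, hi in zip(edges, edges[1:])]
    )
    return {
        "zero_crossing_rate": float(zcr),
        "spectral_centroid": centroid,
        "spectral_rolloff": rolloff,
        "chroma_mean": float(bin_mag.mean()),
    }


def imu_feature_row(
    rel: dict[str, np.ndarray],
    facc: dict[str, np.ndarray],
    fs: float = FS_HZ,
) -> dict[str, float]:
    """All 99 features for one window, in the canonical family order.

    ``rel``: recording-mean-centered acc_x/y/z, roll, pitch, yaw; ``facc``:
    free-acceleration channels. Windows shorter than 1 s yield a missing
    (all-NaN) row.
    """
    n = np.asarray(rel["acc_x"]).size
    if n < fs:
        return {name: math.nan for name in IMU_FEATURE_NAMES}
    mag = acc_magnitude(rel["acc_x"], rel["acc_y"], rel["acc_z"])
    row: dict[str, float] = {}
    row.update(basic_stats(rel, facc, fs))
    row.update({f"cep_{i}": float(c) for i, c in enumerate(cepstral_coeffs(mag, fs))})
    row.update(time_domain_measures(mag, fs))
    row["fundamental_period"] = fundamental_period(mag, fs)
    row.update(movement_measures(rel["acc_x"], rel["acc_y"], rel["acc_z"], fs))
    row.update(spectral_music_measures(mag, fs))
    assert tuple(row) == IMU_FEATURE_NAMES
    return row


def extract_imu_windows(imu, windows, fs: float = FS_HZ) -> list[dict[str, float]]:
    """Per-window IMU feature rows for a recording.

    Acceleration and orientation channels are mean-centered over the whole
    recording ("relative" values) before slicing into windows; free
    acceleration is used raw.
    """
    rel_full = {
        ch: getattr(imu, ch) - getattr(imu, ch).mean()
        for ch in ("acc_x", "acc_y", "acc_z", "roll", "pitch", "yaw")
    }
    facc_full = {ch: getattr(imu, ch) for ch in ("facc_x", "facc_y", "facc_z")}
    rows = []
    for w in windows:
        sel = (imu.t >= w.t0) & (imu.t < w.t1)
        if sel.sum() < 2:
            rows.append({name: math.nan for name in IMU_FEATURE_NAMES})
            continue
        rel = {ch: v[sel] for ch, v in rel_full.items()}
        facc = {ch: v[sel] for ch, v in facc_full.items()}
        rows.append(imu_feature_row(rel, facc, fs))
    return rows
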