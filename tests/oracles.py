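"""Independent, definition-level reference implementations.

Deliberately naive: explicit loops, explicit DFT sums, textbook formulas.
These never share code paths with the package implementations they check.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


# ---------------------------------------------------------------------------
# I-DT fixation detection


def idt_oracle(t, x, y, dispersion_threshold, duration_threshold_ms):
    """Dispersion-threshold fixation detection by exhaustive window
    evaluation: from each start index find the maximal window whose
    dispersion stays within the threshold, recomputing dispersion from
    scratch for every candidate window."""
    t = list(map(float, t))
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(t)
    dur_s = duration_threshold_ms / 1000.0

    def dispersion(i, j):
        xs = x[i : j + 1]
        ys = y[i : j + 1]
        return (max(xs) - min(xs)) + (max(ys) - min(ys))

    fixations = []
    i = 0
    while i < n:
        j = i
        while j < n and t[j] - t[i] < dur_s:
            j += 1
        if j >= n:
            break
        if dispersion(i, j) > dispersion_threshold:
            i += 1
            continue
        while j + 1 < n and dispersion(i, j + 1) <= dispersion_threshold:
            j += 1
        xs = x[i : j + 1]
        ys = y[i : j + 1]
        fixations.append(
            {
                "t_start": t[i],
                "t_end": t[j],
                "centroid_x": sum(xs) / len(xs),
                "centroid_y": sum(ys) / len(ys),
                "dispersion": dispersion(i, j),
                "dispersion_x": max(xs) - min(xs),
                "dispersion_y": max(ys) - min(ys),
            }
        )
        i = j + 1
    return fixations


# ---------------------------------------------------------------------------
# elementary statistics


def mean_oracle(v):
    return sum(v) / len(v)


def var_sample_oracle(v):
    m = mean_oracle(v)
    return sum((x - m) ** 2 for x in v) / (len(v) - 1)


def var_pop_oracle(v):
    m = mean_oracle(v)
    return sum((x - m) ** 2 for x in v) / len(v)


def skew_adjusted_oracle(v):
    """Adjusted Fisher–Pearson sample skewness."""
    n = len(v)
    m = mean_oracle(v)
    m2 = sum((x - m) ** 2 for x in v) / n
    m3 = sum((x - m) ** 3 for x in v) / n
    g1 = m3 / m2**1.5
    return math.sqrt(n * (n - 1)) / (n - 2) * g1


# ---------------------------------------------------------------------------
# spectra via explicit DFT sums


def dft_oracle(s):
    """One-sided DFT magnitudes as an explicit O(n^2) sum."""
    n = len(s)
    n_bins = n // 2 + 1
    out = []
    for k in range(n_bins):
        acc = 0j
        for m, v in enumerate(s):
            acc += v * cmath.exp(-2j * math.pi * k * m / n)
        out.append(acc)
    return out


def cepstrum_oracle(s, n_coeffs, eps=1e-12):
    """Real cepstrum from first principles: log power spectrum of the
    one-sided DFT, inverted with an explicit inverse-DFT sum over the full
    (conjugate-symmetric) spectrum."""
    n = len(s)
    spec = dft_oracle(s)
    logp = [math.log(abs(c) ** 2 + eps) for c in spec]
    # rebuild the full symmetric log-spectrum
    full = list(logp)
    for k in range(n - len(logp)):
        full.append(logp[n // 2 - 1 - k if n % 2 == 0 else n // 2 - k])
    coeffs = []
    for q in range(n_coeffs):
        acc = 0j
        for k, v in enumerate(full):
            acc += v * cmath.exp(2j * math.pi * k * q / n)
        coeffs.append(acc.real / n)
    return coeffs


def spectral_centroid_oracle(s, fs):
    centered = [v - mean_oracle(s) for v in s]
    mags = [abs(c) for c in dft_oracle(centered)]
    n = len(s)
    freqs = [k * fs / n for k in range(len(mags))]
    total = sum(mags)
    return sum(f * m for f, m in zip(freqs, mags)) / total


def spectral_rolloff_oracle(s, fs, frac):
    centered = [v - mean_oracle(s) for v in s]
    energy = [abs(c) ** 2 for c in dft_oracle(centered)]
    n = len(s)
    target = frac * sum(energy)
    acc = 0.0
    for k, e in enumerate(energy):
        acc += e
        if acc >= target:
            return k * fs / n
    return (len(energy) - 1) * fs / n


def chroma_mean_oracle(s, fs, n_bins=12, f_lo=0.5):
    centered = [v - mean_oracle(s) for v in s]
    mags = [abs(c) for c in dft_oracle(centered)]
    n = len(s)
    freqs = [k * fs / n for k in range(len(mags))]
    f_hi = fs / 2.0
    edges = [
        f_lo * (f_hi / f_lo) ** (i / n_bins) for i in range(n_bins + 1)
    ]
    sums = []
    for lo, hi in zip(edges, edges[1:]):
        sums.append(sum(m for f, m in zip(freqs, mags) if lo <= f < hi))
    return mean_oracle(sums)


def zero_crossings_oracle(s):
    signs = []
    prev = 0
    for v in s:
        sign = int(v > 0) - int(v < 0)
        if sign == 0:
            sign = prev
        if sign != 0:
            signs.append(sign)
            prev = sign
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


# ---------------------------------------------------------------------------
# movement / time-domain measures


def energy_integral_oracle(s, fs):
    return sum(v * v for v in s) / fs


def mi_oracle(ax, ay, az):
    return [math.sqrt(a * a + b * b + c * c) for a, b, c in zip(ax, ay, az)]


def sma_oracle(ax, ay, az, fs):
    n = len(ax)
    area = sum(abs(a) + abs(b) + abs(c) for a, b, c in zip(ax, ay, az)) / fs
    return area / (n / fs)


def energy_axis_oracle(s):
    return sum(v * v for v in s) / len(s)


def entropy_oracle(mi, n_bins=16):
    lo, hi = min(mi), max(mi)
    n = len(mi)
    if hi == lo:
        return 0.0
    counts = [0] * n_bins
    for v in mi:
        k = int((v - lo) / (hi - lo) * n_bins)
        counts[min(k, n_bins - 1)] += 1
    h = 0.0
    for c in counts:
        if c:
            p = c / n
            h -= p * math.log2(p)
    return h


def mv_oracle(ax, ay, az):
    n = len(ax)
    total = 0.0
    for i in range(1, n):
        total += abs(ax[i] - ax[i - 1]) + abs(ay[i] - ay[i - 1]) + abs(az[i] - az[i - 1])
    return total / n
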