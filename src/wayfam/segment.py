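"""Matching-to-action segmentation.

A segment spans from the moment a route instruction is requested to the
moment the wayfinder reaches the junction it refers to; segments are the only
parts of a walk used downstream, cut into fixed-width non-overlapping
windows (default 3 s) that form the unit of feature extraction and
classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic_data import GnssTrack, Recording, RouteGeometry

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 3.0
DEFAULT_RADIUS_M = 10.0


@dataclass(frozen=True)
class Segment:
    recording_id: str
    junction_id: str
    t_start: float  # instruction-request time (or clipped sub-span start)
    t_end: float  # junction-arrival time (or clipped sub-span end)

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class Window:
    segment: Segment
    index: int
    t0: float
    duration: float = DEFAULT_WINDOW_S

    @property
    def t1(self) -> float:
        return self.t0 + self.duration


def detect_junction_arrival(
    gnss: GnssTrack,
    route: RouteGeometry,
    junction_id: str,
    radius_m: float = DEFAULT_RADIUS_M,
    t_after: float | None = None,
) -> float | None:
    """First GNSS time at which the position comes within ``radius_m`` of
    the junction vertex (optionally restricted to t >= t_after); None when
    the junction is never reached."""
    target = route.junction_position(junction_id)
    d = np.hypot(gnss.east - target[0], gnss.north - target[1])
    ok = d <= radius_m
    if t_after is not None:
        ok &= gnss.t >= t_after
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    return float(gnss.t[idx[0]])


def _subtract_intervals(
    t0: float, t1: float, exclusions: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """[t0, t1] minus the exclusion intervals, as kept sub-spans."""
    spans = [(t0, t1)]
    for e0, e1 in sorted(exclusions):
        nxt: list[tuple[float, float]] = []
        for s0, s1 in spans:
            if e1 <= s0 or e0 >= s1:
                nxt.append((s0, s1))
                continue
            if e0 > s0:
                nxt.append((s0, e0))
            if e1 < s1:
                nxt.append((e1, s1))
        spans = nxt
    return [(a, b) for a, b in spans if b > a]


def extract_segments(
    recording: Recording, radius_m: float = DEFAULT_RADIUS_M
) -> list[Segment]:
    """One segment per instruction event with a detected arrival; repeated
    requests for the same junction extend one segment from the earliest
    request; spans overlapping exclusion intervals are clipped out (a
    clipped segment may yield several sub-spans)."""
    if not recording.events:
        raise ValueError("recording has no instruction events")
    earliest: dict[str, float] = {}
    for ev in recording.events:
        t = earliest.get(ev.junction_id)
        earliest[ev.junction_id] = ev.t_request if t is None else min(t, ev.t_request)
    segments: list[Segment] = []
    for junction_id, t_request in sorted(earliest.items(), key=lambda kv: kv[1]):
        t_arrival = detect_junction_arrival(
            recording.gnss, recording.route, junction_id, radius_m, t_after=t_request
        )
        if t_arrival is None or t_arrival <= t_request:
            logger.info(
                "no arrival at %s after t=%.1f in %s; event skipped",
                junction_id,
                t_request,
                recording.recording_id,
            )
            continue
        for s0, s1 in _subtract_intervals(
            t_request, t_arrival, recording.exclusion_intervals
        ):
            segments.append(
                Segment(
                    recording_id=recording.recording_id,
                    junction_id=junction_id,
                    t_start=s0,
                    t_end=s1,
                )
            )
    return segments


def window_segments(
    segments: Sequence[Segment], width_s: float = DEFAULT_WINDOW_S
) -> list[Window]:
    """Non-overlapping windows, contiguous from each segment's start;
    trailing remainders shorter than ``width_s`` are discarded."""
    if width_s <= 0:
        raise ValueError("window width must be positive")
    windows: list[Window] = []
    for seg in segments:
        n = math.floor(seg.duration / width_s + 1e-9)
        for i in range(n):
            windows.append(
                Window(segment=seg, index=i, t0=seg.t_start + i * width_s,
                       duration=width_s)
            )
    return windows
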