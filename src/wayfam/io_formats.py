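"""On-disk session layout, feature tables and reports.

One directory per recording: ``gaze.csv`` (t,x,y), ``imu.csv`` (t plus nine
channels), ``gnss.csv`` (t,east,north,quality), ``events.csv``
(t_request,junction_id), ``route.geojson`` (LineString plus decision-point
Point features) and ``manifest.json``. Units are fixed package-wide:
distances in meters, times in seconds, angles in degrees, gaze in normalized
scene coordinates (origin top-left, x right, y down). Feature tables are CSV
with a JSON column manifest alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze_features import GAZE_FEATURE_NAMES
from .imu_features import IMU_FEATURE_NAMES
from .synthetic_data import (
    CONDITIONS,
    DecisionPoint,
    EffectConfig,
    GazeStream,
    PerCondition,
    GnssTrack,
    ImuStream,
    InstructionEvent,
    Recording,
    RouteGeometry,
)

SCHEMA_VERSION = 1

#: canonical units per quantity; the conventions other modules assume
UNITS = {
    "distance": "m",
    "time": "s",
    "angle": "deg",
    "gaze": "normalized scene units (origin top-left, x right, y down)",
    "acceleration": "m/s^2",
}

METADATA_COLUMNS = ("participant_id", "recording_id", "window_id", "condition")

FLOAT_FMT = "%.17g"  # round-trips float64 exactly


class RecordingLoadError(RuntimeError):
    """Structured failure while reading a recording directory."""


class StreamValidationError(RecordingLoadError):
    """A stream violated an invariant; names the offending stream."""

    def __init__(self, stream: str, message: str):
        self.stream = stream
        super().__init__(f"{stream}: {message}")


def _check_monotonic(t: np.ndarray, stream: str) -> None:
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise StreamValidationError(stream, "timestamps not strictly increasing")


def write_recording(recording: Recording, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"t": recording.gaze.t, "x": recording.gaze.x, "y": recording.gaze.y}
    ).to_csv(d / "gaze.csv", index=False, float_format=FLOAT_FMT)
    imu = recording.imu
    pd.DataFrame(
        {"t": imu.t, **{ch: getattr(imu, ch) for ch in ImuStream.CHANNELS}}
    ).to_csv(d / "imu.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(
        {
            "t": recording.gnss.t,
            "east": recording.gnss.east,
            "north": recording.gnss.north,
            "quality": recording.gnss.quality,
        }
    ).to_csv(d / "gnss.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(
        {
            "t_request": [e.t_request for e in recording.events],
            "junction_id": [e.junction_id for e in recording.events],
        }
    ).to_csv(d / "events.csv", index=False, float_format=FLOAT_FMT)
    (d / "route.geojson").write_text(json.dumps(route_to_geojson(recording.route)))
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "participant_id": recording.participant_id,
        "condition": recording.condition,
        "exclusion_intervals": [list(iv) for iv in recording.exclusion_intervals],
        "injected_artifacts": [list(iv) for iv in recording.injected_artifacts],
        "files": {
            "gaze": "gaze.csv",
            "imu": "imu.csv",
            "gnss": "gnss.csv",
            "events": "events.csv",
            "route": "route.geojson",
        },
        "units": UNITS,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return d


def route_to_geojson(route: RouteGeometry) -> dict:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": route.polyline.tolist(),
            },
            "properties": {"role": "route", "decision_radius_m": route.decision_radius_m},
        }
    ]
    for dp in route.decision_points:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": route.polyline[dp.vertex_index].tolist(),
                },
                "properties": {
                    "role": "decision_point",
                    "junction_id": dp.junction_id,
                    "is_turn": dp.is_turn,
                    "vertex_index": dp.vertex_index,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def route_from_geojson(obj: dict) -> RouteGeometry:
    polyline = None
    radius = 10.0
    dps = []
    for feat in obj.get("features", []):
        props = feat.get("properties", {})
        if feat["geometry"]["type"] == "LineString":
            polyline = np.asarray(feat["geometry"]["coordinates"], dtype=float)
            radius = float(props.get("decision_radius_m", radius))
        elif props.get("role") == "decision_point":
            dps.append(
                DecisionPoint(
                    vertex_index=int(props["vertex_index"]),
                    junction_id=str(props["junction_id"]),
                    is_turn=bool(props["is_turn"]),
                )
            )
    if polyline is None:
        raise RecordingLoadError("route.geojson has no LineString feature")
    return RouteGeometry(
        polyline=polyline, decision_points=tuple(dps), decision_radius_m=radius
    )


def read_recording(directory: str | Path) -> Recording:
    d = Path(directory)
    for fname in ("manifest.json", "gaze.csv", "imu.csv", "gnss.csv",
                  "events.csv", "route.geojson"):
        if not (d / fname).exists():
            raise RecordingLoadError(f"missing file {fname} in {d}")
    manifest = json.loads((d / "manifest.json").read_text())
    condition = manifest.get("condition")
    if condition not in CONDITIONS:
        raise RecordingLoadError(f"manifest condition {condition!r} not recognized")

    gaze_df = pd.read_csv(d / "gaze.csv", float_precision="round_trip")
    _check_monotonic(gaze_df["t"].to_numpy(), "gaze")
    gaze = GazeStream(
        t=gaze_df["t"].to_numpy(), x=gaze_df["x"].to_numpy(), y=gaze_df["y"].to_numpy()
    )
    imu_df = pd.read_csv(d / "imu.csv", float_precision="round_trip")
    _check_monotonic(imu_df["t"].to_numpy(), "imu")
    imu = ImuStream(
        t=imu_df["t"].to_numpy(),
        **{ch: imu_df[ch].to_numpy() for ch in ImuStream.CHANNELS},
    )
    gnss_df = pd.read_csv(d / "gnss.csv", float_precision="round_trip")
    _check_monotonic(gnss_df["t"].to_numpy(), "gnss")
    gnss = GnssTrack(
        t=gnss_df["t"].to_numpy(),
        east=gnss_df["east"].to_numpy(),
        north=gnss_df["north"].to_numpy(),
        quality=gnss_df["quality"].to_numpy(dtype=object),
    )
    events_df = pd.read_csv(d / "events.csv", float_precision="round_trip")
    events = [
        InstructionEvent(t_request=float(r.t_request), junction_id=str(r.junction_id))
        for r in events_df.itertuples()
    ]
    route = route_from_geojson(json.loads((d / "route.geojson").read_text()))
    return Recording(
        participant_id=str(manifest["participant_id"]),
        condition=condition,
        gaze=gaze,
        imu=imu,
        gnss=gnss,
        route=route,
        events=events,
        exclusion_intervals=[tuple(iv) for iv in manifest.get("exclusion_intervals", [])],
        injected_artifacts=[tuple(iv) for iv in manifest.get("injected_artifacts", [])],
    )


# ---------------------------------------------------------------------------
# effect configuration


def load_effect_yaml(path: str | Path) -> EffectConfig:
    """Build an EffectConfig from a YAML mapping; per-condition fields may be
    given as {familiar: v, unfamiliar: v} mappings or one shared scalar."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in raw.items():
        if isinstance(value, dict):
            kwargs[key] = PerCondition(
                familiar=float(value["familiar"]),
                unfamiliar=float(value["unfamiliar"]),
            )
        elif key in (
            "yaw_osc_amplitude_deg", "yaw_osc_freq_hz", "acc_noise_sd",
            "fixation_dispersion_scale", "saccade_amplitude_shape",
            "saccade_amplitude_scale",
        ):
            kwargs[key] = PerCondition.both(float(value))
        else:
            kwargs[key] = value
    return EffectConfig(**kwargs)


def effect_to_dict(effect: EffectConfig) -> dict:
    out = {}
    for name, value in vars(effect).items():
        if isinstance(value, PerCondition):
            out[name] = {"familiar": value.familiar, "unfamiliar": value.unfamiliar}
        else:
            out[name] = value
    return out


# ---------------------------------------------------------------------------
# feature tables


def feature_families() -> dict[str, str]:
    """Column → family tag ("gaze" | "imu") for all feature columns."""
    fam = {name: "gaze" for name in GAZE_FEATURE_NAMES}
    fam.update({name: "imu" for name in IMU_FEATURE_NAMES})
    return fam


@dataclass
class FeatureTable:
    """Window-level feature rows plus a column manifest with family tags."""

    df: pd.DataFrame
    families: dict[str, str]

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate feature columns: {dupes}")
        missing = [c for c in METADATA_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"feature table missing metadata columns {missing}")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in METADATA_COLUMNS]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    if table.df.empty:
        raise ValueError("refusing to write an empty feature table")
    path = Path(path)
    table.df.to_csv(path, index=False, float_format=FLOAT_FMT)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "columns": list(table.df.columns),
        "families": table.families,
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=1)
    )


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    families: dict[str, str] = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if list(df.columns) != manifest["columns"]:
            raise ValueError("feature table columns do not match manifest")
        families = manifest["families"]
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing metadata columns {missing}")
    return FeatureTable(df=df, families=families)
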