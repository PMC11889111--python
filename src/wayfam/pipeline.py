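"""End-to-end study driver: cohort generation → preprocessing →
matching-to-action segmentation → feature extraction → classification.

This is the composition surface the calibration experiments (null effect,
planted yaw signal) and the command line run through.
"""

from __future__ import annotations

import pandas as pd

from . import gaze_features, imu_features, model_eval, preprocess, segment
from .io_formats import FeatureTable, feature_families
from .synthetic_data import EffectConfig, Recording, generate_cohort


def extract_features(
    recording: Recording,
    radius_m: float = segment.DEFAULT_RADIUS_M,
    window_s: float = segment.DEFAULT_WINDOW_S,
) -> pd.DataFrame:
    """Window-level gaze + IMU feature rows for one (preprocessed)
    recording, with participant/recording/window metadata."""
    segments = segment.extract_segments(recording, radius_m)
    windows = segment.window_segments(segments, window_s)
    gaze_rows = gaze_features.extract_gaze_windows(
        recording.gaze, recording.imu, windows
    )
    imu_rows = imu_features.extract_imu_windows(recording.imu, windows)
    records = []
    for i, (w, g, m) in enumerate(zip(windows, gaze_rows, imu_rows)):
        records.append(
            {
                "participant_id": recording.participant_id,
                "recording_id": recording.recording_id,
                "window_id": f"{recording.recording_id}_w{i:04d}",
                "condition": recording.condition,
                **g,
                **m,
            }
        )
    return pd.DataFrame.from_records(records)


def build_feature_table(
    recordings: list[Recording],
    preprocess_config: preprocess.PreprocessConfig | None = None,
    radius_m: float = segment.DEFAULT_RADIUS_M,
    window_s: float = segment.DEFAULT_WINDOW_S,
) -> FeatureTable:
    frames = []
    for rec in recordings:
        cleaned = preprocess.preprocess_recording(rec, preprocess_config)
        frames.append(extract_features(cleaned, radius_m, window_s))
    df = pd.concat(frames, ignore_index=True)
    return FeatureTable(df=df, families=feature_families())


def run_study(
    effect: EffectConfig,
    n_participants: int = 12,
    seed: int = 0,
    *,
    feature_sets=("imu",),
    schemes=("l5o4t",),
    n_repeats: int = 5,
    n_holdout_per_condition: int = 3,
    grid: dict | None = None,
    n_cv_folds: int = 5,
    n_search_iter: int | None = 1,
) -> dict:
    """Generate a cohort under ``effect``, run the full pipeline, and return
    the experiment report (plus the feature table row count)."""
    if grid is None:
        grid = model_eval.FIXED_POINT_GRID
    recordings = generate_cohort(n_participants, effect, seed=seed)
    table = build_feature_table(recordings)
    report = model_eval.run_experiment(
        table,
        seed=seed,
        feature_sets=feature_sets,
        schemes=schemes,
        grid=grid,
        n_repeats=n_repeats,
        n_holdout_per_condition=n_holdout_per_condition,
        n_cv_folds=n_cv_folds,
        n_search_iter=n_search_iter,
    )
    report["n_windows"] = int(len(table.df))
    report["n_recordings"] = len(recordings)
    return report
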