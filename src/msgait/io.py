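"""Readers and writers for the artifact's plain-text formats.

Time series are CSV with columns ``time_s, acc_v_g, acc_ml_g, acc_ap_g``
(one file per sensor); annotations are JSON; all derived tables are CSV with
fixed column orders so reruns diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AccelRecording, DataError, GroundTruth, SchemaError

TIMESERIES_COLUMNS = ["time_s", "acc_v_g", "acc_ml_g", "acc_ap_g"]

BOUT_TABLE_COLUMNS = ["subject_id", "bout_id", "start_s", "end_s", "duration_s", "n_windows"]
STRIDE_TABLE_COLUMNS = [
    "subject_id", "bout_id", "stride_idx", "fc_s", "fo_s",
    "stride_s", "stance_s", "swing_s", "duty_factor", "valid_flag",
]
PARAMETER_TABLE_COLUMNS = [
    "subject_id", "bout_id", "context", "duration_class", "duration_s", "n_strides",
    "stride_time_mean_s", "stance_time_mean_s", "swing_time_mean_s",
    "stride_time_cv", "duty_factor_mean", "duty_factor_cv",
    "rms_ap_g", "freqd_ml_hz", "entropy_ratio", "ly_ap_per_s", "ly_ml_per_s",
]
COMPARISON_TABLE_COLUMNS = ["comparison", "feature", "median_1", "median_2", "p_value", "significant"]


def read_recording(path, subject_id: str | None = None, location: str = "chest") -> AccelRecording:
    """Read one sensor CSV into an :class:`AccelRecording`.

    The sampling rate is inferred from the median timestamp increment;
    timestamps must be strictly increasing with jitter below half a sample
    period.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path.name}: non-monotone time column")
    period = float(np.median(dt))
    if np.max(np.abs(dt - period)) > 0.5 * period:
        raise DataError(f"{path.name}: timestamp jitter exceeds half a sample period")
    data = df[TIMESERIES_COLUMNS[1:]].to_numpy(dtype=float).T
    if subject_id is None:
        subject_id = path.stem.rsplit("_", 1)[0]
    return AccelRecording(subject_id=subject_id, location=location, fs=1.0 / period, data=data)


def read_annotations(path) -> GroundTruth:
    ann = json.loads(Path(path).read_text())
    gt = GroundTruth(
        bout_intervals=[(b["start_s"], b["end_s"]) for b in ann["bouts"]],
        gait_events=[[tuple(ev) for ev in b["events"]] for b in ann["bouts"]],
        window_labels=np.asarray(ann["windows"], dtype=int),
    )
    gt.validate()
    return gt


def read_manifest(input_dir) -> dict:
    path = Path(input_dir) / "manifest.json"
    if not path.exists():
        raise SchemaError(f"no manifest.json in {input_dir}")
    return json.loads(path.read_text())


def load_subject(input_dir, subject_id: str):
    """Load (chest, thigh, ground_truth) for one subject from a dataset dir."""
    input_dir = Path(input_dir)
    manifest = read_manifest(input_dir)
    files = manifest["subjects"][subject_id]
    chest = read_recording(input_dir / files["chest"], subject_id, "chest")
    thigh = read_recording(input_dir / files["thigh"], subject_id, "thigh_right")
    gt = read_annotations(input_dir / files["annotations"])
    return chest, thigh, gt


def load_subject_lab(input_dir, subject_id: str):
    """Load the subject's lab hallway-walk recordings, or None if absent."""
    input_dir = Path(input_dir)
    files = read_manifest(input_dir)["subjects"][subject_id]
    if "lab_chest" not in files:
        return None
    chest = read_recording(input_dir / files["lab_chest"], subject_id, "chest")
    thigh = read_recording(input_dir / files["lab_thigh"], subject_id, "thigh_right")
    return chest, thigh


def resample_recording(rec: AccelRecording, fs_target: float) -> AccelRecording:
    """Polyphase resampling to the target rate (identity when rates match)."""
    from fractions import Fraction

    from scipy.signal import resample_poly

    if abs(rec.fs - fs_target) < 1e-9:
        return rec
    frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return AccelRecording(rec.subject_id, rec.location, fs_target, data)


def read_cohort_table(input_dir) -> pd.DataFrame:
    return pd.read_csv(Path(input_dir) / "cohort.csv")


def write_table(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    """Write a derived table with a fixed column order (missing cols = NaN)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        for c in columns:
            if c not in df.columns:
                df[c] = np.nan
        df = df[columns]
    df.to_csv(path, index=False)
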