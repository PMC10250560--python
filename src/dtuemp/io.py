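"""Readers and writers for every pipeline artifact.

All formats are header-keyed UTF-8 CSV with '.' decimal separator and
full-precision floats (Python repr fidelity, so write -> read round trips
are lossless). Column order is free; missing or extra columns are errors
listing the offending names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import AngleSequence, MovementMetrics
from .pose import JOINTS, TrialTrack

TRACK_COLUMNS = ["frame", "joint", "x", "y", "confidence", "flag"]
TRUTH_COLUMNS = ["frame", "theta_deg"]
ANGLE_COLUMNS = ["frame", "theta_deg", "variant"]
METRICS_COLUMNS = ["subject_id", *MovementMetrics.FIELDS]
COHORT_REQUIRED = ["subject_id", "age", "sex", "bmi", "mmse", "tug"]


def _check_columns(df: pd.DataFrame, required: list[str], path, allow_extra=False):
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required]
    if missing or (extra and not allow_extra):
        parts = []
        if missing:
            parts.append(f"missing columns {missing}")
        if extra and not allow_extra:
            parts.append(f"unexpected columns {extra}")
        raise ValueError(f"{path}: {'; '.join(parts)} (expected {required})")


def write_track(track: TrialTrack, path) -> None:
    rows = []
    for joint in JOINTS:
        conf = (
            track.confidence[joint]
            if track.confidence is not None
            else np.ones(track.n_frames)
        )
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(track.n_frames),
                    "joint": joint,
                    "x": track.coords[joint][:, 0],
                    "y": track.coords[joint][:, 1],
                    "confidence": conf,
                    "flag": track.flags[joint].astype(int),
                }
            )
        )
    out = pd.concat(rows).sort_values(["frame", "joint"], kind="stable")
    out.to_csv(path, index=False, float_format="%.17g")


def read_track(path, fps: float) -> TrialTrack:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TRACK_COLUMNS, path)
    if df.empty:
        raise ValueError(f"{path}: empty track (header only)")
    unknown = set(df["joint"].unique()) - set(JOINTS)
    if unknown:
        raise ValueError(f"{path}: unknown joints {sorted(unknown)}")
    by_frame = df.groupby("frame")["joint"].apply(set)
    incomplete = [f for f, js in by_frame.items() if js != set(JOINTS)]
    if incomplete:
        missing_joint = sorted(set(JOINTS) - by_frame[incomplete[0]])[0]
        raise ValueError(f"{path}: frame {incomplete[0]}: missing joint {missing_joint}")
    frames = np.sort(df["frame"].unique())
    if not np.array_equal(frames, np.arange(len(frames))):
        first_gap = int(np.arange(len(frames))[frames != np.arange(len(frames))][0])
        raise ValueError(
            f"{path}: frame indices are not contiguous from 0 "
            f"(first gap at frame {first_gap})"
        )
    coords, conf, flags = {}, {}, {}
    for joint in JOINTS:
        sub = df[df["joint"] == joint].sort_values("frame")
        if len(sub) != len(frames):
            raise ValueError(f"{path}: duplicate rows for joint {joint!r}")
        coords[joint] = sub[["x", "y"]].to_numpy(dtype=float)
        conf[joint] = sub["confidence"].to_numpy(dtype=float)
        flags[joint] = sub["flag"].to_numpy().astype(bool)
    return TrialTrack(fps=fps, coords=coords, confidence=conf, flags=flags)


def write_truth(theta_deg: np.ndarray, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(theta_deg)), "theta_deg": np.asarray(theta_deg, float)}
    ).to_csv(path, index=False, float_format="%.17g")


def read_truth(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TRUTH_COLUMNS, path)
    return df.sort_values("frame")["theta_deg"].to_numpy(dtype=float)


def write_angles(a: AngleSequence, path) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(a)),
            "theta_deg": a.values,
            "variant": a.variant,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_angles(path, fps: float) -> AngleSequence:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ANGLE_COLUMNS, path)
    df = df.sort_values("frame")
    variants = df["variant"].unique()
    if len(variants) != 1:
        raise ValueError(f"{path}: expected a single variant, found {list(variants)}")
    return AngleSequence(df["theta_deg"].to_numpy(dtype=float), fps, str(variants[0]))


def write_metrics(metrics: dict[str, MovementMetrics], path) -> None:
    """One row per subject id."""
    rows = [{"subject_id": sid, **m.as_dict()} for sid, m in metrics.items()]
    pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_metrics(path) -> dict[str, MovementMetrics]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, METRICS_COLUMNS, path)
    return {
        row["subject_id"]: MovementMetrics(
            **{f: float(row[f]) for f in MovementMetrics.FIELDS}
        )
        for _, row in df.iterrows()
    }


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, COHORT_REQUIRED, path, allow_extra=True)
    features = [c for c in df.columns if c not in COHORT_REQUIRED]
    if not features:
        raise ValueError(f"{path}: cohort has no feature columns")
    modeled = df[features + ["mmse", "tug"]]
    if modeled.isna().any().any():
        bad = modeled.columns[modeled.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in modeled columns {bad}")
    return df


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
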