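"""Synthetic elbow flexion-extension trials and cohorts.

The study protocol is a 20-second repetitive elbow flexion-extension bout
recorded at 30 FPS, performed as fast as possible under a concurrent counting
task. No recordings are deposited, so this module generates the whole chain of
inputs with exactly known ground truth:

* ``generate_trial``        — a triangular-wave wrist-elbow angle sequence with
  per-cycle periods drawn from a truncated normal, so phase boundaries and
  durations are known to the frame.
* ``render_keypoints``      — noisy elbow/wrist pixel tracks with optional
  isolated single-frame detector outliers (never two in a row for one joint,
  matching the correction algorithm's core assumption).
* ``render_frames``         — tiny textured grayscale frames with Gaussian
  blobs at the joints, for optical-flow tests.
* ``generate_cohort``       — subjects x (metrics, covariates, MMSE, TUG)
  tables in which one sparse feature subset drives both outcomes, the regime
  multi-task learning is meant to exploit.

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .pose import JOINTS, TrialTrack

logger = logging.getLogger(__name__)

_MIN_PERIOD_S = 0.2  # truncation floor for drawn cycle periods
_STREAM_TRIAL, _STREAM_RENDER, _STREAM_FRAMES, _STREAM_COHORT = range(4)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class TrialSpec:
    """Parameters of one synthetic flexion-extension trial.

    Defaults follow the study protocol (20 s at 30 FPS); kinematic defaults
    are a full-range elbow sweep of 0-120 degrees with 2 s cycles, roughly
    what "as quickly as possible" yields for older adults.
    """

    duration_s: float = 20.0
    fps: float = 30.0
    elbow_anchor: tuple[float, float] = (120.0, 120.0)
    forearm_len: float = 100.0
    cycle_period_mean_s: float = 2.0
    cycle_period_sd_s: float = 0.2
    angle_min_deg: float = 0.0
    angle_max_deg: float = 120.0
    jitter_sd_px: float = 1.0
    outlier_rate: float = 0.0
    outlier_magnitude_px: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.angle_max_deg <= self.angle_min_deg:
            raise ValueError("angle_max_deg must exceed angle_min_deg")
        if not 0.0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier_rate must lie in [0, 0.5)")
        if self.forearm_len <= 0:
            raise ValueError("forearm_len must be positive")
        if self.jitter_sd_px < 0 or self.outlier_magnitude_px < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass(frozen=True)
class GroundTruthTrial:
    """A trial with exactly known angle sequence and phase boundaries.

    ``phase_truth`` entries are ``(kind, start_frame, end_frame)`` with the
    end boundary exclusive (it is the frame at which the next phase starts and
    may equal ``len(theta_true)``), so durations are exact frame counts.
    """

    theta_true: np.ndarray
    phase_truth: list[tuple[str, int, int]]
    spec: TrialSpec


def generate_trial(spec: TrialSpec) -> GroundTruthTrial:
    """Generate a triangular-wave angle trial with variable cycle periods.

    Each cycle is a flexion ramp (angle_min -> angle_max) followed by an
    extension ramp back; its period is drawn from
    Normal(cycle_period_mean_s, cycle_period_sd_s) truncated at 0.2 s and
    each half-cycle is quantised to a whole number of frames (>= 1).
    """
    rng = _rng(spec.seed, _STREAM_TRIAL)
    n_frames = spec.n_frames

    vertex_frames = [0]
    vertex_values = [spec.angle_min_deg]
    phases: list[tuple[str, int, int]] = []
    kind = "flexion"
    while vertex_frames[-1] < n_frames:
        period = _draw_period(rng, spec)
        half = max(1, int(round(period / 2.0 * spec.fps)))
        for _ in range(2):
            start = vertex_frames[-1]
            end = start + half
            vertex_frames.append(end)
            vertex_values.append(
                spec.angle_max_deg if kind == "flexion" else spec.angle_min_deg
            )
            if end <= n_frames:
                phases.append((kind, start, end))
            kind = "extension" if kind == "flexion" else "flexion"

    frames = np.arange(n_frames)
    theta = np.interp(frames, vertex_frames, vertex_values)
    return GroundTruthTrial(theta_true=theta, phase_truth=phases, spec=spec)


def _draw_period(rng: np.random.Generator, spec: TrialSpec) -> float:
    if spec.cycle_period_sd_s == 0:
        if spec.cycle_period_mean_s < _MIN_PERIOD_S:
            raise ValueError(
                f"cycle_period_mean_s={spec.cycle_period_mean_s} below the "
                f"{_MIN_PERIOD_S} s truncation floor"
            )
        return spec.cycle_period_mean_s
    for _ in range(100):
        period = rng.normal(spec.cycle_period_mean_s, spec.cycle_period_sd_s)
        if period >= _MIN_PERIOD_S:
            return period
    raise ValueError(
        "could not draw a cycle period above the 0.2 s floor in 100 attempts; "
        "check cycle_period_mean_s / cycle_period_sd_s"
    )


def truth_coords(trial: GroundTruthTrial) -> dict[str, np.ndarray]:
    """Noise-free elbow and wrist pixel coordinates implied by theta_true.

    Image y points down, so the wrist offset uses -sin(theta): increasing
    angle moves the wrist up on screen.
    """
    spec = trial.spec
    theta = np.deg2rad(trial.theta_true)
    elbow = np.tile(np.asarray(spec.elbow_anchor, dtype=float), (len(theta), 1))
    wrist = elbow + spec.forearm_len * np.column_stack([np.cos(theta), -np.sin(theta)])
    return {"elbow": elbow, "wrist": wrist}


def truth_track(trial: GroundTruthTrial) -> TrialTrack:
    """The zero-noise TrialTrack (useful as a sensor-reference stand-in)."""
    return TrialTrack(fps=trial.spec.fps, coords=truth_coords(trial), source="synthetic")


def exact_flow_from_truth(trial: GroundTruthTrial) -> dict[str, np.ndarray]:
    """Exact per-joint frame-to-frame displacements, (n_frames-1, 2) each.

    Serves as an error-free optical-flow source for testing the correction
    stage in isolation from the flow estimator.
    """
    coords = truth_coords(trial)
    return {joint: np.diff(arr, axis=0) for joint, arr in coords.items()}


def render_keypoints(
    trial: GroundTruthTrial,
    outlier_joints: tuple[str, ...] = ("wrist",),
) -> TrialTrack:
    """Observe the trial through a noisy keypoint detector.

    Adds isotropic Gaussian jitter to both joints and, per joint in
    ``outlier_joints``, displaces the observation by ``outlier_magnitude_px``
    in a uniformly random direction on a Binomial(n, outlier_rate) number of
    frames chosen so that no two outlier frames are adjacent (isolated
    single-frame detector errors). Outlier frames are flagged.
    """
    spec = trial.spec
    rng = _rng(spec.seed, _STREAM_RENDER)
    coords = truth_coords(trial)
    n = len(trial.theta_true)

    observed = {}
    flags = {joint: np.zeros(n, dtype=bool) for joint in JOINTS}
    for joint in JOINTS:
        observed[joint] = coords[joint] + rng.normal(0.0, spec.jitter_sd_px, size=(n, 2))
    for joint in outlier_joints:
        if joint not in JOINTS:
            raise ValueError(f"unknown outlier joint {joint!r}")
        idx = _draw_isolated_frames(rng, n, spec.outlier_rate)
        if idx.size:
            direction = rng.uniform(0.0, 2.0 * np.pi, size=idx.size)
            offset = spec.outlier_magnitude_px * np.column_stack(
                [np.cos(direction), np.sin(direction)]
            )
            observed[joint][idx] += offset
            flags[joint][idx] = True
    return TrialTrack(fps=spec.fps, coords=observed, flags=flags, source="synthetic")


def _draw_isolated_frames(
    rng: np.random.Generator, n: int, rate: float
) -> np.ndarray:
    """Binomial(n, rate) frames, rejected into a non-adjacent placement."""
    k = rng.binomial(n, rate) if rate > 0 else 0
    if k == 0:
        return np.empty(0, dtype=int)
    order = rng.permutation(n)
    taken = np.zeros(n, dtype=bool)
    chosen: list[int] = []
    for f in order:
        if taken[f] or (f > 0 and taken[f - 1]) or (f < n - 1 and taken[f + 1]):
            continue
        taken[f] = True
        chosen.append(int(f))
        if len(chosen) == k:
            break
    return np.sort(np.asarray(chosen, dtype=int))


def render_frames(
    track: TrialTrack,
    size: int = 64,
    blob_sigma_px: float = 2.0,
    background_sigma_px: float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Render a (n_frames, size, size) grayscale stack from a track.

    Each frame is a fixed smoothed random background texture (amplitude 0.5)
    plus unit-amplitude Gaussian blobs at the elbow and wrist coordinates, so
    the intensity argmax near each blob marks the keypoint. Deterministic
    given the seed.
    """
    if size < 48:
        raise ValueError("frame size must be at least 48 px")
    rng = _rng(seed, _STREAM_FRAMES)
    background = ndimage.gaussian_filter(rng.random((size, size)), background_sigma_px)
    background *= 0.5 / max(background.max(), 1e-12)

    n = track.n_frames
    for joint in JOINTS:
        xy = track.coords[joint]
        bad = np.where(
            (xy[:, 0] < 0) | (xy[:, 0] > size - 1) | (xy[:, 1] < 0) | (xy[:, 1] > size - 1)
        )[0]
        if bad.size:
            raise ValueError(
                f"frame {int(bad[0])}: {joint} keypoint {tuple(xy[bad[0]])} outside "
                f"{size}x{size} frame bounds"
            )

    yy, xx = np.mgrid[0:size, 0:size]
    stack = np.empty((n, size, size), dtype=float)
    for t in range(n):
        frame = background.copy()
        for joint in JOINTS:
            x, y = track.coords[joint][t]
            frame += np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * blob_sigma_px**2))
        stack[t] = frame
    return stack


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort for the MTL / STL comparison.

    Six standard-normal features stand in for the z-scored movement metrics;
    a single sparse weight support of size ``support_size`` is shared by both
    outcomes (with task-specific magnitudes), emulating the regime in which
    slower, more variable movement simultaneously predicts lower cognition
    (MMSE) and slower mobility (TUG).
    """

    n_subjects: int = 20
    n_features: int = 6
    support_size: int = 3
    weight_scale: float = 1.5
    noise_sd: tuple[float, float] = (2.0, 1.5)  # (MMSE points, TUG seconds)
    outcome_offsets: tuple[float, float] = (24.0, 12.0)  # (MMSE points, TUG seconds)
    age_mean: float = 75.0
    age_sd: float = 6.0
    sex_probability: float = 0.5
    bmi_mean: float = 25.0
    bmi_sd: float = 4.0
    feature_names: tuple[str, ...] = (
        "flex_mean_s",
        "flex_sd_s",
        "ext_mean_s",
        "ext_sd_s",
        "cycle_mean_s",
        "cycle_sd_s",
    )
    seed: int = 0

    def __post_init__(self):
        if self.support_size > self.n_features:
            raise ValueError("support_size cannot exceed n_features")
        if self.n_subjects < 10:
            raise ValueError("cohorts need at least 10 subjects")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be non-negative")
        if len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length must equal n_features")


MMSE_RANGE = (0.0, 30.0)
TUG_FLOOR_S = 3.0


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table: features, covariates, MMSE and TUG outcomes.

    MMSE = offset - X @ w_mmse + noise, clipped to [0, 30];
    TUG  = offset + X @ w_tug  + noise, floored at 3 s. Both weight vectors
    are positive on the same randomly chosen support, so active features pull
    MMSE down and TUG up together.
    """
    rng = _rng(spec.seed, _STREAM_COHORT)
    n, p = spec.n_subjects, spec.n_features
    X = rng.standard_normal((n, p))

    support = np.sort(rng.choice(p, size=spec.support_size, replace=False))
    w_mmse = np.zeros(p)
    w_tug = np.zeros(p)
    w_mmse[support] = spec.weight_scale * rng.uniform(0.5, 1.5, size=spec.support_size)
    w_tug[support] = spec.weight_scale * rng.uniform(0.5, 1.5, size=spec.support_size)

    mmse_raw = spec.outcome_offsets[0] - X @ w_mmse + rng.normal(0, spec.noise_sd[0], n)
    tug_raw = spec.outcome_offsets[1] + X @ w_tug + rng.normal(0, spec.noise_sd[1], n)
    mmse = np.clip(mmse_raw, *MMSE_RANGE)
    tug = np.maximum(tug_raw, TUG_FLOOR_S)
    n_clipped = int(np.sum(mmse != mmse_raw) + np.sum(tug != tug_raw))
    if n_clipped:
        logger.info("cohort seed=%d: clipped %d outcome values to scale range",
                    spec.seed, n_clipped)

    table = pd.DataFrame(X, columns=list(spec.feature_names))
    table.insert(0, "subject_id", [f"S{i:03d}" for i in range(n)])
    table["age"] = rng.normal(spec.age_mean, spec.age_sd, n)
    table["sex"] = rng.binomial(1, spec.sex_probability, n)
    table["bmi"] = rng.normal(spec.bmi_mean, spec.bmi_sd, n)
    table["mmse"] = mmse
    table["tug"] = tug
    table.attrs["support"] = support.tolist()
    table.attrs["w_mmse"] = w_mmse.tolist()
    table.attrs["w_tug"] = w_tug.tolist()
    return table
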