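"""Optical-flow-based coordinate correction of pose-network tracks.

Pose networks occasionally misplace a joint in an isolated frame (motion
blur at the fast-moving wrist is the typical cause). Flow-based prediction
from the previous frame is immune to that failure but drifts if trusted for
long. The correction rule fuses the two under the working assumption that
the network and the flow do not both fail on the same joint in two
consecutive frames:

for each joint independently, at frame t >= 1, predict the joint from the
last *accepted* coordinate at t-1 plus the flow vector at t-1; if the network
observation disagrees with that prediction by more than a threshold and the
previous frame was itself not a substitution, accept the flow prediction,
otherwise accept the network observation. Frame 0 and frames with failed
flow always take the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowVector, lk_flow
from .pose import JOINTS, TrialTrack


@dataclass(frozen=True)
class CorrectionConfig:
    """Disagreement gate for accepting flow predictions over the network.

    ``disagreement_threshold`` is in pixels when ``threshold_is_absolute``,
    otherwise a fraction of the median per-frame forearm length (default
    0.25, which makes the gate scale-invariant across camera distances).
    ``max_consecutive_substitutions`` caps flow-substitution runs; the
    default of 1 encodes the isolated-single-frame error assumption.
    """

    disagreement_threshold: float = 0.25
    threshold_is_absolute: bool = False
    max_consecutive_substitutions: int = 1
    window_px: int = 15

    def __post_init__(self):
        if self.disagreement_threshold <= 0:
            raise ValueError("disagreement_threshold must be positive")
        if self.max_consecutive_substitutions < 1:
            raise ValueError("max_consecutive_substitutions must be >= 1")

    def threshold_px(self, track: TrialTrack) -> float:
        if self.threshold_is_absolute:
            return self.disagreement_threshold
        return self.disagreement_threshold * float(np.median(track.forearm_lengths()))


@dataclass
class CorrectionReport:
    """Audit trail: which frames were substituted and why."""

    substituted_frames: dict[str, list[int]]
    disagreement_px: dict[str, np.ndarray]
    threshold_px: float
    flow_failures: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_substitutions(self) -> int:
        return sum(len(v) for v in self.substituted_frames.values())

    def max_substitution_run(self, joint: str) -> int:
        frames = self.substituted_frames.get(joint, [])
        if not frames:
            return 0
        runs, run = 1, 1
        for a, b in zip(frames, frames[1:]):
            run = run + 1 if b == a + 1 else 1
            runs = max(runs, run)
        return runs


def _flow_arrays(
    track: TrialTrack,
    flows: dict[str, np.ndarray] | dict[str, list[FlowVector]] | None,
    frames: np.ndarray | None,
    cfg: CorrectionConfig,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Normalise flow input to per-joint (n-1, 2) arrays + ok masks."""
    n = track.n_frames
    if flows is None:
        if frames is None:
            raise ValueError("provide either flow vectors or raw frames")
        frames = np.asarray(frames)
        if len(frames) != n:
            raise ValueError(
                f"frame stack length {len(frames)} != track length {n}"
            )
        flows = {
            joint: [
                lk_flow(frames[t], frames[t + 1], tuple(track.coords[joint][t]),
                        cfg.window_px, joint, t)
                for t in range(n - 1)
            ]
            for joint in JOINTS
        }
    vectors: dict[str, np.ndarray] = {}
    ok: dict[str, np.ndarray] = {}
    for joint in JOINTS:
        per_joint = flows[joint]
        if isinstance(per_joint, np.ndarray):
            arr = np.asarray(per_joint, dtype=float)
            mask = np.all(np.isfinite(arr), axis=1)
        else:
            arr = np.array(
                [[fv.u, fv.v] if fv.status == "ok" else [np.nan, np.nan] for fv in per_joint]
            )
            mask = np.array([fv.status == "ok" for fv in per_joint])
        if len(arr) != n - 1:
            raise ValueError(
                f"joint {joint!r}: expected {n - 1} flow vectors, got {len(arr)}"
            )
        vectors[joint] = arr
        ok[joint] = mask
    return vectors, ok


def correct_track(
    network: TrialTrack,
    flows: dict[str, np.ndarray] | dict[str, list[FlowVector]] | None = None,
    cfg: CorrectionConfig = CorrectionConfig(),
    frames: np.ndarray | None = None,
) -> tuple[TrialTrack, CorrectionReport]:
    """Fuse a network track with flow predictions into a corrected track.

    ``flows`` maps each joint to its n-1 frame-to-frame flow vectors (array of
    (u, v) rows, NaN rows meaning failed flow, or a list of FlowVector);
    alternatively pass raw grayscale ``frames`` and flow is computed here.
    Returns the corrected track plus a report of every substitution and the
    per-frame disagreement magnitudes.
    """
    vectors, ok = _flow_arrays(network, flows, frames, cfg)
    threshold = cfg.threshold_px(network)
    n = network.n_frames

    corrected = network.copy()
    corrected.source = "corrected"
    report = CorrectionReport(
        substituted_frames={j: [] for j in JOINTS},
        disagreement_px={j: np.zeros(n) for j in JOINTS},
        threshold_px=threshold,
        flow_failures={j: [int(t) for t in np.where(~ok[j])[0]] for j in JOINTS},
    )

    for joint in JOINTS:
        accepted = corrected.coords[joint]  # mutated in place frame by frame
        flags = np.zeros(n, dtype=bool)
        run = 0
        for t in range(1, n):
            if not ok[joint][t - 1]:
                run = 0
                continue
            predicted = accepted[t - 1] + vectors[joint][t - 1]
            disagreement = float(np.linalg.norm(network.coords[joint][t] - predicted))
            report.disagreement_px[joint][t] = disagreement
            if disagreement > threshold and run < cfg.max_consecutive_substitutions:
                accepted[t] = predicted
                flags[t] = True
                report.substituted_frames[joint].append(t)
                run += 1
            else:
                run = 0
        corrected.flags[joint] = flags
    return corrected, report


def angle_error_reduction(
    truth: np.ndarray, uncorrected: np.ndarray, corrected: np.ndarray
) -> tuple[float, float, float]:
    """RMSE (degrees) of each sequence against truth, plus the reduction.

    Returns ``(rmse_uncorrected, rmse_corrected, 1 - rmse_corr/rmse_unc)``.
    """
    truth = np.asarray(truth, dtype=float)
    uncorrected = np.asarray(uncorrected, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    if truth.size == 0:
        raise ValueError("empty angle sequences")
    if not truth.shape == uncorrected.shape == corrected.shape:
        raise ValueError("angle sequences must have equal length")
    rmse_unc = float(np.sqrt(np.mean((uncorrected - truth) ** 2)))
    rmse_cor = float(np.sqrt(np.mean((corrected - truth) ** 2)))
    if rmse_unc == 0.0:
        return rmse_unc, rmse_cor, 0.0 if rmse_cor == 0 else -np.inf
    return rmse_unc, rmse_cor, 1.0 - rmse_cor / rmse_unc
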