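"""Angle sequences, flexion/extension phase segmentation, and the six
movement metrics.

The forearm orientation per frame is the rotation angle of the wrist-elbow
line. Because the metrics are phase *durations*, they are invariant to the
angle reference; the convention here is atan2(-(y_w - y_e), x_w - x_e) in
degrees (image y points down, so this is the usual counterclockwise angle
with the horizontal-right direction at 0 and straight up at +90).

Phases follow the local-peak rule: the span from a local maximum to the next
local minimum is an extension phase, minimum to maximum a flexion phase. The
six summary metrics are the mean and sample SD of flexion, extension, and
full-cycle (flexion + following extension) durations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .pose import TrialTrack

logger = logging.getLogger(__name__)

DEFAULT_PROMINENCE_DEG = 10.0
DEFAULT_MIN_SEPARATION_FRAMES = 5

VARIANTS = ("network", "flow", "corrected", "sensor_reference")


@dataclass(frozen=True)
class AngleSequence:
    """Wrist-elbow rotation angle per frame, in degrees."""

    values: np.ndarray
    fps: float
    variant: str = "corrected"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("angle sequence must be finite")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Phase:
    """One flexion or extension span; end_frame is the exclusive boundary."""

    kind: str  # flexion | extension
    start_frame: int
    end_frame: int
    fps: float

    def __post_init__(self):
        if self.kind not in ("flexion", "extension"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.fps


@dataclass
class PhaseSet:
    """Alternating flexion/extension phases from one angle sequence."""

    phases: list[Phase]
    fps: float

    def __post_init__(self):
        for a, b in zip(self.phases, self.phases[1:]):
            if b.kind == a.kind:
                raise ValueError("phase kinds must strictly alternate")
            if b.start_frame < a.end_frame:
                raise ValueError("phases must not overlap")

    def durations(self, kind: str) -> np.ndarray:
        return np.array([p.duration_s for p in self.phases if p.kind == kind])

    def cycle_durations(self) -> np.ndarray:
        """Flexion-extension cycles: each flexion + the extension that follows."""
        out = []
        for a, b in zip(self.phases, self.phases[1:]):
            if a.kind == "flexion" and b.kind == "extension":
                out.append(a.duration_s + b.duration_s)
        return np.array(out)


@dataclass(frozen=True)
class MovementMetrics:
    """The six duration metrics (seconds); NaN marks an undefined value."""

    flex_mean_s: float
    flex_sd_s: float
    ext_mean_s: float
    ext_sd_s: float
    cycle_mean_s: float
    cycle_sd_s: float

    FIELDS = ("flex_mean_s", "flex_sd_s", "ext_mean_s", "ext_sd_s",
              "cycle_mean_s", "cycle_sd_s")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


def compute_angle_sequence(track: TrialTrack, variant: str = "corrected") -> AngleSequence:
    """Rotation angle of the wrist-elbow line per frame, phase-unwrapped.

    Raises if wrist and elbow coincide in any frame (the angle is undefined
    there). Unwrapping guarantees no consecutive step exceeds 180 degrees.
    """
    dx = track.coords["wrist"][:, 0] - track.coords["elbow"][:, 0]
    dy = track.coords["wrist"][:, 1] - track.coords["elbow"][:, 1]
    coincident = np.where((dx == 0) & (dy == 0))[0]
    if coincident.size:
        raise ValueError(
            f"frame {int(coincident[0])}: wrist and elbow coincide; angle undefined"
        )
    theta = np.degrees(np.arctan2(-dy, dx))
    theta = np.unwrap(theta, period=360.0)
    return AngleSequence(values=theta, fps=track.fps, variant=variant)


def segment_phases(
    a: AngleSequence,
    prominence_deg: float = DEFAULT_PROMINENCE_DEG,
    min_separation_frames: int = DEFAULT_MIN_SEPARATION_FRAMES,
) -> PhaseSet:
    """Segment an angle sequence into alternating flexion/extension phases.

    Local maxima and minima are located with the given prominence and minimum
    separation; strict alternation is enforced by keeping only the lowest
    minimum between consecutive maxima (and the highest maximum between
    consecutive minima). Spans before the first and after the last retained
    extremum are discarded. Fewer than one max-min pair yields an empty set.
    """
    values = a.values
    if len(values) < 3:
        raise ValueError("need at least 3 samples to segment")
    maxima, _ = find_peaks(values, prominence=prominence_deg,
                           distance=max(1, min_separation_frames))
    minima, _ = find_peaks(-values, prominence=prominence_deg,
                           distance=max(1, min_separation_frames))
    extrema = _alternate(values, maxima, minima)
    if len(extrema) < 2:
        logger.info("fewer than one max-min pair found; empty phase set")
        return PhaseSet(phases=[], fps=a.fps)
    phases = []
    for (f0, kind0), (f1, _) in zip(extrema, extrema[1:]):
        phase_kind = "extension" if kind0 == "max" else "flexion"
        phases.append(Phase(kind=phase_kind, start_frame=f0, end_frame=f1, fps=a.fps))
    return PhaseSet(phases=phases, fps=a.fps)


def _alternate(values, maxima, minima):
    """Merge extrema into a strictly alternating max/min sequence."""
    tagged = sorted(
        [(int(f), "max") for f in maxima] + [(int(f), "min") for f in minima]
    )
    out: list[tuple[int, str]] = []
    for frame, kind in tagged:
        if out and out[-1][1] == kind:
            prev_frame = out[-1][0]
            better = (
                values[frame] > values[prev_frame]
                if kind == "max"
                else values[frame] < values[prev_frame]
            )
            if better:
                out[-1] = (frame, kind)
        else:
            out.append((frame, kind))
    return out


def compute_metrics(p: PhaseSet) -> MovementMetrics:
    """Mean and sample SD (n-1) of flexion, extension, and cycle durations.

    A kind with fewer than two phases reports its mean from the available
    data and an undefined (NaN) SD; an empty set reports all NaN with a
    warning in the log.
    """
    if not p.phases:
        logger.warning("empty phase set: all metrics undefined")
        return MovementMetrics(*(math.nan,) * 6)
    out = {}
    for name, durations in (
        ("flex", p.durations("flexion")),
        ("ext", p.durations("extension")),
        ("cycle", p.cycle_durations()),
    ):
        out[f"{name}_mean_s"] = float(np.mean(durations)) if durations.size else math.nan
        out[f"{name}_sd_s"] = float(np.std(durations, ddof=1)) if durations.size >= 2 else math.nan
    return MovementMetrics(**out)


def metrics_from_track(
    track: TrialTrack,
    variant: str = "corrected",
    prominence_deg: float = DEFAULT_PROMINENCE_DEG,
    min_separation_frames: int = DEFAULT_MIN_SEPARATION_FRAMES,
    smooth: bool = False,
) -> MovementMetrics:
    """Convenience: track -> angles -> phases -> metrics."""
    angles = compute_angle_sequence(track, variant=variant)
    if smooth:
        angles = AngleSequence(moving_average(angles.values, 5), angles.fps, angles.variant)
    phases = segment_phases(angles, prominence_deg, min_separation_frames)
    return compute_metrics(phases)


def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average with edge shrinkage (optional pre-smoothing)."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out
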