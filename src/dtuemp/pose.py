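"""Keypoint observations and the pose-backend contract.

The pose estimator itself is pluggable: anything that emits the keypoint CSV
contract (``frame,joint,x,y,confidence,flag``) is an acceptable backend. This
module supplies the two pieces the pipeline owns: decoding score heatmaps to
coordinates by the local-maximum method, and the validated in-memory track
container that every downstream stage consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

JOINTS = ("elbow", "wrist")

SOURCES = ("network", "flow", "corrected", "synthetic", "sensor")


@dataclass(frozen=True)
class Heatmap:
    """A per-joint score grid for one frame (rows x cols, unitless)."""

    grid: np.ndarray
    joint: str = "wrist"
    frame_index: int = 0

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("heatmap grid must be a non-empty 2-D array")
        if not np.all(np.isfinite(grid)):
            raise ValueError("heatmap grid must be finite")
        object.__setattr__(self, "grid", grid)


@dataclass(frozen=True)
class KeypointObservation:
    """One joint coordinate in image pixels (x = column, y = row)."""

    frame_index: int
    joint: str
    x: float
    y: float
    confidence: float | None = None
    source: str = "network"

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("keypoint coordinates must be finite")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


def decode_heatmap(h: Heatmap) -> KeypointObservation:
    """Decode a heatmap to a keypoint by the local-maximum method.

    Returns the (x=col, y=row) of the global maximum; ties are broken by the
    smallest row-major index. Confidence is the maximum score after min-max
    normalising the grid (so it lands in [0, 1]). A flat grid is degenerate:
    the origin is returned with confidence 0 and a warning.
    """
    grid = h.grid
    lo, hi = grid.min(), grid.max()
    if hi == lo:
        warnings.warn(
            f"degenerate (constant) heatmap for joint {h.joint!r} at frame "
            f"{h.frame_index}; returning origin with zero confidence",
            stacklevel=2,
        )
        return KeypointObservation(h.frame_index, h.joint, 0.0, 0.0, 0.0, "network")
    flat_idx = int(np.argmax(grid))  # argmax is row-major -> stated tie-break
    row, col = np.unravel_index(flat_idx, grid.shape)
    conf = float(np.clip((grid[row, col] - lo) / (hi - lo), 0.0, 1.0))
    return KeypointObservation(h.frame_index, h.joint, float(col), float(row), conf, "network")


@dataclass
class TrialTrack:
    """Per-frame elbow and wrist coordinates at a fixed frame rate.

    ``coords[joint]`` is an (n_frames, 2) float array of (x, y);
    ``flags[joint]`` marks frames whose observation was injected as a detector
    outlier (synthetic tracks) or substituted by flow (corrected tracks);
    ``confidence[joint]`` is optional per-frame confidence in [0, 1].
    """

    fps: float
    coords: dict[str, np.ndarray]
    confidence: dict[str, np.ndarray] | None = None
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    source: str = "network"

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = None
        for joint in JOINTS:
            if joint not in self.coords:
                raise ValueError(f"track is missing joint {joint!r}")
            arr = np.asarray(self.coords[joint], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"coords[{joint!r}] must have shape (n, 2)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"coords[{joint!r}] must be finite")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("all joints must cover the same frames")
            self.coords[joint] = arr
        for joint in JOINTS:
            if joint not in self.flags:
                self.flags[joint] = np.zeros(n, dtype=bool)
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n_frames(self) -> int:
        return self.coords[JOINTS[0]].shape[0]

    def copy(self) -> "TrialTrack":
        return TrialTrack(
            fps=self.fps,
            coords={j: a.copy() for j, a in self.coords.items()},
            confidence=None
            if self.confidence is None
            else {j: a.copy() for j, a in self.confidence.items()},
            flags={j: a.copy() for j, a in self.flags.items()},
            source=self.source,
        )

    def forearm_lengths(self) -> np.ndarray:
        """Per-frame wrist-to-elbow distance in pixels."""
        return np.linalg.norm(self.coords["wrist"] - self.coords["elbow"], axis=1)


def ingest_track(path, fps: float) -> TrialTrack:
    """Read and validate a keypoint CSV into a :class:`TrialTrack`.

    The CSV contract is ``frame,joint,x,y,confidence,flag`` with one header
    line. Both joints must be present in every frame and frame indices must be
    contiguous from zero.
    """
    from . import io as _io

    return _io.read_track(path, fps=fps)
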