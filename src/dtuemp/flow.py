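"""Sparse Lucas-Kanade optical flow at joint keypoints.

Estimates the frame-to-frame displacement of a single point by solving the
2x2 least-squares system built from spatial image gradients over a small
window, then predicts the next-frame keypoint from the current observation
plus its flow vector. Degenerate windows (the aperture problem) are reported,
not guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .pose import KeypointObservation

DEFAULT_WINDOW_PX = 15
_MIN_EIGENVALUE = 1e-6
_MAX_CONDITION = 1e6


@dataclass(frozen=True)
class FlowVector:
    """Estimated displacement of one joint between consecutive frames."""

    u: float
    v: float
    joint: str
    frame_index: int
    status: str = "ok"  # ok | aperture_failure | out_of_bounds

    def __post_init__(self):
        if self.status == "ok" and not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("ok flow vectors must be finite")


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Luminance average for RGB input; grayscale passes through."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        return frame.mean(axis=2)
    return frame


def lk_flow(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    point: tuple[float, float],
    window_px: int = DEFAULT_WINDOW_PX,
    joint: str = "wrist",
    frame_index: int = 0,
    max_iterations: int = 10,
    tol_px: float = 1e-3,
) -> FlowVector:
    """Lucas-Kanade flow of one point between two frames.

    Solves ``G d = -b`` over a ``window_px`` x ``window_px`` patch, where G is
    the structure tensor of central-difference spatial gradients of the first
    frame and b collects gradient-weighted temporal differences. The solve is
    repeated with the second frame warped by the current estimate (bicubic
    interpolation) until the update falls below ``tol_px``, which keeps the
    linearisation valid for motions of a pixel or two at a single level.

    Status is ``aperture_failure`` when the structure tensor has least
    eigenvalue < 1e-6 or condition number > 1e6, and ``out_of_bounds`` when
    the window (plus its one-pixel gradient margin) does not fit around the
    point.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 3")
    frame_t = to_grayscale(frame_t)
    frame_t1 = to_grayscale(frame_t1)
    if frame_t.shape != frame_t1.shape:
        raise ValueError(
            f"frame size mismatch: {frame_t.shape} vs {frame_t1.shape}"
        )

    half = window_px // 2
    x0, y0 = float(point[0]), float(point[1])
    cx, cy = int(round(x0)), int(round(y0))
    h, w = frame_t.shape
    # one extra pixel margin for central differences
    if not (half + 1 <= cx < w - half - 1 and half + 1 <= cy < h - half - 1):
        return FlowVector(np.nan, np.nan, joint, frame_index, "out_of_bounds")

    ys = slice(cy - half, cy + half + 1)
    xs = slice(cx - half, cx + half + 1)
    ix = 0.5 * (frame_t[ys, cx - half + 1 : cx + half + 2]
                - frame_t[ys, cx - half - 1 : cx + half])
    iy = 0.5 * (frame_t[cy - half + 1 : cy + half + 2, xs]
                - frame_t[cy - half - 1 : cy + half, xs])

    g = np.array(
        [
            [np.sum(ix * ix), np.sum(ix * iy)],
            [np.sum(ix * iy), np.sum(iy * iy)],
        ]
    )
    eigvals = np.linalg.eigvalsh(g)
    if eigvals[0] < _MIN_EIGENVALUE or eigvals[1] / max(eigvals[0], 1e-300) > _MAX_CONDITION:
        return FlowVector(np.nan, np.nan, joint, frame_index, "aperture_failure")

    win_y, win_x = np.mgrid[cy - half : cy + half + 1, cx - half : cx + half + 1]
    patch_t = frame_t[ys, xs]
    d = np.zeros(2)
    for _ in range(max_iterations):
        warped = ndimage.map_coordinates(
            frame_t1, [win_y + d[1], win_x + d[0]], order=3, mode="nearest"
        )
        it = warped - patch_t  # forward temporal difference at the current warp
        b = np.array([np.sum(ix * it), np.sum(iy * it)])
        try:
            step = np.linalg.solve(g, -b)
        except np.linalg.LinAlgError:
            return FlowVector(np.nan, np.nan, joint, frame_index, "aperture_failure")
        d += step
        if np.hypot(*step) < tol_px:
            break
    if not np.all(np.isfinite(d)):
        return FlowVector(np.nan, np.nan, joint, frame_index, "aperture_failure")
    return FlowVector(float(d[0]), float(d[1]), joint, frame_index, "ok")


def predict_next(obs: KeypointObservation, flow: FlowVector) -> KeypointObservation:
    """Advance a keypoint one frame along its flow vector."""
    if flow.status != "ok":
        raise ValueError(
            f"cannot predict from flow with status {flow.status!r} "
            f"(joint {flow.joint}, frame {flow.frame_index})"
        )
    return KeypointObservation(
        frame_index=obs.frame_index + 1,
        joint=obs.joint,
        x=obs.x + flow.u,
        y=obs.y + flow.v,
        confidence=obs.confidence,
        source="flow",
    )


def track_flows(
    frames: np.ndarray,
    coords: np.ndarray,
    window_px: int = DEFAULT_WINDOW_PX,
    joint: str = "wrist",
) -> list[FlowVector]:
    """Flow of one joint across a frame stack, seeded at ``coords[t]``.

    Returns n_frames - 1 vectors; vector t maps frame t to frame t+1.
    """
    frames = np.asarray(frames)
    coords = np.asarray(coords, dtype=float)
    if len(coords) != len(frames):
        raise ValueError("need one coordinate per frame")
    return [
        lk_flow(frames[t], frames[t + 1], tuple(coords[t]), window_px, joint, t)
        for t in range(len(frames) - 1)
    ]
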