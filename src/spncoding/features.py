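"""The six posture features derived from body-part coordinates.

For every video frame six kinematic/postural features are computed from the
tracked body parts:

* **body speed** (cm/s) — projection of the body-center velocity vector onto
  the body axis (unit vector from body center to neck);
* **head speed** (cm/s) — norm of the difference between the body-center
  velocity vector and the head-mounted camera velocity vector;
* **movement angle** (rad, signed) — angle between the body-center velocity
  vectors of the previous and subsequent frames; positive for right turns in
  image coordinates (see note below);
* **body length** (cm) — distance neck→body center plus body center→tail start;
* **neck elongation** (cm) — distance neck→body center;
* **head elevation** (cm) — distance from the neck to the orthogonal
  projection of the camera position onto the axis through the two ears.  In a
  top-down view this is a proxy for head raising, not a true height.

Velocities are central differences at the video frame rate (one-sided at the
ends).  Frames whose required coordinates are masked yield masked features;
derivative-based features are additionally masked on frames adjacent to a
masked coordinate.

Sign convention for the movement angle: with image coordinates (x right,
y down), a positive angle means the velocity rotates clockwise on screen,
i.e. the animal turns to its right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pose import PoseTrack

#: Canonical order of the six features.
FEATURE_NAMES: tuple[str, ...] = (
    "body_speed",
    "head_speed",
    "movement_angle",
    "body_length",
    "neck_elongation",
    "head_elevation",
)

N_FEATURES = len(FEATURE_NAMES)


@dataclass
class FeatureSeries:
    """Per-frame six-feature posture description.

    ``values`` has shape ``(n_frames, 6)`` in the order of FEATURE_NAMES;
    masked entries are NaN and are excluded from all downstream statistics.
    """

    values: np.ndarray
    frame_rate: float
    names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError(f"values must be (n_frames, {len(self.names)})")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    @property
    def valid(self) -> np.ndarray:
        """Frames with all six features defined."""
        return np.isfinite(self.values).all(axis=1)

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="frame")

    @classmethod
    def from_csv(cls, path, frame_rate: float) -> "FeatureSeries":
        df = pd.read_csv(path, index_col=0)
        return cls(df[list(FEATURE_NAMES)].to_numpy(dtype=float), frame_rate)


def _central_velocity(x: np.ndarray, y: np.ndarray, fps: float) -> np.ndarray:
    """Central-difference velocity (n, 2); one-sided at the first/last frame."""
    n = x.size
    v = np.full((n, 2), np.nan)
    if n < 2:
        return v
    v[1:-1, 0] = (x[2:] - x[:-2]) * fps / 2.0
    v[1:-1, 1] = (y[2:] - y[:-2]) * fps / 2.0
    v[0] = [(x[1] - x[0]) * fps, (y[1] - y[0]) * fps]
    v[-1] = [(x[-1] - x[-2]) * fps, (y[-1] - y[-2]) * fps]
    return v


def _signed_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed angle from u to v per row; NaN where either is (near) zero."""
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = (u * v).sum(axis=1)
    ang = np.arctan2(cross, dot)
    norm = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    ang = np.where(norm > 0, ang, np.nan)
    return ang


def compute_features(pose: PoseTrack) -> FeatureSeries:
    """Compute the six posture features from a (possibly masked) pose track."""
    if pose.n_frames < 3:
        raise ValueError("need at least 3 frames to compute velocity features")
    fps = pose.frame_rate
    bx, by, _ = pose.part("body_center")
    nx, ny, _ = pose.part("neck")
    tx, ty, _ = pose.part("tail_start")
    cx, cy, _ = pose.part("camera")
    lx, ly, _ = pose.part("left_ear")
    rx, ry, _ = pose.part("right_ear")

    if not np.isfinite(bx).any():
        raise ValueError("all frames masked: no finite body-center coordinates")

    v_body = _central_velocity(bx, by, fps)
    v_cam = _central_velocity(cx, cy, fps)

    # body axis: unit vector from body center to neck
    axis = np.stack([nx - bx, ny - by], axis=1)
    axis_norm = np.linalg.norm(axis, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis_u = axis / axis_norm[:, None]
    body_speed = (v_body * axis_u).sum(axis=1)

    head_speed = np.linalg.norm(v_body - v_cam, axis=1)

    # movement angle: angle between body-center velocity in the previous and
    # subsequent frames
    n = pose.n_frames
    movement_angle = np.full(n, np.nan)
    movement_angle[1:-1] = _signed_angle(v_body[:-2], v_body[2:])

    neck_elongation = np.hypot(nx - bx, ny - by)
    body_length = neck_elongation + np.hypot(bx - tx, by - ty)

    # head elevation: project the camera onto the inter-ear axis, then measure
    # the distance from the neck to that projected point
    mx, my = (lx + rx) / 2.0, (ly + ry) / 2.0
    ex, ey = rx - lx, ry - ly
    enorm = np.hypot(ex, ey)
    with np.errstate(invalid="ignore", divide="ignore"):
        eux, euy = ex / enorm, ey / enorm
    t = (cx - mx) * eux + (cy - my) * euy
    px, py = mx + t * eux, my + t * euy
    head_elevation = np.hypot(nx - px, ny - py)

    values = np.stack(
        [body_speed, head_speed, movement_angle, body_length,
         neck_elongation, head_elevation],
        axis=1,
    )
    return FeatureSeries(values, frame_rate=fps)


def smooth_features(features: FeatureSeries, window_frames: int = 20) -> FeatureSeries:
    """Mask-aware moving average over ``window_frames`` frames.

    Masked (NaN) frames are excluded from each window's average; frames that
    are themselves masked stay masked.  The window is centered (left-biased by
    one frame for even windows) and shrinks at the series ends, so a constant
    signal is unchanged everywhere.
    """
    w = int(window_frames)
    if w < 1:
        raise ValueError("window_frames must be >= 1")
    if w > features.n_frames:
        raise ValueError("window_frames exceeds series length")
    if w == 1:
        return FeatureSeries(features.values.copy(), features.frame_rate, features.names)

    vals = features.values
    finite = np.isfinite(vals)
    filled = np.where(finite, vals, 0.0)
    kernel = np.ones(w)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        num = np.convolve(filled[:, j], kernel, mode="full")
        den = np.convolve(finite[:, j].astype(float), kernel, mode="full")
        # centered alignment: output frame t uses input [t-(w-1)//2, t+w//2]
        lo = (w - 1) // 2
        sl = slice(w - 1 - lo, w - 1 - lo + vals.shape[0])
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, j] = num[sl] / den[sl]
    out[~finite] = np.nan
    return FeatureSeries(out, features.frame_rate, features.names)
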