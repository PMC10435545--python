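"""Pose-track container and DeepLabCut-style CSV input/output.

A pose track holds per-frame x/y coordinates and a tracking-confidence
(likelihood) value for eight named body parts of a mouse filmed from above.
Coordinates with likelihood below a confidence threshold are masked (NaN)
rather than interpolated, and the mask propagates into the derived posture
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight tracked body parts, in canonical order.
BODY_PARTS: tuple[str, ...] = (
    "nose",
    "neck",
    "left_ear",
    "right_ear",
    "camera",
    "body_center",
    "tail_start",
    "tail_end",
)


@dataclass
class PoseTrack:
    """Tracked coordinates of the eight body parts over a session.

    Attributes
    ----------
    x, y
        Arrays of shape ``(n_parts, n_frames)`` in cm (masked entries NaN).
    likelihood
        Tracking confidence in [0, 1], same shape.
    frame_rate
        Behavioral video frame rate (frames/s), 40 by default.
    """

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    frame_rate: float = 40.0
    parts: tuple[str, ...] = field(default=BODY_PARTS)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (self.x.shape == self.y.shape == self.likelihood.shape):
            raise ValueError("x, y and likelihood must have identical shapes")
        if self.x.shape[0] != len(self.parts):
            raise ValueError(f"expected {len(self.parts)} body-part rows")
        lk = self.likelihood[np.isfinite(self.likelihood)]
        if lk.size and (lk.min() < 0 or lk.max() > 1):
            raise ValueError("likelihood must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(self.x.shape[1])

    def part_index(self, name: str) -> int:
        return self.parts.index(name)

    def part(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = self.part_index(name)
        return self.x[i], self.y[i], self.likelihood[i]

    def copy(self) -> "PoseTrack":
        return PoseTrack(
            self.x.copy(), self.y.copy(), self.likelihood.copy(),
            self.frame_rate, self.parts,
        )


def filter_low_confidence(pose: PoseTrack, threshold: float = 0.9) -> PoseTrack:
    """Mask coordinates whose tracking likelihood is below ``threshold``.

    Coordinates detected with likelihood strictly less than the threshold
    (default 0.9) are removed from further analysis: their x/y entries are set
    to NaN and downstream feature computation propagates the mask.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = pose.copy()
    bad = out.likelihood < threshold
    out.x[bad] = np.nan
    out.y[bad] = np.nan
    return out


def read_dlc_csv(path, frame_rate: float = 40.0, scale: float = 1.0) -> PoseTrack:
    """Read a DeepLabCut-style CSV (scorer/bodyparts/coords header) into a PoseTrack.

    Parameters
    ----------
    scale
        Multiplier converting the file's coordinate units (typically px) to cm.
    """
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    n = len(df)
    x = np.full((len(BODY_PARTS), n), np.nan)
    y = np.full((len(BODY_PARTS), n), np.nan)
    lk = np.zeros((len(BODY_PARTS), n))
    for i, part in enumerate(BODY_PARTS):
        x[i] = df[(scorer, part, "x")].to_numpy(dtype=float) * scale
        y[i] = df[(scorer, part, "y")].to_numpy(dtype=float) * scale
        lk[i] = df[(scorer, part, "likelihood")].to_numpy(dtype=float)
    return PoseTrack(x, y, lk, frame_rate=frame_rate)


def write_dlc_csv(pose: PoseTrack, path, scorer: str = "spncoding") -> None:
    """Write a PoseTrack as a DeepLabCut-style three-header-row CSV."""
    cols = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part in pose.parts for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.empty((pose.n_frames, len(cols)))
    for i in range(len(pose.parts)):
        data[:, 3 * i] = pose.x[i]
        data[:, 3 * i + 1] = pose.y[i]
        data[:, 3 * i + 2] = pose.likelihood[i]
    pd.DataFrame(data, columns=cols).to_csv(path, index_label="frame")
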