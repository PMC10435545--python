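"""Behavior catalog and per-frame behavior label containers.

The repertoire of spontaneous open-field mouse behaviors used throughout the
package is a fixed, ordered catalog of 12 classes.  Per-frame label sequences
carry the acquisition frame rate and expose the run-length *episode* structure
(maximal runs of consecutive frames sharing one label) that several analyses
operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for frames that carry no behavior label.
UNLABELED: int = -1

#: Canonical ordered names of the 12-behavior repertoire.  The integer id of a
#: behavior is its index in this tuple; the order is fixed and part of the API.
BEHAVIOR_NAMES: tuple[str, ...] = (
    "locomotion_fast",        # 0
    "locomotion_straight",    # 1
    "locomotion_turn_right",  # 2
    "locomotion_turn_left",   # 3
    "still_turn_right",       # 4
    "still_turn_left",        # 5
    "head_up",                # 6
    "rearing",                # 7
    "grooming",               # 8
    "locomotion_sniffing",    # 9
    "still_sniffing",         # 10
    "immobility",             # 11
)

#: Behaviors involving translation or turning of the body, as opposed to the
#: static postures (head up, rearing, grooming, still sniffing, immobility).
AMBULATORY_IDS: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 9)


@dataclass(frozen=True)
class BehaviorCatalog:
    """Ordered catalog of behavior classes.

    The default catalog is the 12-class open-field repertoire; a custom
    catalog (e.g. for toy tests) may be constructed from any unique name list.
    """

    names: tuple[str, ...] = BEHAVIOR_NAMES

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("behavior names must be unique")

    @property
    def n_behaviors(self) -> int:
        return len(self.names)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(len(self.names))

    def id_of(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.names)


DEFAULT_CATALOG = BehaviorCatalog()


def episodes_from_labels(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a label vector into (start, end, behavior_id) episodes.

    Intervals are half-open ``[start, end)``.  Unlabeled runs are reported with
    behavior_id = UNLABELED so callers can treat gaps explicitly.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


@dataclass
class BehaviorLabels:
    """Per-frame behavior labels at a stated frame rate.

    Attributes
    ----------
    labels
        Integer array of behavior ids (``UNLABELED`` = -1 for gaps).
    frame_rate
        Frames per second of the label sequence.
    catalog
        The behavior catalog the ids index into.
    """

    labels: np.ndarray
    frame_rate: float
    catalog: BehaviorCatalog = field(default_factory=BehaviorCatalog)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        valid = self.labels[self.labels != UNLABELED]
        if valid.size and (valid.min() < 0 or valid.max() >= len(self.catalog)):
            raise ValueError("labels outside catalog range")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def episodes(self) -> list[tuple[int, int, int]]:
        """Labeled episodes only (unlabeled runs are skipped)."""
        return [ep for ep in episodes_from_labels(self.labels) if ep[2] != UNLABELED]

    def episodes_of(self, behavior_id: int) -> list[tuple[int, int]]:
        return [(s, e) for s, e, b in self.episodes if b == behavior_id]

    def occupancy(self) -> np.ndarray:
        """Fraction of labeled time spent in each behavior (sums to 1)."""
        mask = self.labels != UNLABELED
        counts = np.bincount(self.labels[mask], minlength=len(self.catalog))
        total = counts.sum()
        if total == 0:
            raise ValueError("no labeled frames")
        return counts / total

    def resample(self, target_rate: float) -> "BehaviorLabels":
        """Resample labels to another frame rate by nearest-frame decimation.

        Behavioral video runs at 40 frames/s while imaging runs at 20 frames/s;
        alignment takes every second behavior frame (or, in general, the
        nearest behavior frame for each target frame).
        """
        if target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if target_rate == self.frame_rate:
            return BehaviorLabels(self.labels.copy(), self.frame_rate, self.catalog)
        n_target = int(round(self.n_frames * target_rate / self.frame_rate))
        src = np.minimum(
            (np.arange(n_target) * self.frame_rate / target_rate).astype(np.int64),
            self.n_frames - 1,
        )
        return BehaviorLabels(self.labels[src], target_rate, self.catalog)
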