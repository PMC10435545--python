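"""Readers and writers for the package's tabular session artifacts.

Pose tracks travel as DeepLabCut-style CSVs (see :mod:`.pose`), event rasters
as neurons x frames CSV or HDF5 (see :mod:`.raster`), registries as pair CSVs
(see :mod:`.registry`).  This module adds the label/episode CSVs and a ground
truth sidecar JSON for synthetic sessions.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .catalog import BehaviorCatalog, BehaviorLabels, DEFAULT_CATALOG
from .synthetic import GroundTruth


def write_labels_csv(labels: BehaviorLabels, path) -> None:
    pd.DataFrame({"behavior_id": labels.labels}).to_csv(path, index_label="frame")


def read_labels_csv(path, frame_rate: float,
                    catalog: BehaviorCatalog = DEFAULT_CATALOG) -> BehaviorLabels:
    df = pd.read_csv(path, index_col=0)
    return BehaviorLabels(df["behavior_id"].to_numpy(dtype=np.int64),
                          frame_rate, catalog)


def write_episodes_csv(labels: BehaviorLabels, path) -> None:
    eps = labels.episodes
    pd.DataFrame(eps, columns=["start_frame", "end_frame", "behavior_id"]).assign(
        behavior=[labels.catalog.names[b] for _, _, b in eps]
    ).to_csv(path, index=False)


def write_ground_truth_json(gt: GroundTruth, path) -> None:
    """Serialize the ground truth of a synthetic session (labels excluded;
    write those with write_labels_csv)."""
    payload: dict = {}
    if gt.tuning is not None:
        payload["tuning"] = {
            "class_of": [str(c) for c in gt.tuning.class_of],
            "assigned": [a.tolist() for a in gt.tuning.assigned],
            "baseline_rate": gt.tuning.baseline_rate,
            "active_gain": gt.tuning.active_gain,
            "silent_rate": gt.tuning.silent_rate,
            "episode_gain_sd": gt.tuning.episode_gain_sd,
        }
    if gt.feature_params is not None:
        payload["feature_params"] = {
            "means": gt.feature_params.means.tolist(),
            "sds": gt.feature_params.sds.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
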