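"""Neuronal activation similarity and behavioral similarity.

The population *activation map* of a behavior is the vector of per-neuron
mean deconvolved activity during that behavior over a stated time window.
Two activation maps X1, X2 are compared by the negative Euclidean distance
between the unit-normalized vectors,

    similarity(X1, X2) = -|| X1/||X1|| - X2/||X2|| ||,

which lies in [-2, 0], is scale-invariant, and equals 0 iff the maps are
positively proportional.  Split-half and finer time partitions of a session
quantify the across-time stability of a behavior's population activation;
a spatial (neuron-index) shuffle provides the corresponding chance level.

The *behavioral distance* between two behaviors is the sum over the six
posture features of the 1-D Wasserstein-1 distances between their empirical
feature distributions; behavioral similarity is its negative.  The coupling
between neural and behavioral similarity over all behavior pairs is
summarized by a Spearman rank correlation.

Any activation map computed from less than 5 s of sampled behavior time is
flagged invalid and excluded from comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import spearmanr, wasserstein_distance

from .catalog import BehaviorLabels, UNLABELED
from .features import FeatureSeries
from .raster import EventRaster

#: Minimum sampled duration (s) for a valid activation map.
MIN_SAMPLING_S = 5.0


@dataclass
class ActivationMap:
    """Per-neuron mean activity (events/s) during one behavior in one window."""

    values: np.ndarray
    behavior_id: int
    window: tuple[int, int]
    duration_s: float
    valid: bool

    @property
    def n_neurons(self) -> int:
        return int(self.values.size)


def align_labels(labels: BehaviorLabels, raster: EventRaster) -> np.ndarray:
    """Behavior label per imaging frame (nearest-frame decimation)."""
    aligned = labels.resample(raster.rate).labels
    if aligned.size < raster.n_frames:
        raise ValueError("labels do not cover the raster")
    return aligned[: raster.n_frames]


def activation_map(
    raster: EventRaster,
    labels: BehaviorLabels,
    behavior_id: int,
    frame_window: tuple[int, int] | None = None,
    frame_mask: np.ndarray | None = None,
) -> ActivationMap:
    """Mean per-neuron activity during ``behavior_id`` within a frame window.

    ``frame_window`` is a half-open imaging-frame interval (whole session by
    default); ``frame_mask`` optionally restricts to an arbitrary frame
    subset instead (used for the odd/even-frame and episode partitions).
    The map is invalid if the behavior occupies less than 5 s of the window.
    """
    lab = align_labels(labels, raster)
    if frame_mask is None:
        lo, hi = frame_window if frame_window is not None else (0, raster.n_frames)
        if not (0 <= lo <= hi <= raster.n_frames):
            raise ValueError("frame_window outside the session")
        frame_mask = np.zeros(raster.n_frames, dtype=bool)
        frame_mask[lo:hi] = True
        window = (int(lo), int(hi))
    else:
        frame_mask = np.asarray(frame_mask, dtype=bool)
        window = (0, raster.n_frames)
    sel = frame_mask & (lab == behavior_id)
    duration = sel.sum() / raster.rate
    if sel.any():
        values = raster.events[:, sel].mean(axis=1) * raster.rate
    else:
        values = np.zeros(raster.n_neurons)
    return ActivationMap(values, int(behavior_id), window, float(duration),
                         valid=duration >= MIN_SAMPLING_S)


def activation_similarity(x1, x2) -> float:
    """Negative distance between unit-normalized activation vectors (in [-2, 0])."""
    v1 = x1.values if isinstance(x1, ActivationMap) else np.asarray(x1, dtype=float)
    v2 = x2.values if isinstance(x2, ActivationMap) else np.asarray(x2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("similarity undefined for a zero activation vector")
    return float(-np.linalg.norm(v1 / n1 - v2 / n2))


def dot_product_similarity(x1, x2) -> float:
    """Cosine of the two activation vectors (alternate similarity metric)."""
    v1 = x1.values if isinstance(x1, ActivationMap) else np.asarray(x1, dtype=float)
    v2 = x2.values if isinstance(x2, ActivationMap) else np.asarray(x2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("similarity undefined for a zero activation vector")
    return float(v1 @ v2 / (n1 * n2))


def spatial_shuffle_similarity(x1, x2, n_shuffles: int = 10,
                               seed: int | np.random.Generator = 0) -> float:
    """Chance similarity: mean over random permutations of X2's neuron indices."""
    v1 = x1.values if isinstance(x1, ActivationMap) else np.asarray(x1, dtype=float)
    v2 = x2.values if isinstance(x2, ActivationMap) else np.asarray(x2, dtype=float)
    rng = np.random.default_rng(seed)
    vals = [activation_similarity(v1, rng.permutation(v2)) for _ in range(n_shuffles)]
    return float(np.mean(vals))


PARTITION_SCHEMES = ("halves", "five_min_partitions", "odd_even_frames",
                     "alternating_episodes")


def similarity_partitions(
    raster: EventRaster,
    labels: BehaviorLabels,
    scheme: str = "halves",
    slice_s: float = 300.0,
) -> dict[int, list[float]]:
    """Per-behavior activation similarity under a session time partition.

    Schemes
    -------
    halves
        First vs second half of the session (one value per behavior).
    five_min_partitions
        All balanced 2-colorings of the session's six 5-min slices
        (10 distinct splits up to complement symmetry).
    odd_even_frames
        Odd vs even imaging frames.
    alternating_episodes
        For each behavior, every other episode vs the remaining episodes.

    Behaviors whose occupancy in either part is below 5 s are excluded
    (absent from the returned dict or with that partition's value skipped).
    """
    if scheme not in PARTITION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    lab = align_labels(labels, raster)
    n = raster.n_frames
    behaviors = np.unique(lab[lab != UNLABELED])

    masks: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme == "halves":
        m = np.zeros(n, dtype=bool)
        m[: n // 2] = True
        masks.append((m, ~m))
    elif scheme == "odd_even_frames":
        m = np.zeros(n, dtype=bool)
        m[1::2] = True
        masks.append((m, ~m))
    elif scheme == "five_min_partitions":
        k = int(round(slice_s * raster.rate))
        n_slices = n // k
        if n_slices < 2 or n_slices % 2:
            raise ValueError("session length must be an even number of slices")
        edges = [slice(i * k, (i + 1) * k) for i in range(n_slices)]
        # balanced colorings containing slice 0 in part 1 (kills the
        # complement symmetry): C(n_slices-1, n_slices/2 - 1) splits
        for combo in combinations(range(1, n_slices), n_slices // 2 - 1):
            m = np.zeros(n, dtype=bool)
            for s in (0,) + combo:
                m[edges[s]] = True
            m2 = np.zeros(n, dtype=bool)
            for s in range(n_slices):
                if s != 0 and s not in combo:
                    m2[edges[s]] = True
            masks.append((m, m2))

    out: dict[int, list[float]] = {}
    for b in behaviors:
        if scheme == "alternating_episodes":
            eps = labels.resample(raster.rate).episodes
            eps_b = [(s, e) for s, e, bb in eps if bb == b]
            m1 = np.zeros(n, dtype=bool)
            m2 = np.zeros(n, dtype=bool)
            for k_i, (s, e) in enumerate(eps_b):
                (m1 if k_i % 2 == 0 else m2)[s: min(e, n)] = True
            pair_masks = [(m1, m2)]
        else:
            pair_masks = masks
        vals = []
        for m1, m2 in pair_masks:
            a1 = activation_map(raster, labels, int(b), frame_mask=m1)
            a2 = activation_map(raster, labels, int(b), frame_mask=m2)
            if not (a1.valid and a2.valid):
                continue
            if np.linalg.norm(a1.values) == 0 or np.linalg.norm(a2.values) == 0:
                continue
            vals.append(activation_similarity(a1, a2))
        if vals:
            out[int(b)] = vals
    return out


def inverse_cv(
    raster: EventRaster,
    labels: BehaviorLabels,
    behavior_id: int,
    mode: str = "per_neuron",
) -> float:
    """Inverse coefficient of variation of activation across episodes.

    ``per_neuron`` (default): for each neuron, mean/SD of its episode-wise
    event rates during the behavior, averaged over neurons with defined CV.
    ``ensemble``: inverse CV of the episode-wise ensemble-mean activation.
    Returns NaN when undefined (fewer than 2 episodes handled as an error,
    zero SD as missing).
    """
    if mode not in ("per_neuron", "ensemble"):
        raise ValueError("mode must be 'per_neuron' or 'ensemble'")
    eps = [(s, e) for s, e, b in
           labels.resample(raster.rate).episodes if b == behavior_id]
    eps = [(s, min(e, raster.n_frames)) for s, e in eps if s < raster.n_frames]
    if len(eps) < 2:
        raise ValueError("need at least 2 episodes of the behavior")
    rates = np.stack([
        raster.events[:, s:e].mean(axis=1) * raster.rate for s, e in eps
    ], axis=1)  # (n_neurons, n_episodes)
    if mode == "ensemble":
        ens = rates.mean(axis=0)
        sd = ens.std(ddof=1)
        return float(ens.mean() / sd) if sd > 0 else np.nan
    mean = rates.mean(axis=1)
    sd = rates.std(axis=1, ddof=1)
    ok = sd > 0
    if not ok.any():
        return np.nan
    return float(np.mean(mean[ok] / sd[ok]))


# --------------------------------------------------------------------------
# Behavioral distance and the neural-behavioral coupling
# --------------------------------------------------------------------------
def behavioral_distance(
    features: FeatureSeries,
    labels: BehaviorLabels,
    behavior_i: int,
    behavior_j: int,
    min_frames: int = 10,
) -> float:
    """Sum over the six features of 1-D Wasserstein distances between the
    empirical per-behavior feature distributions."""
    if labels.n_frames != features.n_frames:
        raise ValueError("labels and features must have equal length")
    li = labels.labels == behavior_i
    lj = labels.labels == behavior_j
    if li.sum() < min_frames or lj.sum() < min_frames:
        raise ValueError("behavior absent or with too few frames")
    total = 0.0
    for f in range(features.values.shape[1]):
        a = features.values[li, f]
        b = features.values[lj, f]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            raise ValueError("a feature channel is fully masked for a behavior")
        total += wasserstein_distance(a, b)
    return float(total)


def behavioral_distance_matrix(features: FeatureSeries, labels: BehaviorLabels,
                               min_frames: int = 10) -> np.ndarray:
    """Symmetric matrix of pairwise behavioral distances (NaN where a
    behavior lacks frames)."""
    k = len(labels.catalog)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 0.0)
    present = [b for b in range(k)
               if (labels.labels == b).sum() >= min_frames]
    for i, j in combinations(present, 2):
        d = behavioral_distance(features, labels, i, j, min_frames)
        mat[i, j] = mat[j, i] = d
    return mat


def neural_similarity_matrix(raster: EventRaster, labels: BehaviorLabels,
                             window_s: float | None = None) -> np.ndarray:
    """Pairwise activation similarity between behaviors (whole session or a
    leading window of ``window_s`` seconds)."""
    k = len(labels.catalog)
    hi = raster.n_frames if window_s is None else min(
        raster.n_frames, int(round(window_s * raster.rate)))
    maps = [activation_map(raster, labels, b, frame_window=(0, hi))
            for b in range(k)]
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 0.0)
    for i, j in combinations(range(k), 2):
        mi, mj = maps[i], maps[j]
        if not (mi.valid and mj.valid):
            continue
        if np.linalg.norm(mi.values) == 0 or np.linalg.norm(mj.values) == 0:
            continue
        mat[i, j] = mat[j, i] = activation_similarity(mi, mj)
    return mat


def similarity_coupling(
    raster: EventRaster,
    labels: BehaviorLabels,
    features: FeatureSeries,
    window_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Spearman coupling between neural and behavioral pairwise similarity.

    Returns (neural similarity matrix, behavioral similarity matrix,
    Spearman rho, p-value), computed over the behavior pairs valid in both
    matrices (66 pairs for a full 12-behavior catalog).
    """
    ns = neural_similarity_matrix(raster, labels, window_s=window_s)
    bd = behavioral_distance_matrix(features, labels)
    bs = -bd  # behavioral similarity is the opposite of the distance
    k = ns.shape[0]
    iu = np.triu_indices(k, 1)
    x, y = ns[iu], bs[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 valid behavior pairs")
    rho, p = spearmanr(x[ok], y[ok])
    return ns, bs, float(rho), float(p)
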