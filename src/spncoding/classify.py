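"""Detection of behavior-active, behavior-silent and behavior-inactive cells.

*Behavior information* (BI, bits per event) quantifies how strongly a cell's
event rate is modulated across the behavior repertoire:

    BI = sum_i  p_i * (f_i / f) * log2(f_i / f)

where p_i is the fraction of time spent in behavior i, f_i the cell's event
rate during behavior i, and f its overall event rate.  Writing q_i for the
fraction of the cell's events emitted during behavior i, BI equals
sum_i q_i log2(q_i / p_i) - a Kullback-Leibler divergence between the event
distribution and the time-occupancy distribution over behaviors, which is
what the implementation evaluates (terms with f_i = 0 contribute 0).

Significance is assessed against a shuffle null: 1000 random permutations of
the event train (or circular shifts, preserving autocorrelation), a cell
being *behavior-active* when its BI exceeds the shuffle mean by more than 4
shuffle standard deviations.

A cell is *behavior-silent* for a behavior when its activation occurrence -
the fraction of that behavior's episodes containing at least one event - is
below 0.025, and *behavior-inactive* when its mean event rate during the
behavior is below 0.1 events/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .catalog import BehaviorLabels, UNLABELED
from .raster import EventRaster
from .registry import CellRegistry
from .similarity import MIN_SAMPLING_S, align_labels


# --------------------------------------------------------------------------
# Behavior information (BI)
# --------------------------------------------------------------------------
@dataclass
class BehaviorInformation:
    """BI of one cell plus its ingredients and (optional) shuffle statistics."""

    bi: float
    occupancy: np.ndarray        # p_i over behaviors
    rates: np.ndarray            # f_i, events/s
    overall_rate: float          # f, events/s
    defined: bool
    shuffle_mean: float = np.nan
    shuffle_sd: float = np.nan

    @property
    def sigma_level(self) -> float:
        if not self.defined or not np.isfinite(self.shuffle_sd) or self.shuffle_sd == 0:
            return np.nan
        return (self.bi - self.shuffle_mean) / self.shuffle_sd


def _bi_from_sums(event_sums: np.ndarray, frame_counts: np.ndarray) -> np.ndarray:
    """BI from per-behavior event sums (..., B) and frame counts (B,)."""
    p = frame_counts / frame_counts.sum()
    total = event_sums.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = event_sums / total
        terms = q * np.log2(q / p)
    terms = np.where(event_sums > 0, terms, 0.0)
    bi = terms.sum(axis=-1)
    return np.where(total[..., 0] > 0, bi, np.nan)


def _behavior_sums(events: np.ndarray, lab: np.ndarray, n_behaviors: int):
    mask = lab != UNLABELED
    frame_counts = np.bincount(lab[mask], minlength=n_behaviors).astype(float)
    if events.ndim == 1:
        sums = np.bincount(lab[mask], weights=events[mask], minlength=n_behaviors)
    else:
        oh = sparse.csr_matrix(
            (np.ones(mask.sum()), (np.flatnonzero(mask), lab[mask])),
            shape=(lab.size, n_behaviors),
        )
        sums = np.asarray((sparse.csr_matrix(events) @ oh).todense())
    return sums, frame_counts


def behavior_information(
    events: np.ndarray,
    labels: BehaviorLabels | np.ndarray,
    rate: float = 20.0,
) -> BehaviorInformation:
    """BI of a single cell's event train given aligned behavior labels.

    ``labels`` may be a BehaviorLabels at any rate (it is aligned to the
    event train length at ``rate``) or an already-aligned integer array.
    A never-active cell (overall rate 0) has undefined BI.
    """
    events = np.asarray(events, dtype=float)
    if isinstance(labels, BehaviorLabels):
        n_behaviors = len(labels.catalog)
        lab = labels.resample(rate).labels[: events.size]
    else:
        lab = np.asarray(labels, dtype=np.int64)
        n_behaviors = int(lab.max()) + 1
    if lab.size != events.size:
        raise ValueError("labels do not cover the event train")
    sums, frame_counts = _behavior_sums(events, lab, n_behaviors)
    p = frame_counts / frame_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        f_i = np.where(frame_counts > 0, sums / frame_counts * rate, np.nan)
    f = sums.sum() / frame_counts.sum() * rate
    bi = float(_bi_from_sums(sums, frame_counts))
    return BehaviorInformation(bi, p, f_i, float(f), defined=f > 0)


def _shuffled_sums(events_2d, lab, n_behaviors, n_shuffles, rng, method):
    """Per-behavior event sums under the shuffle null, shape (S, n, B).

    Permuting the events against the labels is implemented by permuting the
    label stream (equivalent in distribution and much cheaper for a whole
    population at once).  The circular variant rolls the label stream, which
    preserves the event train's autocorrelation structure.
    """
    n_frames = lab.size
    ev = sparse.csr_matrix(events_2d)
    out = np.empty((n_shuffles, events_2d.shape[0], n_behaviors))
    for s in range(n_shuffles):
        if method == "permutation":
            lab_s = lab[rng.permutation(n_frames)]
        elif method == "circular":
            lab_s = np.roll(lab, int(rng.integers(1, n_frames)))
        else:
            raise ValueError("method must be 'permutation' or 'circular'")
        mask = lab_s != UNLABELED
        oh = sparse.csr_matrix(
            (np.ones(mask.sum()), (np.flatnonzero(mask), lab_s[mask])),
            shape=(n_frames, n_behaviors),
        )
        out[s] = np.asarray((ev @ oh).todense())
    return out


def classify_behavior_active(
    events: np.ndarray,
    labels: BehaviorLabels,
    n_shuffles: int = 1000,
    sigma_threshold: float = 4.0,
    rate: float = 20.0,
    method: str = "permutation",
    seed: int | np.random.Generator = 0,
) -> tuple[bool, BehaviorInformation]:
    """Shuffle test for one cell: active iff BI > shuffle mean + 4 shuffle SD."""
    events = np.asarray(events, dtype=float)[None, :]
    flags, infos = classify_behavior_active_population(
        EventRaster(events, rate=rate), labels, n_shuffles=n_shuffles,
        sigma_threshold=sigma_threshold, method=method, seed=seed)
    return bool(flags[0]), infos[0]


def classify_behavior_active_population(
    raster: EventRaster,
    labels: BehaviorLabels,
    n_shuffles: int = 1000,
    sigma_threshold: float = 4.0,
    method: str = "permutation",
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[BehaviorInformation]]:
    """Vectorized shuffle test over a whole raster.

    The same ``n_shuffles`` label shuffles are applied to every neuron
    (cells' null distributions are then correlated across cells, but each
    cell's own null has the correct marginal distribution).
    Returns (boolean active flags, per-cell BehaviorInformation).
    """
    rng = np.random.default_rng(seed)
    lab = align_labels(labels, raster)
    n_behaviors = len(labels.catalog)
    sums, frame_counts = _behavior_sums(raster.events, lab, n_behaviors)
    bi = _bi_from_sums(sums, frame_counts)                      # (n,)
    shuf = _shuffled_sums(raster.events, lab, n_behaviors, n_shuffles, rng,
                          method)
    bi_shuf = _bi_from_sums(shuf, frame_counts)                 # (S, n)
    mean = np.nanmean(bi_shuf, axis=0)
    sd = np.nanstd(bi_shuf, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = (bi - mean) / sd
    active = np.isfinite(sigma) & (sigma > sigma_threshold)

    p = frame_counts / frame_counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        f_i = np.where(frame_counts > 0, sums / frame_counts * raster.rate, np.nan)
    f = sums.sum(axis=1) / frame_counts.sum() * raster.rate
    infos = [
        BehaviorInformation(float(bi[i]), p, f_i[i], float(f[i]),
                            defined=f[i] > 0, shuffle_mean=float(mean[i]),
                            shuffle_sd=float(sd[i]))
        for i in range(raster.n_neurons)
    ]
    return active, infos


def classify_active_per_behavior(
    raster: EventRaster,
    labels: BehaviorLabels,
    n_shuffles: int = 1000,
    sigma_threshold: float = 4.0,
    method: str = "permutation",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-behavior activation test: (n_neurons, n_behaviors) boolean flags.

    For each behavior independently, a cell is flagged when its in-behavior
    event rate exceeds the shuffle mean by more than ``sigma_threshold``
    shuffle SDs (one-sided).  Behaviors occupying less than 5 s are excluded
    (all-NaN column reported as False with the column masked via NaN sums in
    the companion rate matrix; flags are simply False there).
    """
    rng = np.random.default_rng(seed)
    lab = align_labels(labels, raster)
    n_behaviors = len(labels.catalog)
    sums, frame_counts = _behavior_sums(raster.events, lab, n_behaviors)
    shuf = _shuffled_sums(raster.events, lab, n_behaviors, n_shuffles, rng,
                          method)
    mean = shuf.mean(axis=0)
    sd = shuf.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = (sums - mean) / sd
    flags = np.isfinite(sigma) & (sigma > sigma_threshold)
    excluded = frame_counts / raster.rate < MIN_SAMPLING_S
    flags[:, excluded] = False
    return flags


# --------------------------------------------------------------------------
# Occurrence-based silent / inactive classification
# --------------------------------------------------------------------------
def _episodes_at_rate(labels: BehaviorLabels, rate: float, n_frames: int):
    eps = labels.resample(rate).episodes
    return [(s, min(e, n_frames), b) for s, e, b in eps if s < n_frames]


def activation_occurrence(
    events: np.ndarray,
    labels: BehaviorLabels,
    behavior_id: int,
    rate: float = 20.0,
) -> float | np.ndarray:
    """Fraction of the behavior's episodes containing at least one event.

    ``events`` may be a single cell (frames,) -> float, or a raster
    (n_neurons, frames) -> per-neuron array.
    """
    events = np.asarray(events, dtype=float)
    single = events.ndim == 1
    ev2 = events[None, :] if single else events
    eps = [(s, e) for s, e, b in
           _episodes_at_rate(labels, rate, ev2.shape[1]) if b == behavior_id]
    if not eps:
        raise ValueError(f"behavior {behavior_id} has no episodes")
    hits = np.zeros(ev2.shape[0])
    for s, e in eps:
        hits += ev2[:, s:e].sum(axis=1) > 0
    occ = hits / len(eps)
    return float(occ[0]) if single else occ


def occurrence_table(raster: EventRaster, labels: BehaviorLabels) -> np.ndarray:
    """(n_neurons, n_behaviors) activation occurrence; NaN where a behavior
    has no episodes."""
    n_behaviors = len(labels.catalog)
    table = np.full((raster.n_neurons, n_behaviors), np.nan)
    for b in range(n_behaviors):
        try:
            table[:, b] = activation_occurrence(raster.events, labels, b,
                                                rate=raster.rate)
        except ValueError:
            pass
    return table


def classify_behavior_silent(occurrence: np.ndarray,
                             threshold: float = 0.025) -> np.ndarray:
    """Silent iff activation occurrence is strictly below ``threshold``."""
    occ = np.asarray(occurrence, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isfinite(occ) & (occ < threshold)


def classify_behavior_inactive(
    raster: EventRaster,
    labels: BehaviorLabels,
    rate_threshold: float = 0.1,
) -> np.ndarray:
    """Inactive iff the mean in-behavior event rate is strictly below
    ``rate_threshold`` (events/s); behaviors occupying < 5 s are excluded
    (False)."""
    lab = align_labels(labels, raster)
    n_behaviors = len(labels.catalog)
    sums, frame_counts = _behavior_sums(raster.events, lab, n_behaviors)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = sums / frame_counts * raster.rate
    flags = np.isfinite(rates) & (rates < rate_threshold)
    flags[:, frame_counts / raster.rate < MIN_SAMPLING_S] = False
    return flags


def classify_silent_by_shuffle(
    events: np.ndarray,
    labels: BehaviorLabels,
    behavior_id: int,
    n_shuffles: int = 1000,
    percentile: float = 2.5,
    rate: float = 20.0,
    seed: int | np.random.Generator = 0,
) -> bool:
    """Shuffle-based silent test for one cell.

    The cell's event train is circularly shifted ``n_shuffles`` times; the
    cell is silent for the behavior iff its observed activation occurrence
    falls below the given low percentile of the shuffled occurrence
    distribution.  When that percentile is 0 (e.g. a cell with no events at
    all), an observed occurrence of exactly 0 is still flagged.
    """
    rng = np.random.default_rng(seed)
    events = np.asarray(events, dtype=float)
    obs = activation_occurrence(events, labels, behavior_id, rate=rate)
    n = events.size
    shifted = np.stack([np.roll(events, int(rng.integers(1, n)))
                        for _ in range(n_shuffles)])
    shuf = activation_occurrence(shifted, labels, behavior_id, rate=rate)
    q = np.percentile(shuf, percentile)
    if q > 0:
        return bool(obs < q)
    return bool(obs == 0)


# --------------------------------------------------------------------------
# Longitudinal stability
# --------------------------------------------------------------------------
def jaccard_stability(
    flags_a: np.ndarray,
    flags_b: np.ndarray,
    registry: CellRegistry,
) -> float:
    """Jaccard index of binary (neuron x behavior) attributes across sessions.

    Attribute sets are restricted to registered cell pairs; returns
    intersection-over-union, or NaN when the union is empty.
    """
    if registry.n_pairs == 0:
        raise ValueError("empty registry")
    a = np.asarray(flags_a, dtype=bool)[registry.pairs[:, 0]]
    b = np.asarray(flags_b, dtype=bool)[registry.pairs[:, 1]]
    union = (a | b).sum()
    if union == 0:
        return np.nan
    return float((a & b).sum() / union)


def registry_controls(
    registry: CellRegistry,
    mode: str,
    seed: int | np.random.Generator = 0,
) -> CellRegistry:
    """Control registries for longitudinal analyses.

    ``shuffle_pairs``
        Randomly re-pair session-B cells among the registered pairs (a
        derangement, so no cell keeps its true partner).
    ``closest_neighbor``
        Replace every session-B cell with its nearest *other* session-B cell
        by centroid distance (requires centroids).
    """
    rng = np.random.default_rng(seed)
    pairs = registry.pairs.copy()
    if mode == "shuffle_pairs":
        m = pairs.shape[0]
        if m < 2:
            raise ValueError("need at least 2 pairs to shuffle")
        while True:
            perm = rng.permutation(m)
            if not (perm == np.arange(m)).any():
                break
        pairs[:, 1] = pairs[perm, 1]
    elif mode == "closest_neighbor":
        cb = registry.centroids_b
        if cb is None:
            raise ValueError("closest_neighbor requires session-B centroids")
        ok = np.flatnonzero(np.isfinite(cb).all(axis=1))
        if ok.size < 2:
            raise ValueError("need at least 2 session-B cells with centroids")
        for k in range(pairs.shape[0]):
            b = pairs[k, 1]
            d = np.linalg.norm(cb[ok] - cb[b], axis=1)
            d[ok == b] = np.inf
            pairs[k, 1] = ok[np.argmin(d)]
    else:
        raise ValueError("mode must be 'shuffle_pairs' or 'closest_neighbor'")
    if mode == "shuffle_pairs":
        return CellRegistry(pairs, registry.centroids_a, registry.centroids_b)
    # the closest-neighbor control may map several A cells onto one B cell,
    # so the uniqueness check of the regular constructor is bypassed
    return _unchecked_registry(pairs, registry.centroids_a, registry.centroids_b)


def _unchecked_registry(pairs, ca, cb) -> CellRegistry:
    """Registry that may repeat session-B cells (closest-neighbor control)."""
    reg = object.__new__(CellRegistry)
    reg.pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    reg.centroids_a = ca
    reg.centroids_b = cb
    return reg
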