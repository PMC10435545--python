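"""One-vs-one linear SVM decoding of behavior from population activity.

The deconvolved event raster is convolved with a 500-ms square window and the
resulting frame-wise population vectors feed 66 binary linear SVMs, one per
unordered behavior pair (12-class catalog).  Multiclass prediction is the
behavior winning the most pairwise votes (ties to the lowest behavior id).
Data are split 80/20 into train and test; the SVM regularization strength is
selected by 5-fold cross-validation on the training set over a logarithmic
grid.  The split is a contiguous block by default to limit temporal leakage
through the convolution window; a frame-random split is available.

Performance is summarized by the test-set accuracy (fraction of correctly
predicted time bins), the *behavior reconstruction error* (mean behavioral
distance between predicted and observed behaviors; 0 for correct bins), and
per-behavior one-vs-rest simple matching coefficients (TP+TN)/N.

Chance levels come from a *time-lagged null*: the behavior label series is
flipped in time, cyclically shifted by a random lag (at least 30 s), a fresh
decoder is trained on the lagged labels, and its predictions are scored
against the original labels; the null is the average over 10 random lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import warnings

import numpy as np
from scipy.stats import spearmanr
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .catalog import BehaviorLabels, UNLABELED
from .raster import EventRaster
from .registry import CellRegistry
from .similarity import align_labels

#: Logarithmic regularization grid for the 5-fold CV.
DEFAULT_C_GRID = (0.01, 1.0, 100.0)

#: Session-eligibility thresholds for subset analyses.
MIN_ACTIVE_NEURONS = 40
MIN_SILENT_NEURONS = 20
MIN_REGISTERED_NEURONS = 40


def preprocess_activity(raster: EventRaster, window_ms: float = 500.0) -> np.ndarray:
    """Boxcar-convolve the raster over ``window_ms`` (frames x neurons).

    The square kernel spans ``round(window_ms / 1000 * rate)`` frames
    (10 frames at 20 frames/s), centered, and sums the events it covers;
    output length equals input length.
    """
    k = int(round(window_ms / 1000.0 * raster.rate))
    if k < 1:
        raise ValueError("window shorter than one frame")
    kernel = np.ones(k)
    out = np.empty((raster.n_frames, raster.n_neurons))
    lo = (k - 1) // 2
    for i in range(raster.n_neurons):
        full = np.convolve(raster.events[i], kernel, mode="full")
        out[:, i] = full[k - 1 - lo: k - 1 - lo + raster.n_frames]
    return out


@dataclass
class DecoderModel:
    """Fitted one-vs-one decoder.

    ``classifiers`` maps each unordered behavior pair (i, j), i < j, to a
    fitted linear SVM (or None when the pair was degenerate in training).
    """

    classifiers: dict
    classes: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    neuron_idx: np.ndarray
    window_ms: float
    seed: int | None = None

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    @property
    def degenerate_pairs(self) -> list:
        return [p for p, clf in self.classifiers.items() if clf is None]

    def transform(self, features: np.ndarray) -> np.ndarray:
        if features.shape[1] != self.scaler_mean.size:
            raise ValueError("feature dimensionality does not match the model")
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (features - self.scaler_mean) / self.scaler_sd
        return np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0)


@dataclass
class DecodingReport:
    """Decoding performance summary."""

    accuracy: float
    reconstruction_error: float = np.nan
    per_behavior_smc: dict = field(default_factory=dict)
    pair_accuracy: dict = field(default_factory=dict)
    n_test_frames: int = 0
    n_neurons: int = 0
    discarded: bool = False
    null_mean: float = np.nan
    null_sd: float = np.nan
    lag_accuracies: list = field(default_factory=list)
    lag_errors: list = field(default_factory=list)


def _contiguous_split(n: int, split_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    n_test = int(round(n * (1.0 - split_fraction)))
    start = int(rng.integers(0, n - n_test + 1))
    test = np.arange(start, start + n_test)
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def train_decoder(
    features: np.ndarray,
    labels: np.ndarray,
    split_fraction: float = 0.8,
    n_folds: int = 5,
    c_grid=DEFAULT_C_GRID,
    split: str = "blocks",
    max_pair_frames: int = 1500,
    cv_subsample: int = 500,
    seed: int | np.random.Generator = 0,
) -> DecoderModel:
    """Fit the 66 pairwise linear SVMs on an 80/20 train/test split.

    ``features`` is (frames x neurons) preprocessed activity; ``labels`` the
    aligned behavior ids.  Per-neuron z-scoring uses training frames only.
    For each behavior pair the regularization strength is selected by
    ``n_folds``-fold cross-validation over ``c_grid``; pair training sets
    larger than ``max_pair_frames`` frames are subsampled for tractability.
    Pairs missing a behavior in the training split are flagged degenerate.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=np.int64)
    if features.shape[0] != labels.size:
        raise ValueError("features and labels must cover the same frames")
    classes = np.unique(labels[labels != UNLABELED])
    if classes.size < 2:
        raise ValueError("need at least 2 behavior classes")
    n = labels.size
    if split == "blocks":
        train_idx, test_idx = _contiguous_split(n, split_fraction, rng)
    elif split == "random":
        perm = rng.permutation(n)
        cut = int(round(n * split_fraction))
        train_idx, test_idx = np.sort(perm[:cut]), np.sort(perm[cut:])
    else:
        raise ValueError("split must be 'blocks' or 'random'")

    mean = features[train_idx].mean(axis=0)
    sd = features[train_idx].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (features - mean) / sd

    lab_train = labels[train_idx]
    classifiers: dict = {}
    for i, j in combinations(classes.tolist(), 2):
        sel = np.flatnonzero((lab_train == i) | (lab_train == j))
        if (lab_train[sel] == i).sum() == 0 or (lab_train[sel] == j).sum() == 0:
            classifiers[(i, j)] = None
            continue
        if sel.size > max_pair_frames:
            sel = np.sort(rng.choice(sel, size=max_pair_frames, replace=False))
        x = z[train_idx[sel]]
        y = lab_train[sel]
        folds = min(n_folds, min((y == i).sum(), (y == j).sum()))
        best_c = c_grid[len(c_grid) // 2]
        if folds >= 2 and len(c_grid) > 1:
            # C-selection runs on a subsample of the pair's training frames
            # (the selection is stable well below the full set size); the
            # winning C is refitted on the full pair training set below
            cv_sel = np.arange(y.size)
            if y.size > cv_subsample:
                cv_sel = np.sort(rng.choice(y.size, size=cv_subsample,
                                            replace=False))
            xc, yc = x[cv_sel], y[cv_sel]
            fold_of = np.arange(yc.size) % folds
            scores = np.zeros(len(c_grid))
            for f in range(folds):
                tr, te = fold_of != f, fold_of == f
                if np.unique(yc[tr]).size < 2:
                    continue
                for ci, c in enumerate(c_grid):
                    clf = LinearSVC(dual=False, tol=1e-2, max_iter=400, C=c)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        clf.fit(xc[tr], yc[tr])
                    scores[ci] += (clf.predict(xc[te]) == yc[te]).mean()
            best_c = c_grid[int(np.argmax(scores))]
        svc = LinearSVC(dual=False, tol=1e-2, max_iter=400, C=best_c)
        with warnings.catch_warnings():
            # truncated liblinear runs are part of the speed/accuracy tradeoff
            warnings.simplefilter("ignore", ConvergenceWarning)
            svc.fit(x, y)
        classifiers[(i, j)] = svc
    return DecoderModel(
        classifiers=classifiers,
        classes=classes,
        scaler_mean=mean,
        scaler_sd=sd,
        train_idx=train_idx,
        test_idx=test_idx,
        neuron_idx=np.arange(features.shape[1]),
        window_ms=500.0,
    )


def predict_behavior(model: DecoderModel, features: np.ndarray) -> np.ndarray:
    """Majority vote over the pairwise classifiers; ties to the lowest id."""
    z = model.transform(features)
    k = int(model.classes.max()) + 1
    votes = np.zeros((features.shape[0], k))
    for (i, j), clf in model.classifiers.items():
        if clf is None:
            continue
        pred = clf.predict(z)
        votes[pred == i, i] += 1
        votes[pred == j, j] += 1
    # argmax breaks ties toward the lowest behavior id
    return votes.argmax(axis=1)


def evaluate_decoding(
    model: DecoderModel,
    features: np.ndarray,
    labels: np.ndarray,
    distances: np.ndarray | None = None,
    frame_idx: np.ndarray | None = None,
) -> DecodingReport:
    """Score the decoder on ``frame_idx`` (the model's test frames by default).

    Reports accuracy, the behavioral-distance reconstruction error (mean
    distance between predicted and observed behavior, 0 on correct bins;
    requires the pairwise ``distances`` matrix), per-behavior one-vs-rest
    simple matching coefficients, and per-pair accuracies on the frames
    belonging to each behavior pair.
    """
    labels = np.asarray(labels, dtype=np.int64)
    idx = model.test_idx if frame_idx is None else np.asarray(frame_idx)
    obs = labels[idx]
    keep = obs != UNLABELED
    idx, obs = idx[keep], obs[keep]
    pred = predict_behavior(model, features[idx])
    accuracy = float((pred == obs).mean()) if obs.size else np.nan

    err = np.nan
    if distances is not None:
        d = np.asarray(distances, dtype=float)[obs, pred]
        err = float(np.nanmean(np.where(pred == obs, 0.0, d)))

    smc = {}
    for b in model.classes.tolist():
        smc[b] = float(((pred == b) == (obs == b)).mean())

    pair_acc = {}
    for (i, j), clf in model.classifiers.items():
        if clf is None:
            continue
        sel = (obs == i) | (obs == j)
        if not sel.any():
            continue
        pij = clf.predict(model.transform(features[idx[sel]]))
        pair_acc[(i, j)] = float((pij == obs[sel]).mean())

    return DecodingReport(
        accuracy=accuracy,
        reconstruction_error=err,
        per_behavior_smc=smc,
        pair_accuracy=pair_acc,
        n_test_frames=int(obs.size),
        n_neurons=int(model.neuron_idx.size),
    )


def time_lag_null(
    features: np.ndarray,
    labels: np.ndarray,
    rate: float,
    n_lags: int = 10,
    min_lag_s: float = 30.0,
    distances: np.ndarray | None = None,
    split: str = "blocks",
    seed: int | np.random.Generator = 0,
    **train_kw,
) -> DecodingReport:
    """Chance-level decoding from flipped, cyclically lagged label series.

    For each of ``n_lags`` random lags (|lag| > ``min_lag_s``), the label
    series is reversed and rolled, a full decoder is retrained on the lagged
    labels, and its predictions on the original test frames are scored
    against the *original* labels.  The report carries the mean accuracy and
    reconstruction error over lags plus their spread.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=np.int64)
    n = labels.size
    margin = int(round(min_lag_s * rate))
    if n <= 2 * margin:
        raise ValueError("session shorter than twice the lag margin")
    accs, errs = [], []
    for _ in range(n_lags):
        lag = int(rng.integers(margin, n - margin))
        lagged = np.roll(labels[::-1], lag)
        model = train_decoder(features, lagged, split=split, seed=rng, **train_kw)
        rep = evaluate_decoding(model, features, labels, distances=distances,
                                frame_idx=model.test_idx)
        accs.append(rep.accuracy)
        errs.append(rep.reconstruction_error)
    return DecodingReport(
        accuracy=float(np.mean(accs)),
        reconstruction_error=float(np.mean(errs)) if distances is not None else np.nan,
        n_test_frames=0,
        n_neurons=features.shape[1],
        null_mean=float(np.mean(accs)),
        null_sd=float(np.std(accs, ddof=1)) if n_lags > 1 else np.nan,
        lag_accuracies=accs,
        lag_errors=errs,
    )


def decode_session(
    raster: EventRaster,
    labels: BehaviorLabels,
    distances: np.ndarray | None = None,
    window_ms: float = 500.0,
    seed: int | np.random.Generator = 0,
    **train_kw,
) -> tuple[DecoderModel, DecodingReport]:
    """Convenience wrapper: preprocess, train, and evaluate on the test split."""
    feats = preprocess_activity(raster, window_ms)
    lab = align_labels(labels, raster)
    model = train_decoder(feats, lab, seed=seed, **train_kw)
    report = evaluate_decoding(model, feats, lab, distances=distances)
    return model, report


def subset_decode(
    raster: EventRaster,
    labels: BehaviorLabels,
    subset: np.ndarray,
    min_neurons: int,
    distances: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    **train_kw,
) -> DecodingReport:
    """Decode from a neuron subset; discarded (not an error) under threshold.

    Eligibility follows the session thresholds: at least 40 neurons for the
    behavior-active subset, at least 20 for behavior-silent (or -inactive)
    subsets (strictly fewer is discarded).
    """
    subset = np.asarray(subset)
    if subset.dtype == bool:
        subset = np.flatnonzero(subset)
    if subset.size < min_neurons:
        return DecodingReport(accuracy=np.nan, discarded=True,
                              n_neurons=int(subset.size))
    model, report = decode_session(raster.subset(subset), labels,
                                   distances=distances, seed=seed, **train_kw)
    return report


def longitudinal_decode(
    raster_a: EventRaster,
    labels_a: BehaviorLabels,
    raster_b: EventRaster,
    labels_b: BehaviorLabels,
    registry: CellRegistry,
    min_registered: int = MIN_REGISTERED_NEURONS,
    distances: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    **train_kw,
) -> DecodingReport:
    """Train on session A (registered cells only), test on session B.

    Session-B columns are ordered by the registry so each model input
    dimension corresponds to the same physical cell in both sessions.  Pairs
    with fewer than ``min_registered`` registered cells are discarded.
    """
    if registry.n_pairs < min_registered:
        return DecodingReport(accuracy=np.nan, discarded=True,
                              n_neurons=registry.n_pairs)
    sub_a = raster_a.subset(registry.pairs[:, 0])
    sub_b = raster_b.subset(registry.pairs[:, 1])
    feats_a = preprocess_activity(sub_a)
    feats_b = preprocess_activity(sub_b)
    lab_a = align_labels(labels_a, sub_a)
    lab_b = align_labels(labels_b, sub_b)
    model = train_decoder(feats_a, lab_a, seed=seed, **train_kw)
    return evaluate_decoding(model, feats_b, lab_b, distances=distances,
                             frame_idx=np.arange(lab_b.size))


def pair_accuracy_vs_distance(
    report: DecodingReport,
    distances: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rank correlation between per-pair decoding accuracy and behavioral
    distance over the 66 behavior pairs.  Returns (accuracies, distances,
    Spearman rho); rho is NaN (flagged) when either vector is constant."""
    pairs = sorted(report.pair_accuracy)
    acc = np.array([report.pair_accuracy[p] for p in pairs])
    d = np.array([distances[p] for p in pairs])
    ok = np.isfinite(acc) & np.isfinite(d)
    acc, d = acc[ok], d[ok]
    if acc.size < 3 or np.ptp(acc) == 0 or np.ptp(d) == 0:
        return acc, d, np.nan
    rho, _ = spearmanr(acc, d)
    return acc, d, float(rho)
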