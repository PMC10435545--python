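"""Annotation-agreement metrics and the permutation-based t-test.

Classification performance against human annotation is summarized per class
by accuracy, precision, recall and F1 (harmonic mean of precision and
recall), macro-averaged with equal class weights.  Human reference labels
come from a majority vote over annotators, discarding items whose winning
class gets less than half the votes.  Group comparisons use a two-sided
permutation t-test; the omnibus linear mixed-effects modelling that precedes
such post hoc tests in a full study is delegated to general statistics
libraries and is not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import BEHAVIOR_NAMES

#: Sentinel for items discarded by the majority vote.
DISCARDED: int = -1


@dataclass
class ConfusionMatrix:
    """Reference x predicted count matrix over a fixed class catalog."""

    counts: np.ndarray
    class_names: tuple[str, ...] = field(default=BEHAVIOR_NAMES)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, reference, predicted,
                    class_names: tuple[str, ...] = BEHAVIOR_NAMES) -> "ConfusionMatrix":
        k = len(class_names)
        reference = np.asarray(reference, dtype=np.int64)
        predicted = np.asarray(predicted, dtype=np.int64)
        counts = np.zeros((k, k), dtype=np.int64)
        np.add.at(counts, (reference, predicted), 1)
        return cls(counts, class_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def per_class_metrics(cm: ConfusionMatrix, class_id: int) -> dict[str, float]:
    """One-vs-rest accuracy, precision, recall and F1 for one class.

    accuracy = (TP + TN) / N, precision = TP / (TP + FP),
    recall = TP / (TP + FN), F1 = 2 * precision * recall / (precision + recall).
    Ratios with zero denominator are reported as NaN (undefined), never as 0.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = cm.counts[class_id, class_id]
    fp = cm.counts[:, class_id].sum() - tp
    fn = cm.counts[class_id, :].sum() - tp
    tn = n - tp - fp - fn

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = np.nan
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def all_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    rows = [per_class_metrics(cm, i) for i in range(len(cm.class_names))]
    return pd.DataFrame(rows, index=list(cm.class_names))


def macro_average(metrics: pd.DataFrame) -> dict[str, float]:
    """Unweighted mean of per-class metrics, skipping undefined (NaN) classes."""
    if len(metrics) == 0:
        raise ValueError("no classes")
    return {col: float(np.nanmean(metrics[col].to_numpy())) for col in metrics.columns}


def majority_classification(votes: np.ndarray | list) -> int:
    """Majority vote over annotator class votes for one item.

    Returns the modal class if it holds at least 50% of the votes and is a
    unique mode; otherwise DISCARDED.  (A class with exactly half the votes
    is kept, since only items with *less than* 50% agreement are discarded;
    exact ties between two modal classes are discarded.)
    """
    votes = np.asarray(votes, dtype=np.int64)
    if votes.size == 0:
        raise ValueError("need at least one vote")
    classes, counts = np.unique(votes, return_counts=True)
    top = counts.max()
    if top / votes.size < 0.5 or (counts == top).sum() > 1:
        return DISCARDED
    return int(classes[np.argmax(counts)])


def majority_classification_table(annotations: pd.DataFrame) -> pd.Series:
    """Majority classification per item from a long-format annotation table.

    ``annotations`` has columns item, annotator, vote (optionally pass for
    repeated scoring; all passes count as votes).
    """
    return annotations.groupby("item")["vote"].apply(
        lambda v: majority_classification(v.to_numpy()))


def annotator_consistency(annotations: pd.DataFrame, annotator) -> float:
    """Intra-annotator consistency: simple matching between the annotator's
    two scoring passes over the same items."""
    sub = annotations[annotations["annotator"] == annotator]
    wide = sub.pivot_table(index="item", columns="pass", values="vote",
                           aggfunc="first")
    if wide.shape[1] != 2:
        raise ValueError("annotator must have exactly two passes")
    both = wide.dropna()
    return float((both.iloc[:, 0] == both.iloc[:, 1]).mean())


def _t_statistic(a_sum, a_sq, na, b_sum, b_sq, nb):
    """Pooled-variance two-sample t from sufficient statistics (vectorized)."""
    ma, mb = a_sum / na, b_sum / nb
    ssa = a_sq - na * ma ** 2
    ssb = b_sq - nb * mb ** 2
    sp2 = (ssa + ssb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return t


def permutation_t_test(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided permutation test on the two-sample pooled-variance t statistic.

    The p-value is the fraction of group-label permutations whose |t| is at
    least the observed |t|, counting the observed labelling itself in both
    numerator and denominator (add-one rule), so the returned p is never
    exactly 0: with finitely many permutations a zero p-value would overstate
    the evidence.

    Degenerate case: if both groups have zero variance and equal means the
    statistic is undefined and p = 1 is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 samples")
    pooled = np.concatenate([a, b])
    na, nb = a.size, b.size
    if np.ptp(pooled) == 0:
        return 1.0

    t_obs = _t_statistic(a.sum(), (a ** 2).sum(), na, b.sum(), (b ** 2).sum(), nb)
    if not np.isfinite(t_obs):
        # zero pooled variance with unequal means cannot happen (ptp>0 above);
        # equal means with zero variance handled above
        return 1.0

    rng = np.random.default_rng(seed)
    tot_sum = pooled.sum()
    tot_sq = (pooled ** 2).sum()
    # vectorized permutations: random order per row, group A = first na columns
    perm = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    pa = perm[:, :na]
    a_sum = pa.sum(axis=1)
    a_sq = (pa ** 2).sum(axis=1)
    t_perm = _t_statistic(a_sum, a_sq, na, tot_sum - a_sum, tot_sq - a_sq, nb)
    t_perm = np.nan_to_num(t_perm, nan=0.0)
    n_extreme = int((np.abs(t_perm) >= abs(t_obs) - 1e-12).sum())
    return (n_extreme + 1) / (n_perm + 1)
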