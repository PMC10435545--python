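"""Unsupervised identification of behaviors from the six posture features.

The pipeline mirrors a consensus-clustering design:

1. the six features are z-scored and a quarter of the (valid) frames is
   subsampled;
2. the subsample is embedded in 3 dimensions by t-SNE (3 being validated
   against the number of principal components needed to explain >= 70% of the
   variance), with 10 independent t-SNE replicates;
3. each embedding is clustered by a Gaussian mixture model, 50 random
   restarts per embedding, giving 500 partitions of the same frames;
4. the 500 partitions are reduced to one consensus partition by average-
   linkage agglomeration of the frame-frame Hamming (co-assignment
   disagreement) matrix; clusters with fewer than 20 frames are dropped;
5. surviving clusters are merged in ascending order of their pairwise
   Wasserstein distance (sum of the six per-feature 1-D distances, in
   z-scored units) until the smallest distance reaches a cutoff of 1;
6. each merged cluster is registered to one of the 12 catalog behaviors,
   either through an explicit user mapping (emulating manual registration)
   or through threshold rules on the cluster's median features;
7. every frame of the session is assigned the behavior with the highest
   likelihood under per-behavior Gaussian models fitted in feature space;
8. episodes shorter than 4 frames (100 ms) are removed and unlabeled gaps
   are split half to the preceding and half to the following behavior.

Replication counts, the GMM component range, the consensus cut and the
embedding-subsample cap are configurable; the defaults are stated in the
methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import wasserstein_distance
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import rand_score
from sklearn.mixture import GaussianMixture

from .catalog import (
    BehaviorCatalog,
    BehaviorLabels,
    DEFAULT_CATALOG,
    UNLABELED,
    episodes_from_labels,
)
from .features import FEATURE_NAMES, FeatureSeries


class EmptyConsensusError(RuntimeError):
    """All consensus clusters fell below the minimum size floor."""


class UnregisteredClusterError(RuntimeError):
    """A cluster matched no registration rule and no explicit map entry."""


@dataclass
class ArchetypePartition:
    """One clustering of a fixed frame subset.

    ``frame_indices`` index into the full session; ``cluster_ids`` are
    contiguous nonnegative integers (UNLABELED = -1 allowed after the
    size-floor step of the consensus).
    """

    frame_indices: np.ndarray
    cluster_ids: np.ndarray
    provenance: tuple = ()

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=np.int64)
        if self.frame_indices.size != self.cluster_ids.size:
            raise ValueError("frame_indices and cluster_ids must align")

    @property
    def n_clusters(self) -> int:
        labeled = self.cluster_ids[self.cluster_ids != UNLABELED]
        return int(np.unique(labeled).size)

    def relabeled(self) -> "ArchetypePartition":
        """Contiguous cluster ids (stable order), UNLABELED untouched."""
        ids = self.cluster_ids.copy()
        labeled = ids != UNLABELED
        uniq = np.unique(ids[labeled])
        remap = {c: k for k, c in enumerate(uniq.tolist())}
        ids[labeled] = np.array([remap[c] for c in ids[labeled]])
        return ArchetypePartition(self.frame_indices, ids, self.provenance)


def pca_dimension_criterion(values: np.ndarray, variance: float = 0.70) -> int:
    """Smallest number of principal components explaining >= ``variance``."""
    pca = PCA().fit(values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, variance) + 1)


def standardize(features: FeatureSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each feature over its valid frames; returns (z, mean, sd)."""
    vals = features.values
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (vals - mean) / sd, mean, sd


def embed_features(
    features: FeatureSeries,
    subsample_fraction: float = 0.25,
    n_dims: int = 3,
    n_replicates: int = 10,
    perplexity: float = 30.0,
    max_frames: int | None = None,
    tsne_iter: int = 500,
    seed: int | np.random.Generator = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """t-SNE embeddings of a frame subsample of the z-scored features.

    Returns ``n_replicates`` embeddings (same frames, independent t-SNE
    randomizations) and the subsampled frame indices.  The requested
    dimensionality is validated against the 70%-variance PCA criterion and a
    warning is emitted on mismatch.
    """
    rng = np.random.default_rng(seed)
    z, _, _ = standardize(features)
    valid = np.flatnonzero(np.isfinite(z).all(axis=1))
    n_sub = int(round(subsample_fraction * valid.size))
    if max_frames is not None:
        n_sub = min(n_sub, max_frames)
    if n_sub <= perplexity * 3:
        raise ValueError("too few frames for the requested perplexity")
    idx = np.sort(rng.choice(valid, size=n_sub, replace=False))
    zs = z[idx]

    k70 = pca_dimension_criterion(zs)
    if k70 != n_dims:
        warnings.warn(
            f"PCA 70%-variance criterion suggests {k70} dimensions, "
            f"embedding uses {n_dims}", stacklevel=2)

    embeddings = []
    for r in range(n_replicates):
        ts = TSNE(n_components=n_dims, perplexity=perplexity,
                  max_iter=tsne_iter, init="pca",
                  random_state=int(rng.integers(2**31 - 1)))
        embeddings.append(ts.fit_transform(zs))
    return embeddings, idx


def cluster_embeddings(
    embeddings: list[np.ndarray],
    frame_indices: np.ndarray,
    n_gmm_replicates: int = 50,
    gmm_range: tuple[int, int] = (8, 30),
    gmm_step: int = 3,
    seed: int | np.random.Generator = 0,
) -> list[ArchetypePartition]:
    """GMM partitions of each embedding, ``n_gmm_replicates`` restarts each.

    The mixture component count is selected per embedding by the Bayesian
    information criterion over ``gmm_range`` (deliberately allowing more
    components than behaviors, so over-segmentation precedes merging).
    """
    rng = np.random.default_rng(seed)
    partitions: list[ArchetypePartition] = []
    for e_idx, emb in enumerate(embeddings):
        if np.allclose(emb.std(axis=0), 0):
            raise RuntimeError("degenerate embedding: all points identical")
        ks = list(range(gmm_range[0], gmm_range[1] + 1, gmm_step))
        bics = []
        for k in ks:
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 reg_covar=1e-4, max_iter=100,
                                 random_state=int(rng.integers(2**31 - 1)))
            gm.fit(emb)
            bics.append(gm.bic(emb))
        k_best = ks[int(np.argmin(bics))]
        for r in range(n_gmm_replicates):
            gm = GaussianMixture(n_components=k_best, covariance_type="full",
                                 reg_covar=1e-4, max_iter=100, init_params="random",
                                 random_state=int(rng.integers(2**31 - 1)))
            labels = gm.fit_predict(emb)
            partitions.append(ArchetypePartition(frame_indices, labels,
                                                 provenance=(e_idx, r)))
    return partitions


def consensus_clusters(
    partitions: list[ArchetypePartition],
    min_cluster_frames: int = 20,
    cut: float = 0.5,
) -> ArchetypePartition:
    """Consensus partition from many partitions of the same frames.

    The frame-frame Hamming disagreement (1 - co-assignment frequency across
    partitions) is clustered by average-linkage agglomeration and cut at
    ``cut``; consensus clusters smaller than ``min_cluster_frames`` are
    dropped (their frames become UNLABELED).
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    idx0 = partitions[0].frame_indices
    for p in partitions[1:]:
        if not np.array_equal(p.frame_indices, idx0):
            raise ValueError("partitions must cover the same frame subset")
    n = idx0.size
    co = np.zeros((n, n), dtype=np.float32)
    for p in partitions:
        c = p.cluster_ids
        co += (c[:, None] == c[None, :])
    co /= len(partitions)
    dist = 1.0 - co
    np.fill_diagonal(dist, 0.0)
    zlink = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(zlink, t=cut, criterion="distance") - 1

    ids, counts = np.unique(labels, return_counts=True)
    small = ids[counts < min_cluster_frames]
    out = labels.astype(np.int64)
    out[np.isin(labels, small)] = UNLABELED
    if (out == UNLABELED).all():
        raise EmptyConsensusError("all consensus clusters below the size floor")
    return ArchetypePartition(idx0, out, provenance=("consensus",)).relabeled()


def _cluster_wasserstein(feat_a: np.ndarray, feat_b: np.ndarray) -> float:
    """Sum over feature channels of 1-D Wasserstein distances."""
    return float(sum(
        wasserstein_distance(feat_a[:, f], feat_b[:, f])
        for f in range(feat_a.shape[1])
    ))


def merge_clusters_wasserstein(
    partition: ArchetypePartition,
    features_z: np.ndarray,
    cutoff: float = 1.0,
) -> ArchetypePartition:
    """Agglomerate clusters whose feature-distribution distance is < cutoff.

    ``features_z`` are the z-scored feature values for the partition's
    frames (the cutoff of 1 is interpreted in standardized units).  The pair
    with the smallest summed per-feature Wasserstein distance is merged
    repeatedly while that distance stays below the cutoff.
    """
    ids = partition.cluster_ids.copy()
    if features_z.shape[0] != ids.size:
        raise ValueError("features must align with the partition frames")
    clusters = {int(c): np.flatnonzero(ids == c)
                for c in np.unique(ids[ids != UNLABELED])}
    if len(clusters) <= 1:
        return partition.relabeled()

    def dist(a: int, b: int) -> float:
        return _cluster_wasserstein(features_z[clusters[a]], features_z[clusters[b]])

    d = {(a, b): dist(a, b) for a, b in combinations(sorted(clusters), 2)}
    while len(clusters) > 1:
        (a, b), dmin = min(d.items(), key=lambda kv: kv[1])
        if dmin >= cutoff:
            break
        clusters[a] = np.concatenate([clusters[a], clusters[b]])
        del clusters[b]
        d = {k: v for k, v in d.items() if b not in k}
        for c in clusters:
            if c != a:
                key = (min(a, c), max(a, c))
                d[key] = dist(a, c)
    for c, members in clusters.items():
        ids[members] = c
    return ArchetypePartition(partition.frame_indices, ids,
                              partition.provenance + ("merged",)).relabeled()


#: Default thresholds (raw feature units: cm/s, cm/s, rad, cm, cm, cm) for
#: rule-based registration of clusters to the behavior catalog.
DEFAULT_REGISTRATION_THRESHOLDS = {
    "speed_fast": 15.0,        # body speed above this: locomotion fast
    "speed_moving": 2.0,       # body speed above this: locomoting
    "angle_turn": 0.06,        # |movement angle| above this: turning
    "body_long": 6.8,          # body length above this + elongated neck: sniffing
    "neck_long": 3.6,
    "body_short": 4.5,         # body length below this: rearing / grooming
    "head_elev_high": 2.2,     # head elevation above this: head up / rearing
    "head_speed_groom": 4.0,   # camera clearly moving during grooming
    "angle_sd_groom": 0.15,    # large movement-angle variability: grooming
    "head_speed_still": 1.0,   # camera speed ~0: immobility
}


def cluster_feature_stats(partition: ArchetypePartition,
                          features: FeatureSeries) -> dict[int, dict[str, float]]:
    """Median of each feature (plus movement-angle SD) per cluster, raw units."""
    vals = features.values[partition.frame_indices]
    stats: dict[int, dict[str, float]] = {}
    for c in np.unique(partition.cluster_ids[partition.cluster_ids != UNLABELED]):
        sub = vals[partition.cluster_ids == c]
        entry = {name: float(np.nanmedian(sub[:, i]))
                 for i, name in enumerate(FEATURE_NAMES)}
        entry["movement_angle_sd"] = float(np.nanstd(sub[:, 2]))
        stats[int(c)] = entry
    return stats


def _rule_behavior(s: dict[str, float], th: dict[str, float]) -> int | None:
    """Threshold rules mapping cluster feature medians to a behavior id."""
    bs, hs, ang = s["body_speed"], s["head_speed"], s["movement_angle"]
    bl, ne, he = s["body_length"], s["neck_elongation"], s["head_elevation"]
    ang_sd = s["movement_angle_sd"]
    if bs > th["speed_fast"]:
        return 0                                    # locomotion fast
    if bs > th["speed_moving"]:
        if bl > th["body_long"] and ne > th["neck_long"]:
            return 9                                # locomotion sniffing
        if ang > th["angle_turn"]:
            return 2                                # locomotion turn right
        if ang < -th["angle_turn"]:
            return 3                                # locomotion turn left
        return 1                                    # locomotion straight
    # still postures
    if bl > th["body_long"] and ne > th["neck_long"]:
        return 10                                   # still sniffing
    if he > th["head_elev_high"]:
        return 7 if bl < th["body_short"] else 6    # rearing / head up
    # grooming: still, compact posture, head low but camera clearly moving
    # (or, equivalently, large movement-angle variability)
    if bl < th["body_short"] and (hs > th["head_speed_groom"]
                                  or ang_sd > th["angle_sd_groom"]):
        return 8                                    # grooming
    if ang > th["angle_turn"]:
        return 4                                    # still turn right
    if ang < -th["angle_turn"]:
        return 5                                    # still turn left
    if hs < th["head_speed_still"]:
        return 11                                   # immobility
    return None


def register_clusters(
    partition: ArchetypePartition,
    features: FeatureSeries,
    catalog: BehaviorCatalog = DEFAULT_CATALOG,
    mapping: dict[int, int | str] | None = None,
    thresholds: dict[str, float] | None = None,
) -> dict[int, int]:
    """Map every cluster to one behavior of the catalog.

    An explicit ``mapping`` (cluster id -> behavior id or name), emulating
    manual registration from video inspection, takes precedence; remaining
    clusters go through threshold rules on their median features.  A cluster
    matching neither raises UnregisteredClusterError listing its medians.
    """
    th = dict(DEFAULT_REGISTRATION_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    stats = cluster_feature_stats(partition, features)
    result: dict[int, int] = {}
    for c, s in stats.items():
        if mapping is not None and c in mapping:
            m = mapping[c]
            result[c] = catalog.id_of(m) if isinstance(m, str) else int(m)
            continue
        b = _rule_behavior(s, th)
        if b is None:
            raise UnregisteredClusterError(
                f"cluster {c} matched no registration rule; feature medians: {s}")
        result[c] = b
    return result


def assign_frames_max_likelihood(
    features: FeatureSeries,
    partition: ArchetypePartition,
    cluster_to_behavior: dict[int, int],
    catalog: BehaviorCatalog = DEFAULT_CATALOG,
    reg: float = 1e-6,
    min_frames_per_behavior: int = 30,
) -> BehaviorLabels:
    """Assign every session frame to its maximum-likelihood behavior.

    Per-behavior full-covariance Gaussians are fitted on the z-scored
    features of the registered cluster frames; all frames with valid
    features are then assigned the behavior with the highest log-likelihood
    (ties broken toward the lower behavior id).  Frames with masked features
    stay UNLABELED for the post-processing step to fill.
    """
    z, _, _ = standardize(features)
    zp = z[partition.frame_indices]
    behaviors = sorted(set(cluster_to_behavior.values()))
    params = {}
    for b in behaviors:
        members = np.concatenate([
            np.flatnonzero(partition.cluster_ids == c)
            for c, bb in cluster_to_behavior.items() if bb == b
        ])
        sub = zp[members]
        sub = sub[np.isfinite(sub).all(axis=1)]
        if sub.shape[0] < min_frames_per_behavior:
            warnings.warn(f"behavior {b}: only {sub.shape[0]} frames to fit the "
                          "likelihood model", stacklevel=2)
        mu = sub.mean(axis=0)
        cov = np.cov(sub.T) + reg * np.eye(sub.shape[1])
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn(f"behavior {b}: singular covariance, regularized",
                          stacklevel=2)
            cov += 1e-3 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        params[b] = (mu, cov)

    n = features.n_frames
    valid = np.isfinite(z).all(axis=1)
    loglik = np.full((n, len(catalog)), -np.inf)
    from scipy.stats import multivariate_normal

    for b, (mu, cov) in params.items():
        loglik[valid, b] = multivariate_normal.logpdf(z[valid], mu, cov)
    labels = np.full(n, UNLABELED, dtype=np.int64)
    labels[valid] = np.argmax(loglik[valid], axis=1)  # ties -> lower id
    return BehaviorLabels(labels, features.frame_rate, catalog)


def postprocess_labels(labels: BehaviorLabels, min_frames: int = 4) -> BehaviorLabels:
    """Remove sub-100-ms episodes and fill unlabeled gaps.

    Episodes shorter than ``min_frames`` are deleted (frames become
    unlabeled); each unlabeled run is then split, the first half (rounding
    up) joining the preceding behavior and the second half the following one
    (runs at the series edge take their single neighbor).  The two steps
    repeat until no short episode remains; the result has no unlabeled
    frames and no episode shorter than ``min_frames``.
    """
    lab = labels.labels.copy()
    if (lab == UNLABELED).all():
        raise ValueError("fully unlabeled input")
    for _ in range(lab.size):
        runs = episodes_from_labels(lab)
        short = [(s, e) for s, e, b in runs
                 if b != UNLABELED and e - s < min_frames]
        for s, e in short:
            lab[s:e] = UNLABELED
        gaps = [(s, e) for s, e, b in episodes_from_labels(lab) if b == UNLABELED]
        if not gaps and not short:
            break
        if (lab == UNLABELED).all():
            raise ValueError("post-processing removed all labels")
        for s, e in gaps:
            prev = lab[s - 1] if s > 0 else None
            nxt = lab[e] if e < lab.size else None
            if prev is None and nxt is None:
                continue
            if prev is None:
                lab[s:e] = nxt
            elif nxt is None:
                lab[s:e] = prev
            else:
                half = s + (e - s + 1) // 2   # odd gaps: extra frame to previous
                lab[s:half] = prev
                lab[half:e] = nxt
    return BehaviorLabels(lab, labels.frame_rate, labels.catalog)


def partition_agreement(a: ArchetypePartition, b: ArchetypePartition) -> float:
    """Pair-counting Rand index between two partitions of the same frames."""
    if not np.array_equal(a.frame_indices, b.frame_indices):
        raise ValueError("partitions cover different frame subsets")
    return float(rand_score(a.cluster_ids, b.cluster_ids))


@dataclass
class SegmentationResult:
    """Labels plus the intermediate products of the segmentation pipeline."""

    labels: BehaviorLabels
    consensus: ArchetypePartition
    merged: ArchetypePartition
    cluster_to_behavior: dict[int, int]
    frame_indices: np.ndarray
    mean_partition_agreement: float = np.nan
    diagnostics: dict = field(default_factory=dict)


def segment_session(
    features: FeatureSeries,
    catalog: BehaviorCatalog = DEFAULT_CATALOG,
    subsample_fraction: float = 0.25,
    n_embed_replicates: int = 10,
    n_gmm_replicates: int = 50,
    gmm_range: tuple[int, int] = (8, 30),
    max_embed_frames: int | None = 3000,
    perplexity: float = 30.0,
    wasserstein_cutoff: float = 1.0,
    consensus_cut: float = 0.5,
    min_cluster_frames: int = 20,
    min_episode_frames: int = 4,
    mapping: dict[int, int | str] | None = None,
    thresholds: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> SegmentationResult:
    """Run the full unsupervised behavior-identification pipeline."""
    rng = np.random.default_rng(seed)
    embeddings, idx = embed_features(
        features, subsample_fraction=subsample_fraction, n_replicates=n_embed_replicates,
        perplexity=perplexity, max_frames=max_embed_frames, seed=rng)
    partitions = cluster_embeddings(embeddings, idx,
                                    n_gmm_replicates=n_gmm_replicates,
                                    gmm_range=gmm_range, seed=rng)
    consensus = consensus_clusters(partitions, min_cluster_frames=min_cluster_frames,
                                   cut=consensus_cut)
    z, _, _ = standardize(features)
    merged = merge_clusters_wasserstein(consensus, z[idx], cutoff=wasserstein_cutoff)
    cmap = register_clusters(merged, features, catalog, mapping=mapping,
                             thresholds=thresholds)
    raw = assign_frames_max_likelihood(features, merged, cmap, catalog)
    labels = postprocess_labels(raw, min_frames=min_episode_frames)

    # agreement diagnostic over a few partition pairs
    n_pairs = min(50, len(partitions) * (len(partitions) - 1) // 2)
    pairs = list(combinations(range(len(partitions)), 2))
    sel = rng.choice(len(pairs), size=n_pairs, replace=False)
    agree = [partition_agreement(partitions[pairs[k][0]], partitions[pairs[k][1]])
             for k in sel]
    return SegmentationResult(
        labels=labels, consensus=consensus, merged=merged,
        cluster_to_behavior=cmap, frame_indices=idx,
        mean_partition_agreement=float(np.mean(agree)),
        diagnostics={"n_partitions": len(partitions)},
    )
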