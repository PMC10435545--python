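"""Consensus clustering, merging, registration, assignment, post-processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spncoding import synthetic as syn
from spncoding.catalog import BehaviorLabels, UNLABELED
from spncoding.features import FeatureSeries
from spncoding.segmentation import (
    ArchetypePartition,
    EmptyConsensusError,
    UnregisteredClusterError,
    assign_frames_max_likelihood,
    cluster_embeddings,
    consensus_clusters,
    embed_features,
    merge_clusters_wasserstein,
    partition_agreement,
    pca_dimension_criterion,
    postprocess_labels,
    register_clusters,
)


def test_pca_criterion_on_known_spectrum():
    rng = np.random.default_rng(0)
    # 3 equal strong directions (each ~1/3 of the variance, so 2 components
    # stay below 70%) + 3 negligible ones: criterion returns 3
    latent = rng.standard_normal((2000, 3)) * np.array([1.0, 1.0, 1.0])
    small = rng.standard_normal((2000, 3)) * 0.05
    x = np.concatenate([latent, small], axis=1)
    assert pca_dimension_criterion(x) == 3


def test_embed_and_cluster_partition_counts():
    rng = np.random.default_rng(1)
    blobs = np.concatenate([
        rng.normal(0, 0.3, (300, 6)),
        rng.normal(4, 0.3, (300, 6)),
    ])
    feats = FeatureSeries(blobs, 40.0)
    embs, idx = embed_features(feats, subsample_fraction=1.0, n_replicates=2,
                               perplexity=20, seed=2)
    assert len(embs) == 2 and embs[0].shape == (600, 3)
    parts = cluster_embeddings(embs, idx, n_gmm_replicates=3,
                               gmm_range=(2, 4), gmm_step=2, seed=3)
    assert len(parts) == 6  # embeddings x replicates


def test_consensus_of_identical_partitions_is_identity():
    idx = np.arange(100)
    ids = np.repeat([0, 1], 50)
    parts = [ArchetypePartition(idx, ids) for _ in range(5)]
    cons = consensus_clusters(parts, min_cluster_frames=5)
    assert partition_agreement(cons, parts[0]) == 1.0


def test_consensus_drops_small_clusters():
    idx = np.arange(100)
    ids = np.zeros(100, dtype=int)
    ids[:19] = 1                      # 19-frame cluster: below the 20 floor
    parts = [ArchetypePartition(idx, ids) for _ in range(4)]
    cons = consensus_clusters(parts, min_cluster_frames=20)
    assert (cons.cluster_ids[:19] == UNLABELED).all()
    assert (cons.cluster_ids[19:] != UNLABELED).all()


def test_consensus_recovers_blobs_under_label_noise():
    rng = np.random.default_rng(4)
    idx = np.arange(400)
    truth = np.repeat([0, 1], 200)
    parts = []
    for r in range(30):
        noisy = truth.copy()
        flip = rng.random(400) < 0.1
        noisy[flip] = 1 - noisy[flip]
        perm = rng.permutation(2)       # random cluster ids per partition
        parts.append(ArchetypePartition(idx, perm[noisy]))
    cons = consensus_clusters(parts, min_cluster_frames=20)
    assert partition_agreement(cons, ArchetypePartition(idx, truth)) >= 0.9


def test_consensus_invariant_to_cluster_id_permutation():
    rng = np.random.default_rng(5)
    idx = np.arange(200)
    truth = np.repeat([0, 1, 2, 3], 50)
    parts = [ArchetypePartition(idx, truth) for _ in range(4)]
    permuted = [ArchetypePartition(idx, rng.permutation(4)[truth])
                for _ in range(4)]
    c1 = consensus_clusters(parts, min_cluster_frames=5)
    c2 = consensus_clusters(permuted, min_cluster_frames=5)
    assert partition_agreement(c1, c2) == 1.0


def test_all_small_clusters_raise():
    idx = np.arange(30)
    ids = np.arange(30) // 10   # three 10-frame clusters
    parts = [ArchetypePartition(idx, ids)] * 3
    with pytest.raises(EmptyConsensusError):
        consensus_clusters(parts, min_cluster_frames=20)


def test_merge_identical_distributions_and_dirac_distance():
    idx = np.arange(300)
    ids = np.arange(300) // 100     # three clusters
    z = np.zeros((300, 6))
    z[100:200, 0] = 0.5             # cluster 1 offset by 0.5 on one feature
    z[200:, 0] = 5.0                # cluster 2 far away
    part = ArchetypePartition(idx, ids)
    merged = merge_clusters_wasserstein(part, z, cutoff=1.0)
    # clusters 0 and 1 (distance 0.5 < 1) merge; cluster 2 stays
    assert merged.n_clusters == 2
    a = merged.cluster_ids[0]
    assert (merged.cluster_ids[:200] == a).all()
    assert (merged.cluster_ids[200:] != a).all()


def test_merge_respects_cutoff_trace():
    # three clusters at pairwise Dirac distances 0.5, 2.0, 2.5: exactly one
    # merge happens and the remaining distance exceeds the cutoff
    idx = np.arange(150)
    ids = np.arange(150) // 50
    z = np.zeros((150, 6))
    z[50:100, 0] = 0.5
    z[100:, 0] = 2.5
    merged = merge_clusters_wasserstein(ArchetypePartition(idx, ids), z,
                                        cutoff=1.0)
    assert merged.n_clusters == 2


def test_register_clusters_rules_and_mapping_precedence(short_labels):
    feats = syn.generate_feature_series(short_labels, seed=1)
    # build a partition whose clusters are the true behaviors
    idx = np.arange(short_labels.n_frames)
    part = ArchetypePartition(idx, short_labels.labels.copy())
    cmap = register_clusters(part, feats)
    # rule-based registration recovers the identity mapping
    assert cmap == {b: b for b in range(12)}
    # explicit mapping overrides the rules
    cmap2 = register_clusters(part, feats, mapping={0: "grooming"})
    assert cmap2[0] == 8 and cmap2[1] == 1


def test_register_unmatched_cluster_raises():
    idx = np.arange(100)
    part = ArchetypePartition(idx, np.zeros(100, dtype=int))
    vals = np.tile([0.5, 2.0, 0.0, 5.5, 2.8, 1.0], (100, 1))  # still, hs 2
    feats = FeatureSeries(vals, 40.0)
    with pytest.raises(UnregisteredClusterError):
        register_clusters(part, feats)


def test_max_likelihood_assignment_recovers_held_out_frames(short_labels):
    feats = syn.generate_feature_series(short_labels, seed=2)
    half = short_labels.n_frames // 2
    part = ArchetypePartition(np.arange(half), short_labels.labels[:half].copy())
    cmap = {b: b for b in np.unique(short_labels.labels[:half])}
    labels = assign_frames_max_likelihood(feats, part, cmap)
    held = slice(half, None)
    agree = (labels.labels[held] == short_labels.labels[held]).mean()
    assert agree >= 0.95


def test_postprocess_short_episode_absorbed():
    lab = np.array([0] * 20 + [1] * 3 + [0] * 20)
    out = postprocess_labels(BehaviorLabels(lab, 40.0), min_frames=4)
    assert (out.labels == 0).all()


@pytest.mark.parametrize("gap,expect_prev", [(6, 3), (7, 4)])
def test_postprocess_gap_fill_split(gap, expect_prev):
    lab = np.array([0] * 20 + [UNLABELED] * gap + [1] * 20)
    out = postprocess_labels(BehaviorLabels(lab, 40.0), min_frames=4)
    assert (out.labels[:20 + expect_prev] == 0).all()
    assert (out.labels[20 + expect_prev:] == 1).all()


def test_postprocess_edge_gaps_take_single_neighbor():
    lab = np.array([UNLABELED] * 5 + [2] * 30 + [UNLABELED] * 5)
    out = postprocess_labels(BehaviorLabels(lab, 40.0))
    assert (out.labels == 2).all()


def test_postprocess_fully_unlabeled_raises():
    with pytest.raises(ValueError):
        postprocess_labels(BehaviorLabels(np.full(50, UNLABELED), 40.0))


@given(st.lists(st.integers(-1, 3), min_size=10, max_size=120))
@settings(deadline=None, max_examples=200)
def test_postprocess_closure_property(seq):
    lab = np.array(seq)
    if (lab != UNLABELED).sum() == 0:
        return
    try:
        out = postprocess_labels(BehaviorLabels(lab, 40.0), min_frames=4)
    except ValueError:
        # degenerate inputs whose episodes are all below the floor
        return
    assert (out.labels != UNLABELED).all()
    for s, e, b in out.episodes:
        assert e - s >= 4 or (s == 0 and e == out.n_frames)


def test_rand_index_closed_forms():
    idx = np.arange(3)
    a = ArchetypePartition(idx, np.array([0, 0, 1]))   # {12|3}
    b = ArchetypePartition(idx, np.array([0, 1, 1]))   # {1|23}
    assert partition_agreement(a, b) == pytest.approx(1 / 3)
    assert partition_agreement(a, a) == 1.0
    relab = ArchetypePartition(idx, np.array([5, 5, 2]))
    assert partition_agreement(a, relab) == 1.0
    with pytest.raises(ValueError):
        partition_agreement(a, ArchetypePartition(np.arange(1, 4),
                                                  np.array([0, 0, 1])))
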