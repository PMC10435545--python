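"""Activation similarity, time partitions, behavioral distance, coupling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wasserstein_distance

from spncoding import synthetic as syn
from spncoding.catalog import BehaviorLabels
from spncoding.features import FeatureSeries
from spncoding.raster import EventRaster
from spncoding.similarity import (
    activation_map,
    activation_similarity,
    behavioral_distance,
    dot_product_similarity,
    inverse_cv,
    neural_similarity_matrix,
    similarity_coupling,
    similarity_partitions,
    spatial_shuffle_similarity,
)


def test_similarity_scale_invariance_and_orthogonality():
    x = np.array([1.0, 2.0, 3.0])
    assert activation_similarity(x, 3 * x) == pytest.approx(0.0)
    assert activation_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) \
        == pytest.approx(-np.sqrt(2))
    assert activation_similarity(x, -x) == pytest.approx(-2.0)
    with pytest.raises(ValueError):
        activation_similarity(x, np.zeros(3))


def test_similarity_matches_direct_formula_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        direct = -np.linalg.norm(a / np.linalg.norm(a) - b / np.linalg.norm(b))
        assert activation_similarity(a, b) == pytest.approx(direct, abs=1e-12)
        assert dot_product_similarity(a, b) == pytest.approx(
            a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), abs=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=30)
def test_similarity_bounded_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 5, 20) + 1e-3
    b = rng.uniform(0, 5, 20) + 1e-3
    s = activation_similarity(a, b)
    assert -2.0 <= s <= 0.0
    assert s == pytest.approx(activation_similarity(b, a))
    assert activation_similarity(a, 2.5 * a) == pytest.approx(0.0, abs=1e-9)


def test_spatial_shuffle_constant_vector_invariant():
    x = np.full(30, 2.0)
    y = np.arange(1, 31, dtype=float)
    assert spatial_shuffle_similarity(y, x, seed=0) == pytest.approx(
        activation_similarity(y, x))
    # determinism
    r1 = spatial_shuffle_similarity(y, y, seed=5)
    assert r1 == spatial_shuffle_similarity(y, y, seed=5)


def test_spatial_shuffle_one_hot_orthogonality():
    rng = np.random.default_rng(1)
    n = 500
    x = np.zeros(n)
    x[rng.integers(n)] = 1.0
    y = np.zeros(n)
    y[rng.integers(n)] = 1.0
    s = spatial_shuffle_similarity(x, y, n_shuffles=200, seed=2)
    assert s == pytest.approx(-np.sqrt(2), abs=0.05)


def test_activation_map_occupancy_rule(small_session):
    labels, _, raster, _ = small_session
    m = activation_map(raster, labels, 0)
    assert m.valid
    # a 4-s window cannot contain 5 s of any behavior
    m2 = activation_map(raster, labels, 0, frame_window=(0, 80))
    assert not m2.valid


def test_five_min_partition_count():
    labels = syn.generate_behavior_sequence(duration_s=1800, seed=3)
    tuning = syn.make_tuning(30, seed=4)
    raster, _ = syn.generate_event_raster(labels, tuning, seed=5)
    out = similarity_partitions(raster, labels, "five_min_partitions")
    # C(6,3)/2 = 10 balanced unordered splits of six 5-min slices
    assert all(len(v) == 10 for v in out.values())


def test_odd_even_and_episode_partitions_reproducible(small_session):
    labels, _, raster, _ = small_session
    a = similarity_partitions(raster, labels, "odd_even_frames")
    b = similarity_partitions(raster, labels, "odd_even_frames")
    assert a == b
    eps = similarity_partitions(raster, labels, "alternating_episodes")
    assert set(eps) <= set(range(12))


def test_inverse_cv_monotone_in_episode_noise():
    labels = syn.generate_behavior_sequence(duration_s=900, seed=6)
    vals = []
    for sd in (0.2, 0.8, 2.0):
        tuning = syn.make_tuning(40, frac_active=1.0, frac_silent=0.0,
                                 episode_gain_sd=sd, baseline_rate=2.0, seed=7)
        raster, _ = syn.generate_event_raster(labels, tuning, seed=8)
        vals.append(inverse_cv(raster, labels, 0))
    assert vals[0] > vals[1] > vals[2]


def test_inverse_cv_requires_two_episodes():
    labels = BehaviorLabels(np.zeros(100, dtype=int), 20.0)
    raster = EventRaster(np.ones((3, 100)), rate=20.0)
    with pytest.raises(ValueError):
        inverse_cv(raster, labels, 0)


def test_behavioral_distance_identity_and_dirac():
    lab = BehaviorLabels(np.repeat([0, 1], 100), 40.0)
    vals = np.zeros((200, 6))
    vals[100:, 0] = 1.5   # behaviors differ by a Dirac shift on one feature
    feats = FeatureSeries(vals, 40.0)
    assert behavioral_distance(feats, lab, 0, 0) == 0.0
    assert behavioral_distance(feats, lab, 0, 1) == pytest.approx(1.5)


def test_behavioral_distance_gaussian_shift():
    rng = np.random.default_rng(9)
    n = 40000
    lab = BehaviorLabels(np.repeat([0, 1], n), 40.0)
    vals = rng.standard_normal((2 * n, 6))
    vals[n:] += 2.0     # each feature shifted by 2 -> distance ~ 12
    feats = FeatureSeries(vals, 40.0)
    d = behavioral_distance(feats, lab, 0, 1)
    assert d == pytest.approx(12.0, rel=0.05)


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=20)
def test_behavioral_distance_metric_properties(seed):
    rng = np.random.default_rng(seed)
    lab = BehaviorLabels(np.repeat([0, 1, 2], 60), 40.0)
    vals = rng.standard_normal((180, 6)) + rng.uniform(-2, 2, (3, 6)).repeat(60, 0)
    feats = FeatureSeries(vals, 40.0)
    d01 = behavioral_distance(feats, lab, 0, 1)
    d10 = behavioral_distance(feats, lab, 1, 0)
    d02 = behavioral_distance(feats, lab, 0, 2)
    d12 = behavioral_distance(feats, lab, 1, 2)
    assert d01 == pytest.approx(d10)            # symmetry
    assert d01 >= 0
    assert d02 <= d01 + d12 + 1e-9              # triangle inequality


def test_coupling_perfect_monotone_relation():
    # activation vectors placed on a great-circle arc so that the pairwise
    # neural similarity is an exactly monotone function of the behavioral
    # distance; g uses powers of two so all pairwise distances are distinct
    n_per = 400
    lab = BehaviorLabels(np.repeat(np.arange(12), n_per), 40.0)
    g = 2.0 ** np.arange(12)
    vals = np.zeros((12 * n_per, 6))
    vals[:, 0] = np.repeat(g, n_per)   # point-mass feature per behavior
    feats = FeatureSeries(vals, 40.0)
    theta = g / g.max() * (np.pi / 2)
    lab20 = lab.resample(20.0).labels
    events = np.zeros((2, lab20.size))
    events[0] = np.cos(theta[lab20])
    events[1] = np.sin(theta[lab20])
    raster = EventRaster(events, rate=20.0)
    ns, bs, rho, _ = similarity_coupling(raster, lab, feats)
    assert rho == pytest.approx(1.0, abs=1e-9)


def test_coupling_null_is_near_zero():
    # independent random neural and behavioral structure, equal occupancy so
    # no shared sampling-noise driver: coupling should be weak
    n_per = 200
    lab = BehaviorLabels(np.repeat(np.arange(12), n_per), 40.0)
    lab20 = lab.resample(20.0).labels
    rhos = []
    for s in range(8):
        rng = np.random.default_rng(100 + s)
        rates = rng.lognormal(0, 1, size=(30, 12))     # random activation maps
        raster = EventRaster(rates[:, lab20], rate=20.0)
        vals = rng.standard_normal((12, 6))[lab.labels]  # random point masses
        feats = FeatureSeries(vals, 40.0)
        _, _, rho, _ = similarity_coupling(raster, lab, feats)
        rhos.append(abs(rho))
    assert np.median(rhos) < 0.3
    assert np.mean(np.array(rhos) <= 0.3) >= 0.5


def test_neural_similarity_matrix_window_restriction(small_session):
    labels, _, raster, _ = small_session
    full = neural_similarity_matrix(raster, labels)
    short = neural_similarity_matrix(raster, labels, window_s=60.0)
    assert full.shape == short.shape == (12, 12)
    # shorter window -> fewer valid behaviors possible, never more
    assert np.isfinite(short).sum() <= np.isfinite(full).sum()
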