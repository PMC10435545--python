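"""Behavior information, shuffle classification, occurrence rules, stability."""

import numpy as np
import pytest

from spncoding import synthetic as syn
from spncoding.catalog import BehaviorLabels
from spncoding.classify import (
    activation_occurrence,
    behavior_information,
    classify_active_per_behavior,
    classify_behavior_active,
    classify_behavior_active_population,
    classify_behavior_inactive,
    classify_behavior_silent,
    classify_silent_by_shuffle,
    jaccard_stability,
    occurrence_table,
    registry_controls,
)
from spncoding.raster import EventRaster
from spncoding.registry import CellRegistry


def brute_force_bi(events: np.ndarray, lab: np.ndarray, rate: float) -> float:
    """Independent oracle: literal evaluation of the BI formula with
    per-behavior rates accumulated frame by frame."""
    behaviors = np.unique(lab)
    n = lab.size
    f = events.sum() / n * rate
    bi = 0.0
    for b in behaviors:
        frames = [t for t in range(n) if lab[t] == b]
        p = len(frames) / n
        f_b = sum(events[t] for t in frames) / len(frames) * rate
        if f_b > 0:
            bi += p * (f_b / f) * np.log2(f_b / f)
    return bi


def test_bi_constant_rate_is_zero():
    lab = np.repeat(np.arange(4), 50)
    events = np.ones(200)
    assert behavior_information(events, lab).bi == pytest.approx(0.0, abs=1e-12)


def test_bi_two_state_closed_form_is_one_bit():
    # p = (1/2, 1/2), rates (2f, 0): BI = 0.5 * 2 * log2(2) = 1 bit
    lab = np.repeat([0, 1], 100)
    events = np.zeros(200)
    events[:100] = 1.0
    assert behavior_information(events, lab).bi == pytest.approx(1.0, abs=1e-12)


def test_bi_matches_brute_force_oracle_on_random_cases():
    rng = np.random.default_rng(0)
    worst = 0.0
    for _ in range(100):
        nb = int(rng.integers(2, 13))
        n = int(rng.integers(50, 300))
        lab = rng.integers(0, nb, size=n)
        events = rng.poisson(rng.uniform(0.02, 0.6), size=n).astype(float)
        if events.sum() == 0 or np.unique(lab).size < 2:
            continue
        got = behavior_information(events, lab).bi
        want = brute_force_bi(events, lab, 20.0)
        worst = max(worst, abs(got - want))
    assert worst < 1e-10


def test_bi_undefined_for_silent_cell():
    info = behavior_information(np.zeros(100), np.repeat([0, 1], 50))
    assert not info.defined


def test_planted_active_cell_detected(small_session):
    labels, tuning, raster, _ = small_session
    i = int(np.flatnonzero(tuning.mask("active"))[0])
    is_active, info = classify_behavior_active(raster.events[i], labels,
                                               n_shuffles=300, seed=1)
    assert is_active and info.sigma_level > 4


def test_threshold_monotonicity(small_session):
    labels, tuning, raster, _ = small_session
    lo, _ = classify_behavior_active_population(raster, labels, n_shuffles=200,
                                                sigma_threshold=2, seed=3)
    hi, _ = classify_behavior_active_population(raster, labels, n_shuffles=200,
                                                sigma_threshold=6, seed=3)
    assert (hi <= lo).all()
    inf_t, _ = classify_behavior_active_population(raster, labels, n_shuffles=200,
                                                   sigma_threshold=np.inf, seed=3)
    assert not inf_t.any()


def test_per_behavior_flags_planted_cell(small_session):
    labels, tuning, raster, _ = small_session
    flags = classify_active_per_behavior(raster, labels, n_shuffles=300, seed=5)
    act = np.flatnonzero(tuning.mask("active"))
    hits = [flags[i, tuning.assigned[i]].any() for i in act]
    assert np.mean(hits) >= 0.8
    unt = np.flatnonzero(tuning.mask("untuned"))
    assert flags[unt].mean() <= 0.02


def test_activation_occurrence_counts():
    # 10 episodes of behavior 0, events in exactly one of them -> 0.1
    lab = np.tile(np.repeat([0, 1], 10), 10)
    labels = BehaviorLabels(lab, 20.0)
    events = np.zeros(lab.size)
    events[5] = 2.0
    occ = activation_occurrence(events, labels, 0, rate=20.0)
    assert occ == pytest.approx(0.1)
    assert activation_occurrence(np.zeros(lab.size), labels, 0) == 0.0
    assert activation_occurrence(np.ones(lab.size), labels, 0) == 1.0


def test_silent_threshold_is_strict():
    occ = np.array([0.0, 0.02, 0.025, 0.03, np.nan])
    flags = classify_behavior_silent(occ)
    assert flags.tolist() == [True, True, False, False, False]


def test_inactive_threshold_is_strict():
    n = 4000  # 200 s at 20 frames/s; both behaviors occupy >= 5 s
    lab = BehaviorLabels(np.repeat([0, 1], n // 2), 20.0)
    events = np.zeros((3, n))
    events[0, 0] = 1.0                          # 0.01 Hz in behavior 0
    # neuron 1: mean rate during behavior 0 exactly 0.1 events/s
    events[1, np.arange(0, n // 2, 200)] = 1.0  # 10 events per 100 s = 0.1 Hz
    events[2, : n // 2] = 1.0                   # 20 Hz
    raster = EventRaster(events, rate=20.0)
    flags = classify_behavior_inactive(raster, lab)
    assert flags[0, 0]           # below threshold
    assert not flags[1, 0]       # exactly 0.1 Hz: strict <
    assert not flags[2, 0]


def test_silent_by_shuffle_detects_planted(small_session):
    labels, tuning, raster, _ = small_session
    sil = np.flatnonzero(tuning.mask("silent"))[:5]
    hits = []
    for i in sil:
        b = int(tuning.assigned[i][0])
        hits.append(classify_silent_by_shuffle(raster.events[i], labels, b,
                                               n_shuffles=200, seed=int(i)))
    assert np.mean(hits) >= 0.8
    # all-zero cell flagged for any behavior
    assert classify_silent_by_shuffle(np.zeros(raster.n_frames), labels, 0,
                                      n_shuffles=50, seed=0)


def test_occurrence_table_shape(small_session):
    labels, _, raster, _ = small_session
    table = occurrence_table(raster, labels)
    assert table.shape == (raster.n_neurons, 12)
    finite = table[np.isfinite(table)]
    assert ((0 <= finite) & (finite <= 1)).all()


def test_jaccard_closed_forms():
    reg = CellRegistry(np.array([[0, 0], [1, 1], [2, 2]]))
    a = np.zeros((3, 4), dtype=bool)
    b = np.zeros((3, 4), dtype=bool)
    a[0, 0] = a[1, 1] = True          # attributes {a, b}
    b[1, 1] = b[2, 2] = True          # attributes {b, c}
    assert jaccard_stability(a, b, reg) == pytest.approx(1 / 3)
    assert jaccard_stability(a, a, reg) == 1.0
    b2 = np.zeros_like(b)
    b2[2, 3] = True
    assert jaccard_stability(a, b2, reg) == 0.0


def test_registry_controls_shuffle_and_neighbor():
    rng = np.random.default_rng(0)
    cents = rng.uniform(0, 100, (10, 2))
    reg = CellRegistry(np.stack([np.arange(10), np.arange(10)], axis=1),
                       cents, cents)
    shuf = registry_controls(reg, "shuffle_pairs", seed=1)
    assert not (shuf.pairs[:, 1] == reg.pairs[:, 1]).any()   # derangement
    shuf2 = registry_controls(reg, "shuffle_pairs", seed=1)
    assert np.array_equal(shuf.pairs, shuf2.pairs)           # deterministic
    nn = registry_controls(reg, "closest_neighbor", seed=0)
    assert not (nn.pairs[:, 1] == reg.pairs[:, 1]).any()
    # two cells only: closest neighbor swaps them
    reg2 = CellRegistry(np.array([[0, 0], [1, 1]]), cents[:2], cents[:2])
    nn2 = registry_controls(reg2, "closest_neighbor")
    assert nn2.pairs[:, 1].tolist() == [1, 0]


def test_control_registries_degrade_stability():
    tuning = syn.make_tuning(150, frac_active=0.3, frac_silent=0.3, seed=70)
    ra, rb, reg, gt = syn.generate_session_pair(tuning, overlap_fraction=0.6,
                                                duration_s=300, seed=71)
    la, lb = gt.labels, gt.extras["labels_b"]
    occ_a = occurrence_table(ra, la)
    occ_b = occurrence_table(rb, lb)
    fa, fb = classify_behavior_silent(occ_a), classify_behavior_silent(occ_b)
    true_j = jaccard_stability(fa, fb, reg)
    ctrl_j = jaccard_stability(fa, fb, registry_controls(reg, "shuffle_pairs",
                                                         seed=72))
    assert true_j > ctrl_j
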