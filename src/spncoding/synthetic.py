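"""Synthetic session generator with known ground truth.

The raw recordings this package analyzes (top-down pose videos and
microendoscopic calcium imaging of striatal projection neurons during free
open-field exploration) are not publicly deposited, so every downstream stage
is exercised against synthetic sessions with planted ground truth:

* a 12-behavior Markovian label sequence with geometric episode dwell times
  (40 frames/s);
* per-behavior Gaussian distributions of the six posture features;
* a pose track constructed to reproduce a given feature series when the
  posture features are recomputed from it (round-trip property);
* deconvolved event rasters (20 frames/s) containing planted
  *behavior-active*, *behavior-silent* and untuned cells, with multiplicative
  lognormal episode-to-episode gain variability;
* paired sessions with partial cell overlap and a registration map.

Default sizes emulate the study conditions: 300 neurons per session, 30-min
sessions, 10% planted active cells (rate gain 5 during their behavior), 10%
planted silent cells, baseline rate 0.5 events/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import BehaviorCatalog, BehaviorLabels, DEFAULT_CATALOG
from .features import FEATURE_NAMES, FeatureSeries
from .pose import BODY_PARTS, PoseTrack
from .raster import EventRaster
from .registry import CellRegistry

BEHAVIOR_FRAME_RATE = 40.0
IMAGING_FRAME_RATE = 20.0

# Neuron classes
ACTIVE, SILENT, UNTUNED = "active", "silent", "untuned"


# --------------------------------------------------------------------------
# Tuning specification and ground truth
# --------------------------------------------------------------------------
@dataclass
class TuningSpec:
    """Ground-truth tuning of a synthetic population.

    ``class_of[i]`` is "active", "silent" or "untuned"; ``assigned[i]`` lists
    the behavior ids the neuron is tuned to (empty for untuned cells).
    Active cells fire at ``baseline_rate * active_gain`` during assigned
    behaviors; silent cells fire at ``silent_rate`` (0 by default) during
    assigned behaviors; everywhere else every cell fires at ``baseline_rate``.
    A per-episode multiplicative lognormal gain (mean 1, sd
    ``episode_gain_sd``) models episode-to-episode ensemble variability.
    """

    class_of: np.ndarray                      # (n,) str
    assigned: list                            # list of int arrays
    baseline_rate: float = 0.5
    active_gain: float = 5.0
    silent_rate: float = 0.0
    episode_gain_sd: float = 0.5

    def __post_init__(self) -> None:
        self.class_of = np.asarray(self.class_of, dtype=object)
        if self.baseline_rate < 0 or self.silent_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.active_gain <= 1:
            raise ValueError("active_gain must be > 1")
        if self.episode_gain_sd < 0:
            raise ValueError("episode_gain_sd must be >= 0")
        if len(self.assigned) != self.n_neurons:
            raise ValueError("assigned must have one entry per neuron")

    @property
    def n_neurons(self) -> int:
        return int(self.class_of.size)

    def mask(self, cls: str) -> np.ndarray:
        return self.class_of == cls


def behavior_neighbor_order(params: "FeatureParams | None" = None) -> np.ndarray:
    """Behaviors sorted by ground-truth behavioral distance from each behavior.

    Row b lists all behaviors ordered by increasing distance from b, where the
    distance is the sum over features of 1-D Wasserstein distances between
    the generator's per-behavior Gaussians (computed by quantile averaging).
    """
    if params is None:
        params = default_feature_params()
    z = np.linspace(0.0005, 0.9995, 512)
    from scipy.stats import norm

    qz = norm.ppf(z)
    nb = params.n_behaviors
    dist = np.zeros((nb, nb))
    for i in range(nb):
        for j in range(i + 1, nb):
            d = 0.0
            for f in range(params.means.shape[1]):
                qi = params.means[i, f] + params.sds[i, f] * qz
                qj = params.means[j, f] + params.sds[j, f] * qz
                d += np.mean(np.abs(qi - qj))
            dist[i, j] = dist[j, i] = d
    return np.argsort(dist, axis=1)


def make_tuning(
    n_neurons: int = 300,
    frac_active: float = 0.1,
    frac_silent: float = 0.1,
    baseline_rate: float = 0.5,
    active_gain: float = 5.0,
    silent_rate: float = 0.0,
    episode_gain_sd: float = 0.5,
    n_assigned: int = 3,
    neighbor_assignment: bool = True,
    catalog: BehaviorCatalog = DEFAULT_CATALOG,
    seed: int | np.random.Generator = 0,
) -> TuningSpec:
    """Draw a random tuning specification with planted cell classes.

    Each tuned cell gets a uniformly drawn preferred behavior; with
    ``neighbor_assignment`` (default) its assigned set is the preferred
    behavior plus the ``n_assigned - 1`` behaviors closest to it in the
    generator's ground-truth feature space, so that behaviorally similar
    behaviors recruit overlapping ensembles (the substrate of the
    neural-behavioral similarity coupling).  With it off, assigned sets are
    uniform random subsets.
    """
    rng = np.random.default_rng(seed)
    n_active = int(round(frac_active * n_neurons))
    n_silent = int(round(frac_silent * n_neurons))
    if n_active + n_silent > n_neurons:
        raise ValueError("frac_active + frac_silent exceeds 1")
    class_of = np.array(
        [ACTIVE] * n_active + [SILENT] * n_silent
        + [UNTUNED] * (n_neurons - n_active - n_silent),
        dtype=object,
    )
    rng.shuffle(class_of)
    order = behavior_neighbor_order() if neighbor_assignment else None
    assigned = []
    for cls in class_of:
        if cls == UNTUNED:
            assigned.append(np.empty(0, dtype=np.int64))
        elif neighbor_assignment:
            pref = int(rng.integers(len(catalog)))
            assigned.append(np.sort(order[pref, :n_assigned]))
        else:
            assigned.append(np.sort(rng.choice(len(catalog), size=n_assigned,
                                               replace=False)))
    return TuningSpec(class_of, assigned, baseline_rate, active_gain,
                      silent_rate, episode_gain_sd)


def dspn_like_tuning(n_neurons: int = 300, seed=0, **kw) -> TuningSpec:
    """Preset emulating a direct-pathway population: activation-biased coding
    (more planted active cells) and low episode-to-episode variability."""
    kw.setdefault("frac_active", 0.18)
    kw.setdefault("frac_silent", 0.08)
    kw.setdefault("episode_gain_sd", 0.3)
    return make_tuning(n_neurons, seed=seed, **kw)


def ispn_like_tuning(n_neurons: int = 300, seed=0, **kw) -> TuningSpec:
    """Preset emulating an indirect-pathway population: silencing-biased
    coding (more planted silent cells) and high episode variability."""
    kw.setdefault("frac_active", 0.14)
    kw.setdefault("frac_silent", 0.18)
    kw.setdefault("episode_gain_sd", 1.0)
    return make_tuning(n_neurons, seed=seed, **kw)


@dataclass
class GroundTruth:
    """Everything the generators know that the analyses must recover."""

    labels: BehaviorLabels = None
    tuning: TuningSpec = None
    feature_params: "FeatureParams" = None
    registry: CellRegistry = None
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Behavior sequence
# --------------------------------------------------------------------------
def uniform_transition(n: int = 12) -> np.ndarray:
    """Uniform off-diagonal transition matrix (no self-transitions)."""
    t = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(t, 0.0)
    return t


def generate_behavior_sequence(
    catalog: BehaviorCatalog = DEFAULT_CATALOG,
    duration_s: float = 1800.0,
    transition: np.ndarray | None = None,
    dwell_mean_s: float | np.ndarray = 2.0,
    frame_rate: float = BEHAVIOR_FRAME_RATE,
    seed: int | np.random.Generator = 0,
) -> BehaviorLabels:
    """Markov chain of behavior episodes with geometric dwell times.

    At every frame the current behavior is left with hazard
    ``1 / (dwell_mean_s * frame_rate)``, giving geometric episode durations
    with the requested mean; the successor is drawn from the corresponding
    row of ``transition`` (uniform off-diagonal by default).
    """
    n = len(catalog)
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if transition is None:
        transition = uniform_transition(n)
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (n, n) or (transition < 0).any() or \
            not np.allclose(transition.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition must be a row-stochastic matrix")
    dwell = np.broadcast_to(np.asarray(dwell_mean_s, dtype=float), (n,))
    if (dwell < 0.1).any():
        raise ValueError("dwell_mean_s must be >= 0.1 s")
    n_frames = int(round(duration_s * frame_rate))
    if n_frames < 1:
        raise ValueError("duration too short to contain one episode")

    rng = np.random.default_rng(seed)
    hazard = 1.0 / (dwell * frame_rate)
    labels = np.empty(n_frames, dtype=np.int64)
    state = int(rng.integers(n))
    # draw geometric dwells episode by episode
    t = 0
    while t < n_frames:
        length = int(rng.geometric(min(hazard[state], 1.0)))
        end = min(t + length, n_frames)
        labels[t:end] = state
        t = end
        state = int(rng.choice(n, p=transition[state]))
    return BehaviorLabels(labels, frame_rate, catalog)


# --------------------------------------------------------------------------
# Feature distributions and feature series
# --------------------------------------------------------------------------
@dataclass
class FeatureParams:
    """Per-behavior mean and standard deviation of the six posture features."""

    means: np.ndarray   # (n_behaviors, 6)
    sds: np.ndarray     # (n_behaviors, 6)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.shape[1] != len(FEATURE_NAMES):
            raise ValueError("means and sds must be (n_behaviors, 6)")
        if (self.sds < 0).any():
            raise ValueError("sds must be >= 0")

    @property
    def n_behaviors(self) -> int:
        return int(self.means.shape[0])


#: Default per-behavior feature means.  Units: cm/s, cm/s, rad, cm, cm, cm,
#: in the FEATURE_NAMES order (body speed, head speed, movement angle,
#: body length, neck elongation, head elevation).  Head speeds of turning
#: behaviors are large because the camera offset swings around the body
#: center while the animal turns.
DEFAULT_FEATURE_MEANS = np.array([
    # bs     hs    angle   bl    ne    he
    [22.0,  2.5,  0.00,   6.0,  3.0,  1.0],   # locomotion_fast
    [ 9.0,  2.5,  0.00,   6.0,  3.0,  1.0],   # locomotion_straight
    [ 7.0, 10.0,  0.12,   6.0,  3.0,  1.0],   # locomotion_turn_right
    [ 7.0, 10.0, -0.12,   6.0,  3.0,  1.0],   # locomotion_turn_left
    [ 0.8,  9.5,  0.12,   5.5,  2.8,  1.0],   # still_turn_right
    [ 0.8,  9.5, -0.12,   5.5,  2.8,  1.0],   # still_turn_left
    [ 0.8,  2.0,  0.00,   5.5,  1.6,  3.5],   # head_up
    [ 0.8,  2.0,  0.00,   3.5,  1.6,  3.5],   # rearing
    [ 0.8,  8.0,  0.00,   3.8,  2.2,  0.8],   # grooming
    [ 6.0,  2.5,  0.00,   7.5,  4.2,  0.8],   # locomotion_sniffing
    [ 0.8,  1.5,  0.00,   7.5,  4.2,  0.8],   # still_sniffing
    [ 0.3,  0.3,  0.00,   5.5,  2.8,  1.0],   # immobility
])

DEFAULT_FEATURE_SDS = np.array([
    [ 2.0,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 1.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 1.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 1.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 0.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 0.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 0.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 0.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 0.2,  0.6,  0.25,   0.25, 0.20, 0.25],  # grooming: large angle variation
    [ 1.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 0.2,  0.6,  0.03,   0.25, 0.20, 0.25],
    [ 0.1,  0.1,  0.03,   0.25, 0.20, 0.25],
])


def default_feature_params() -> FeatureParams:
    return FeatureParams(DEFAULT_FEATURE_MEANS.copy(), DEFAULT_FEATURE_SDS.copy())


def generate_feature_series(
    labels: BehaviorLabels,
    feature_params: FeatureParams | None = None,
    noise_scale: float = 1.0,
    noise_smoothing_frames: int = 20,
    seed: int | np.random.Generator = 0,
) -> FeatureSeries:
    """Draw per-frame feature vectors from the per-behavior distributions.

    ``noise_scale`` multiplies the per-behavior standard deviations (0 gives
    point-mass features at the behavior means).  The noise is temporally
    smoothed over ``noise_smoothing_frames`` (rescaled to keep the marginal
    per-frame standard deviation), emulating the temporal smoothing that
    posture features undergo before analysis; set it to 1 for white noise.
    """
    if feature_params is None:
        feature_params = default_feature_params()
    if feature_params.n_behaviors < len(labels.catalog):
        raise ValueError("feature_params missing behaviors present in the catalog")
    rng = np.random.default_rng(seed)
    lab = labels.labels
    if (lab < 0).any():
        raise ValueError("labels must be fully labeled")
    noise = rng.standard_normal((lab.size, len(FEATURE_NAMES)))
    w = int(noise_smoothing_frames)
    if w > 1:
        kernel = np.ones(w) / np.sqrt(w)   # unit marginal variance after MA
        for j in range(noise.shape[1]):
            noise[:, j] = np.convolve(noise[:, j], kernel, mode="same")
    vals = feature_params.means[lab] + noise_scale * feature_params.sds[lab] * noise
    # head speed is a vector norm, hence nonnegative
    np.clip(vals[:, 1], 0.0, None, out=vals[:, 1])
    return FeatureSeries(vals, labels.frame_rate)


# --------------------------------------------------------------------------
# Pose-track construction (inverse of compute_features)
# --------------------------------------------------------------------------
def generate_pose_track(
    features: FeatureSeries,
    seed: int | np.random.Generator = 0,
    low_likelihood_fraction: float = 0.05,
    start_xy: tuple[float, float] = (20.0, 20.0),
    min_speed: float = 0.05,
    wiggle_bound: float = 0.6,
) -> PoseTrack:
    """Construct body-part coordinates whose derived features reproduce ``features``.

    The body center integrates the body-speed feature along a heading that
    accumulates half the movement angle per frame; neck, tail and camera are
    placed along the body axis at the distances dictated by neck elongation,
    body length and head elevation.  The camera additionally carries a
    bounded lateral offset whose per-frame step is solved so the recomputed
    head speed matches the head-speed feature (clamped when the requested
    head speed is kinematically infeasible, e.g. lower than the rotational
    swing of the head during sustained turns).

    Likelihood is 1 everywhere except a ``low_likelihood_fraction`` of frames
    in which one random body part gets a likelihood drawn below 0.9.

    Round-trip fidelity (``compute_features(generate_pose_track(f))`` vs
    ``f``) is exact for body length and neck elongation and approximate for
    the velocity-based features; see the package methods note for the
    documented tolerances.
    """
    vals = features.values
    if not np.isfinite(vals).all():
        raise ValueError("features must be finite")
    bs, hs, ang, bl, ne, he = (vals[:, i].copy() for i in range(6))
    if (ne <= 0).any() or (bl - ne <= 0).any():
        raise ValueError("infeasible features: lengths must be positive")
    if (hs < 0).any():
        raise ValueError("infeasible features: head speed must be >= 0")
    n = vals.shape[0]
    fps = features.frame_rate
    rng = np.random.default_rng(seed)

    # speeds below min_speed are clipped so the heading stays defined
    bs = np.where(np.abs(bs) < min_speed, min_speed * np.sign(bs + 1e-12), bs)
    bs = np.where(bs == 0, min_speed, bs)

    # heading: the recomputed movement angle at frame t is theta[t+1] -
    # theta[t-1].  The exact two-chain recursion is numerically unstable (its
    # even and odd subchains drift apart), so the per-frame turn increment is
    # the stable smoothed form delta_t = (m_t + m_{t+1})/4, which satisfies
    # delta_t + delta_{t-1} = m_t up to the second difference of the angle
    # noise (episode-mean angles are reproduced exactly).
    delta = np.zeros(n)
    if n > 1:
        delta[:-1] = (ang[:-1] + ang[1:]) / 4.0
    theta = np.concatenate([[0.0], np.cumsum(delta[:-1])])

    u = np.stack([np.cos(theta), np.sin(theta)], axis=1)      # body axis
    nvec = np.stack([-np.sin(theta), np.cos(theta)], axis=1)  # lateral axis

    # body-center trajectory
    steps = (bs / fps)[:, None] * u
    bc = np.concatenate([[start_xy], start_xy + np.cumsum(steps[:-1], axis=0)])

    neck = bc + ne[:, None] * u
    tail_start = bc - (bl - ne)[:, None] * u
    tail_end = tail_start - 3.0 * u
    nose = neck + 1.2 * u

    # camera: radial offset he along the body axis from the neck, plus a
    # bounded lateral wiggle solved to realize the head-speed feature
    a = np.zeros(n)
    sgn = 1.0
    radial = (ne + he)[:, None] * u   # camera offset from body center, minus wiggle
    for t in range(1, n):
        q = (radial[t] - radial[t - 1]) * fps       # passive offset velocity
        q_u = float(q @ u[t])
        q_n = float(q @ nvec[t])
        resid = hs[t] ** 2 - q_u ** 2
        if resid <= 0:
            da = -q_n                                # infeasible: cancel lateral
        else:
            root = np.sqrt(resid)
            # keep the wiggle direction persistent (hysteresis) so the
            # central-difference velocity recovers the requested speed;
            # flip direction only at the amplitude bound
            da = -q_n + sgn * root
            if abs(a[t - 1] + da / fps) > wiggle_bound:
                alt = -q_n - sgn * root
                if abs(a[t - 1] + alt / fps) <= wiggle_bound:
                    sgn = -sgn
                    da = alt
        a[t] = np.clip(a[t - 1] + da / fps, -wiggle_bound, wiggle_bound)
    camera = neck + he[:, None] * u + a[:, None] * nvec

    # ears straddle the camera, perpendicular to the body axis
    left_ear = camera - 0.6 * nvec
    right_ear = camera + 0.6 * nvec

    coords = {
        "nose": nose, "neck": neck, "left_ear": left_ear, "right_ear": right_ear,
        "camera": camera, "body_center": bc, "tail_start": tail_start,
        "tail_end": tail_end,
    }
    x = np.stack([coords[p][:, 0] for p in BODY_PARTS])
    y = np.stack([coords[p][:, 1] for p in BODY_PARTS])
    likelihood = np.ones_like(x)

    if not 0.0 <= low_likelihood_fraction <= 1.0:
        raise ValueError("low_likelihood_fraction must lie in [0, 1]")
    n_low = int(round(low_likelihood_fraction * n))
    if n_low:
        frames = rng.choice(n, size=n_low, replace=False)
        parts = rng.integers(len(BODY_PARTS), size=n_low)
        likelihood[parts, frames] = rng.uniform(0.3, 0.89, size=n_low)
    return PoseTrack(x, y, likelihood, frame_rate=fps)


# --------------------------------------------------------------------------
# Event rasters
# --------------------------------------------------------------------------
def _rate_matrix(tuning: TuningSpec, n_behaviors: int) -> np.ndarray:
    """Per-neuron, per-behavior event rate (events/s)."""
    rates = np.full((tuning.n_neurons, n_behaviors), tuning.baseline_rate)
    for i in range(tuning.n_neurons):
        if tuning.class_of[i] == ACTIVE:
            rates[i, tuning.assigned[i]] = tuning.baseline_rate * tuning.active_gain
        elif tuning.class_of[i] == SILENT:
            rates[i, tuning.assigned[i]] = tuning.silent_rate
    return rates


def generate_event_raster(
    labels: BehaviorLabels,
    tuning: TuningSpec,
    imaging_rate: float = IMAGING_FRAME_RATE,
    seed: int | np.random.Generator = 0,
    pathway: str | None = None,
) -> tuple[EventRaster, GroundTruth]:
    """Inhomogeneous-Poisson event raster with planted tuning.

    Behavior labels (40 frames/s) are aligned to the imaging rate by nearest-
    frame decimation; each neuron then emits Poisson counts per imaging frame
    at its class- and behavior-dependent rate, multiplied by a per-episode
    lognormal gain (mean 1, sd ``tuning.episode_gain_sd``).  Planted silent
    cells emit exactly zero events during their assigned behaviors.
    """
    rng = np.random.default_rng(seed)
    aligned = labels.resample(imaging_rate)
    lab = aligned.labels
    n_frames = lab.size
    n_behaviors = len(labels.catalog)
    rates = _rate_matrix(tuning, n_behaviors)          # (n, B)
    lam = rates[:, lab] / imaging_rate                  # (n, frames)

    # episode-to-episode variability of the planted tuned responses: a
    # lognormal (mean 1) gain per (tuned neuron, episode).  Untuned cells
    # stay homogeneous Poisson, so their behavior information is calibrated
    # against the event-permutation null.
    tuned = np.flatnonzero(tuning.class_of != UNTUNED)
    if tuning.episode_gain_sd > 0 and tuned.size:
        s = np.sqrt(np.log1p(tuning.episode_gain_sd ** 2))
        eps = aligned.episodes
        gains = rng.lognormal(mean=-s * s / 2.0, sigma=s,
                              size=(tuned.size, len(eps)))
        gain_frames = np.ones((tuned.size, n_frames))
        for k, (a, b, _) in enumerate(eps):
            gain_frames[:, a:b] = gains[:, [k]]
        lam[tuned] = lam[tuned] * gain_frames

    events = rng.poisson(lam).astype(float)
    raster = EventRaster(events, rate=imaging_rate, pathway=pathway)
    gt = GroundTruth(labels=labels, tuning=tuning)
    return raster, gt


def generate_session_pair(
    tuning: TuningSpec,
    overlap_fraction: float = 0.34,
    remap_fraction: float = 0.0,
    duration_s: float = 1800.0,
    seed: int | np.random.Generator = 0,
    catalog: BehaviorCatalog = DEFAULT_CATALOG,
    fov_size: float = 400.0,
) -> tuple[EventRaster, EventRaster, CellRegistry, GroundTruth]:
    """Two sessions sharing a fraction of cells, with a registration map.

    ``round(overlap_fraction * n_neurons)`` cells appear in both sessions;
    shared cells keep their class and behavior assignment in session B except
    a ``remap_fraction`` of them whose tuning is independently redrawn.
    Centroids (uniform over a square field of view; registered cells jittered
    by ~2 units between sessions) support closest-neighbor controls.
    """
    if not (0.0 <= overlap_fraction <= 1.0 and 0.0 <= remap_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = tuning.n_neurons
    n_shared = int(round(overlap_fraction * n))
    if n_shared < 2:
        raise ValueError("overlap yields fewer than 2 shared cells")

    # session B tuning: shared cells copy session A, a remap_fraction redrawn
    shared_a = rng.choice(n, size=n_shared, replace=False)
    order = rng.permutation(n)      # position of each B cell
    class_b2 = np.empty(n, dtype=object)
    assigned_b2: list = [None] * n
    shared_b = order[:n_shared]
    for k, ia in enumerate(shared_a):
        ib = shared_b[k]
        class_b2[ib] = tuning.class_of[ia]
        assigned_b2[ib] = tuning.assigned[ia].copy()
    # non-shared B cells reuse the class/assignment pool of a random A cell
    pool = rng.permutation(n)
    for j, ib in enumerate(order[n_shared:]):
        src = pool[j]
        class_b2[ib] = tuning.class_of[src]
        assigned_b2[ib] = tuning.assigned[src].copy()
    n_remap = int(round(remap_fraction * n_shared))
    remap_idx = rng.choice(n_shared, size=n_remap, replace=False)
    n_behaviors = len(catalog)
    for k in remap_idx:
        ib = shared_b[k]
        if class_b2[ib] != UNTUNED:
            size = max(len(assigned_b2[ib]), 1)
            assigned_b2[ib] = np.sort(rng.choice(n_behaviors, size=size,
                                                 replace=False))
    tuning_b = TuningSpec(class_b2, assigned_b2, tuning.baseline_rate,
                          tuning.active_gain, tuning.silent_rate,
                          tuning.episode_gain_sd)

    labels_a = generate_behavior_sequence(catalog, duration_s, seed=rng)
    labels_b = generate_behavior_sequence(catalog, duration_s, seed=rng)
    raster_a, _ = generate_event_raster(labels_a, tuning, seed=rng)
    raster_b, _ = generate_event_raster(labels_b, tuning_b, seed=rng)

    cent_a = rng.uniform(0, fov_size, size=(n, 2))
    cent_b = rng.uniform(0, fov_size, size=(n, 2))
    cent_b[shared_b] = cent_a[shared_a] + rng.normal(0, 2.0, size=(n_shared, 2))
    registry = CellRegistry(np.stack([shared_a, shared_b], axis=1), cent_a, cent_b)
    gt = GroundTruth(labels=labels_a, tuning=tuning, registry=registry,
                     extras={"labels_b": labels_b, "tuning_b": tuning_b,
                             "remapped_shared_idx": remap_idx})
    return raster_a, raster_b, registry, gt


def scramble_tuning(
    raster: EventRaster,
    labels: BehaviorLabels | None = None,
    seed: int | np.random.Generator = 0,
    shifts: np.ndarray | None = None,
) -> EventRaster:
    """Destroy behavior locking by a per-neuron circular time shift.

    Each neuron's event train is rolled by an independent random offset,
    which preserves its total event count and autocorrelation while breaking
    the relation to the behavior labels (emulating a pharmacological
    perturbation that decouples activity from behavior).  Explicit ``shifts``
    (one per neuron) may be supplied instead of random ones.
    """
    rng = np.random.default_rng(seed)
    n, f = raster.events.shape
    if shifts is None:
        shifts = rng.integers(0, f, size=n)
    shifts = np.asarray(shifts, dtype=np.int64)
    out = np.empty_like(raster.events)
    for i in range(n):
        out[i] = np.roll(raster.events[i], int(shifts[i]))
    return EventRaster(out, raster.rate, raster.pathway, raster.session_id)
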