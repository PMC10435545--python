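# spncoding

Analyses of how striatal projection neuron (SPN) populations encode
spontaneous mouse behavior: unsupervised behavior segmentation from pose
tracking, behavior-tuning statistics for calcium event rasters, population
activation-similarity metrics, SVM behavior decoding with a behavioral-
distance error, and longitudinal (cross-session) stability — plus a
synthetic-session generator with planted ground truth so the whole chain is
testable without raw recordings.

It is written for systems-neuroscience users who have (a) DeepLabCut-style
pose CSVs of a top-down open-field recording (40 frames/s) and (b)
deconvolved calcium event rasters (neurons × frames, 20 frames/s) from
microendoscopic imaging of direct- (dSPN) or indirect-pathway (iSPN)
neurons, optionally with a CellReg-style cross-session registration map.

## The core statistics

* **Behavior segmentation.** Six posture features (body speed, head speed,
  movement angle, body length, neck elongation, head elevation) are computed
  per frame, embedded by t-SNE (10 replicates), clustered by Gaussian
  mixtures (50 restarts each → 500 partitions), reduced to a consensus by
  Hamming-distance agglomeration, merged by the summed per-feature
  Wasserstein distance up to a cutoff of 1, registered to a fixed
  12-behavior catalog, and extended to every frame by maximum likelihood;
  episodes under 100 ms are removed.
* **Activation similarity.** For a behavior with population activation maps
  X₁, X₂ in two time windows, similarity = −‖X₁/‖X₁‖ − X₂/‖X₂‖‖ ∈ [−2, 0].
* **Behavior information.** BI = Σᵢ pᵢ (fᵢ/f) log₂(fᵢ/f) bits/event, tested
  against 1000 event shuffles; cells above 4σ are *behavior-active*.
  Cells emitting events in < 2.5% of a behavior's episodes are
  *behavior-silent* (< 0.1 Hz: *behavior-inactive*).
* **Decoding.** 66 one-vs-one linear SVMs (80/20 split, 5-fold CV) on
  500-ms-boxcar-convolved activity; chance level from decoders retrained on
  time-reversed, randomly lagged labels (10 lags); errors weighted by the
  behavioral (Wasserstein) distance between predicted and observed behavior.
* **Stability.** Jaccard index of cell classifications across registered
  sessions, against shuffled-pair and closest-neighbor registration
  controls.

## Worked example

```python
import numpy as np
from spncoding import synthetic as syn
from spncoding.classify import (classify_behavior_active_population,
                                classify_behavior_silent, occurrence_table)
from spncoding.similarity import (similarity_partitions, similarity_coupling,
                                  behavioral_distance_matrix)
from spncoding.decoding import decode_session

labels = syn.generate_behavior_sequence(duration_s=600, seed=0)
tuning = syn.dspn_like_tuning(n_neurons=120, seed=0)
raster, truth = syn.generate_event_raster(labels, tuning, seed=0, pathway="dSPN")
feats = syn.generate_feature_series(labels, seed=0)

active, infos = classify_behavior_active_population(raster, labels, seed=0)
silent = classify_behavior_silent(occurrence_table(raster, labels))
print(f"behavior-active cells: {active.sum()}/{raster.n_neurons}")
print(f"cells silent for >=1 behavior: {silent.any(axis=1).sum()}")

halves = similarity_partitions(raster, labels, "halves")
print(f"mean split-half activation similarity: "
      f"{np.mean([v[0] for v in halves.values()]):.3f}")
_, _, rho, p = similarity_coupling(raster, labels, feats)
print(f"neural-behavioral coupling: Spearman rho = {rho:.2f} (p = {p:.1e})")

D = behavioral_distance_matrix(feats, labels)
model, report = decode_session(raster, labels, distances=D, seed=0)
print(f"decoding accuracy: {report.accuracy:.3f}; "
      f"reconstruction error: {report.reconstruction_error:.2f}")
```

Output:

```
behavior-active cells: 33/120
cells silent for >=1 behavior: 10
mean split-half activation similarity: -0.340
neural-behavioral coupling: Spearman rho = 0.24 (p = 5.5e-02)
decoding accuracy: 0.504; reconstruction error: 4.82
```

The 10-minute synthetic dSPN-like session plants 18% behavior-active cells
(most of the 33 detected, at a strict 4σ criterion, are planted tuned
cells), its split-half similarity of −0.34 is far above the ≈ −√2 chance
level of shuffled maps, the positive Spearman ρ reflects that behaviorally
similar behaviors recruit overlapping ensembles, and a decoding accuracy of
0.50 over 12 classes is ≈ 6× the time-lagged chance level (~0.09).

A thin CLI mirrors the main analyses:
`spncoding simulate|segment|similarity|classify|decode --help`.

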