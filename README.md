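# mpspec

Automated Raman / FTIR spectral analysis for microplastic identification:
preprocessing, artifact removal, classification, out-of-distribution
filtering and substrate masking for spectral images — with a synthetic-data
generator that makes every stage testable end to end against ground truth.

## Who this is for

Environmental analytical chemists identifying microplastic particles from
vibrational spectra face a chain of practical obstacles before any library
match or classifier can be trusted: fluorescence baselines swamp Raman
bands, cosmic-ray spikes masquerade as sharp peaks, atmospheric CO₂ imprints
a doublet on FTIR absorbance, spectral libraries are class-imbalanced, and a
classifier trained on a finite polymer library will confidently mislabel
anything it has never seen. `mpspec` implements the full chain as a library
plus a small CLI, sized so every component trains and evaluates in seconds
on one CPU.

## What is inside

* **Preprocessing** (`mpspec.preprocessing`) — linear resampling to a fixed
  1000-point grid (Raman 200–3200 cm⁻¹, FTIR 400–4000 cm⁻¹) with class-mean
  padding of uncovered regions; iterative asymmetric penalized least-squares
  (i-arPLS) baseline estimation, minimizing
  `Σᵢ wᵢ (yᵢ − zᵢ)² + λ‖Δ²z‖²` with asymmetric logistic weights refreshed
  each iteration from the negative-residual distribution and an adaptive
  convergence ratio `‖w_new − w‖/‖w‖ < tol`; maximum-intensity
  normalization; Savitzky–Golay smoothing. Pipeline order is a contract:
  resample → baseline → artifact removal → normalize → smooth, so an
  artifact can never become the normalization maximum.
* **Artifact removal** (`mpspec.artifacts`) — hybrid cosmic-ray rejection:
  a rule-based stage (band sharpness ≥ 1.0, derivative score ≥ 0.2, robust
  z-gate 25.0, sub-grid width < 1.5 cm⁻¹) plus a gradient-boosting stage for
  the candidates the rules leave behind, with shape-preserving PCHIP
  correction of confirmed rays; and sigmoid-weighted excision of the CO₂
  doublet at 2288/2392 cm⁻¹ (edge buffer 30 points, extended flank factor
  2.0, 12 baseline samples, smoothing factor 0.98) that leaves adjacent
  genuine bands — e.g. the ABS nitrile stretch near 2240–2260 cm⁻¹ —
  untouched.
* **Augmentation** (`mpspec.augmentation`) — minimum-seed routing (classes
  with < 50 originals fall back to correlation matching), expansion to a
  fixed per-class target by baseline-resampling (i-arPLS-family)
  augmentation, SMOTE-style convex interpolation, or jittered resampling.
* **Classification** (`mpspec.classification`) — Pearson-correlation (PCC)
  library matching, and a compact 1-D residual network with parallel
  multiscale kernels and squeeze-and-excitation gating, trained as a
  stratified k-fold ensemble whose softmax is the mean of fold softmaxes.
  The network is implemented in NumPy with explicit backpropagation
  (`mpspec.nn`) and verified by numerical gradient checks.
* **OOD filtering** (`mpspec.ood`) — three tiers: PCC screening against a
  non-polymer library; a random forest over ensemble uncertainty features
  (predictive entropy, Mahalanobis distance in the penultimate embedding space,
  fold disagreement, top-2 margin) thresholded into Accept/Verify/Reject
  (Raman τ = 0.10/0.90, FTIR τ = 0.45/0.70); and a disambiguation stage for
  confusable predictions (PE vs fatty-acid slip additives and their graded
  mixtures).
* **Image masking** (`mpspec.imaging`) — a semisupervised ensemble (random
  forest on PCA scores + engineered pixel statistics, fused with
  PCA-informed K-means by weighted confidence scoring) that labels substrate
  pixels so only particle spectra are classified.
* **Synthetic data** (`mpspec.synth`) — ground-truthed generators for
  polymer-like classes, fluorescence baselines, cosmic rays (FWHM
  0.31–1.15 cm⁻¹, amplitude 5.7–19.5× local background), CO₂ doublets
  (intensities 0.20–0.90 and 0.15–0.71), and substrate/particle images.

## Worked example

Train the gradient-boosting ray stage on generator scenarios, then run the
hybrid pipeline on a PVC-like Raman spectrum carrying 20 injected cosmic
rays:

```python
import numpy as np
from mpspec.artifacts import build_ray_training_set, train_ray_classifier, remove_rays_hybrid
from mpspec.synth import RAMAN_PRESETS, generate_ray_scenario

specs = list(RAMAN_PRESETS.values())
features, labels = build_ray_training_set(specs, n_scenarios_per_class=4, seed=7)
classifier = train_ray_classifier(features, labels, model="gb", seed=0)
print(f"GB ray classifier: weighted F1 = {classifier.cv_metrics['weighted_f1']:.3f} (5-fold CV)")

spectrum, truth = generate_ray_scenario(RAMAN_PRESETS["PVC"], n_rays=20, seed=36000)
cleaned, detections = remove_rays_hybrid(spectrum, classifier)
hits = sum(1 for c in truth.positions
           if any(abs(d.center_wavenumber - c) <= 2.0 for d in detections))
by_stage = {s: sum(d.stage == s for d in detections) for s in ("rule", "ml")}
print(f"detected {hits}/20 injected rays ({by_stage['rule']} rule-based, {by_stage['ml']} ML)")
residual = np.abs(cleaned.intensities - truth.clean).max()
print(f"max residual after PCHIP correction: {residual:.3f} (spectrum max 1.0)")
```

which prints:

```
GB ray classifier: weighted F1 = 1.000 (5-fold CV)
detected 20/20 injected rays (17 rule-based, 3 ML)
max residual after PCHIP correction: 0.115 (spectrum max 1.0)
```

All 20 rays are found; most clear the rule-based criteria and the
gradient-boosting stage recovers the rest. The residual is measured
against the pre-injection ground truth the generator retains (the worst
point here is a ray that landed on a genuine band flank, where exact
restoration is limited by the 3 cm⁻¹ grid).

The same workflows are available from the shell:

```bash
mpspec simulate --preset pvc-raman --n 1 --seed 3 --out-dir sim/
mpspec preprocess sim/pvc_raman_0.txt --modality raman --out clean.txt
mpspec classify clean.txt --library-dir library/ --out predictions.csv
```

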