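# Methods

This note documents the models and numerical choices behind `mpspec`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely open.

## Canonical representation

Both modalities are resampled by linear interpolation onto fixed 1000-point
grids: Raman 200–3200 cm⁻¹ (step ≈ 3.003 cm⁻¹) and FTIR 400–4000 cm⁻¹
(step ≈ 3.604 cm⁻¹). Axes are stored ascending for both modalities — FTIR
instruments print 4000 → 400 cm⁻¹, and readers flip such input (recording
the flip in metadata) so a single interpolation and peak-finding code path
serves everything. Grid regions a spectrum does not cover are filled from
the class-mean vector when the class is known, otherwise from the
spectrum's own mean with a logged warning; filled intervals are recorded in
`padded_regions` so downstream consumers can ignore them. Interpolation is
exact at grid knots, so an input already on the grid passes through
bit-identically.

## Baseline correction (i-arPLS)

The baseline `z` minimizes `Σᵢ wᵢ(yᵢ − zᵢ)² + λ‖Δ²z‖²` where `Δ²` is the
second-difference operator. Each iteration re-derives the weights from the
residual distribution: with `d = y − z` and `m, s` the mean and standard
deviation of the negative residuals, `w = logistic(−2(d − (2s − m))/s)` —
points far above the baseline (bands, spikes) get asymptotically zero
weight, points at or below it weight ≈ 1. Iteration stops when the adaptive
convergence ratio `‖w_new − w‖ / ‖w‖` falls below `tol` (default 1e-3), or
immediately when the residual is zero to numerical precision (flat input);
hitting `max_iter` (default 50) flags `converged=False` but never raises.
The banded system is solved with a sparse LU factorization (the matrix is
pentadiagonal; ~1 ms per solve at n = 1000).

Defaults: λ = 1e5 (Raman) and 1e6 (FTIR), both configurable. The stiffer
FTIR penalty reflects that ATR drift and scattering slopes are smoother than
fluorescence humps. On the synthetic suite these defaults recover linear
and broad-Gaussian (σ ≈ 500 cm⁻¹) baselines with RMSE below 0.5% of the
baseline range, preserve peak heights within 5%, never shift peak positions
by more than one grid point, and are idempotent to better than 1% of range.
Corrected spectra are not clipped to non-negative values: slight overshoot
is a property of all penalized-least-squares baselines and clipping would
bias subsequent statistics.

## Cosmic-ray removal

Cosmic rays are single-detector-hit spikes: 0.31–1.15 cm⁻¹ FWHM — narrower
than one grid step. Two consequences drive the design:

1. **Apparent widths are resolution-limited.** A half-maximum crossing
   width can never fall below ~one grid step, so the sub-grid `fwhm`
   feature is estimated by a log-parabola through the candidate and its two
   neighbours (on-grid samples of a Gaussian are themselves Gaussian, so
   the fit is exact in the noiseless case), with local-median background
   subtraction and a floor on neighbour residuals. Noise scatters the
   estimate around the 1.5 cm⁻¹ narrow/broad routing threshold, which is
   precisely why a second, learned stage is needed.
2. **Candidate gating must not depend on intensity statistics.** The
   robust z-score gate is computed on the *second difference* (curvature):
   genuine bands are smooth at the grid scale, so the curvature MAD of a
   50-point window stays at the noise level even inside dense band
   clusters, while spikes score in the hundreds. The rule stage gates
   candidates at z ≥ 25; the ML stage enumerates candidates at a
   permissive z ≥ 5 so that low-amplitude rays riding on band flanks are
   still scored.

The rule stage flags a candidate when its estimated width is below
1.5 cm⁻¹ AND band sharpness ((height/background)/width) ≥ 1.0 AND the
height-normalized derivative score ≥ 0.2. Unflagged candidates with
estimated width below 8 cm⁻¹ go to a gradient-boosting classifier trained
on generator scenarios (features: sub-grid width, derivative sharpness,
asymmetry, amplitude ratio, intensity z-score, neighbour contrast,
second-derivative magnitude; a random-forest alternative is provided and
evaluated by the same stratified 5-fold CV). On the synthetic campaign
(2000 rays across 100 spectra, five class presets) the rule stage alone
recovers ≈ 78% and the hybrid ≈ 99.9–100%, with zero false positives on
clean spectra.

**Correction.** Only the contaminated core (detection index ± 1, extended
where the residual against a 7-point median filter stays above a noise
threshold, capped at ± 3) is replaced; the two guard points per side are
recorded in the detection's support but are provably uncontaminated (a
sub-grid Gaussian is numerically zero two pixels out) and anchor the
interpolation. The default replacement is a PCHIP bridge through five
flanking points per side — shape-preserving, never ringing beyond its knot
extrema. When the uncontaminated neighbourhood is well described by a
single Gaussian band (concave log-quadratic fit with relative RMSE < 0.15
and no extrapolation blow-up), the band-model patch is used instead: a ray
sitting on a band apex would otherwise have the genuine peak clipped by a
chord. Rays at least two band-FWHM away from any genuine band restore to
within 5% of the spectrum's peak intensity; a ray that hides part of an
8 cm⁻¹ band under a ~15 cm⁻¹ replacement window is ill-posed for any
interpolating corrector at this grid spacing, so only the median error is
bounded across all detections.

## CO₂ excision

The FTIR doublet region 2288–2392 cm⁻¹ is replaced by a PCHIP bridge
fitted on 12 locally-averaged samples (5-point means, 6 per side) drawn
from flanking windows of width 2.0 × the region width beyond the edge
buffer. The bridge is blended with the original through a clipped logistic
weight: w = 1 across the region and a short 4-point plateau beyond each
edge (the doublet centres sit *at* the region boundaries, so their outer
tails must still be removed), falling to exactly 0 within the 30-point
edge buffer. The smoothing factor (0.98) sets the logistic span, i.e. how
abrupt the hand-over is; the steep-but-smooth ramp suppresses the ringing
a hard splice would cause while leaving genuine bands a few tens of cm⁻¹
outside the region — the ABS nitrile stretch at 2240–2260 cm⁻¹ — changed
by well under 5% of peak height. Outside region + buffer the output equals
the input exactly. On 100 synthetic spectra with doublet intensities drawn
from 0.20–0.90 / 0.15–0.71 the mean intensity reduction at both centres is
≈ 99.5%, and the integrated local efficiency on the PET worked example
exceeds 99% in both peak regions.

An earlier variant in which the smoothing factor directly multiplied the
replacement's deviation from the original caps the attainable centre
reduction at ~98% by construction and cannot reach the >99% local
efficiencies the clipped-ramp design achieves; it was discarded for that
reason.

## Augmentation and routing

Classes with at least 50 original spectra are routed to deep-model
training and expanded to a fixed per-class target; smaller classes are
reserved for PCC matching. Three strategies: (a) *original* — resampling
with replacement plus Gaussian intensity jitter (σ = 0.01 of the seed
maximum); (b) *i-arPLS-family* — each output adds to a seed a synthetic
baseline drawn from the same linear / broad-Gaussian family the corrector
removes, scaled by `perturb_scale` (default 0.1), plus jitter,
renormalized — the model must become invariant to exactly the nuisance the
corrector targets; (c) *SMOTE-style* — convex interpolation between a seed
and one of its k nearest neighbours with uniform weight, which keeps every
output inside the elementwise envelope of its parent pair. Zero
perturbation reproduces the seeds exactly; seeds are always retained at
the head of each class pool, and every augmented spectrum keeps its seed
label.

## Residual-network classifier

The network is a stem convolution (stride 2) followed by residual blocks.
Each block runs parallel convolutions at three kernel sizes (default 3, 7,
15 grid points ≈ 10–45 cm⁻¹ of context), concatenates, applies ReLU and a
squeeze-and-excitation gate (global average → bottleneck → sigmoid,
channelwise multiplication by factors in [0, 1]), and adds the skip path
(1×1 projection when the channel count changes). With all branch weights
zero a block is the identity on its non-negative input domain — the
skip-connection contract. Global average pooling, dropout and a linear
head complete the model. Default channels are (32, 64, 64, 128); the test
suite and desk-scale workflows use a two-block (6, 12) configuration that
keeps every architectural ingredient and trains in seconds.

The engine is pure NumPy with explicit backpropagation (im2col
convolutions, Adam), validated by central-difference gradient checks to
~1e-8 relative error. Inputs are standardized per training split (scalar
mean/sd stored on the model). Training is seeded end to end — fold
assignment, initialization, shuffling, dropout — giving identical metrics
across reruns on one platform; bitwise reproducibility across BLAS builds
is not promised.

Predictions come from a stratified k-fold ensemble (default 10 folds;
label proportions preserved within one member per fold): the ensemble
softmax is the mean of fold softmaxes and the label its argmax. On the
separable 5-class synthetic task (60 clean spectra per class) the
3-fold desk configuration reaches 100% held-out fold accuracy. A
single-kernel configuration of the same depth serves as the plain-CNN
comparator; the model card records parameter counts for such comparisons.

## Out-of-distribution filtering

Tier 1 rejects outright any query whose best Pearson correlation against a
non-polymer reference library reaches the screening threshold (default
0.90), reporting the matched identity. Tier 2 extracts uncertainty
features from the ensemble — maximum softmax, predictive entropy (−Σ p ln p,
bounded by ln K), per-class Mahalanobis distances of the ensemble-mean
penultimate embedding under a shared covariance with ridge
ε = 1e-3 · trace/dim (floored away from zero for degenerate embeddings),
the standard deviation over folds of each fold's top-class confidence, and
the top-2 margin — and scores them with a random forest trained on
balanced held-out ID vs OOD feature sets. The acceptance score is the
forest's ID probability; dual thresholds split it into Reject (< τ_low),
Verify (queued to a file for human review) and Accept (> τ_high), with
modality defaults Raman (0.10, 0.90) and FTIR (0.45, 0.70). On the
synthetic suite with well-separated OOD classes (mineral and biopolymer
presets) no OOD spectrum reaches the Accept tier at the Raman defaults,
while ≥ 80% of held-out ID spectra are accepted. Tier 3 triggers only when
the primary prediction is in a confusable set (default {PE}): a dedicated
classifier over {PE, fatty-acid confounders, graded convex mixtures}
refines the label and reports the mixture proportions encoded in the
predicted class. Two mixture classes built from identical spectra are
irreducibly confusable; the ensemble then splits its softmax mass between
exactly those two, which is the correct behaviour, not a defect.

## Substrate masking (SSEM)

Per-pixel features are the top principal-component scores of the image's
own fitted PCA (component signs fixed deterministically), peak intensity,
variance, skewness, and normalized spatial coordinates. A random forest is
trained on labelled pixels with stratified k-fold CV reporting; K-means
(k = 2) clusters the PC scores per image, and the cluster whose centroid
has the lower mean peak intensity is taken as substrate (substrates are
spectrally flat; the mapping is overridable). A pixel is labelled
substrate when `w_rf · P_rf(substrate) + w_cluster · 1[cluster=substrate]`
exceeds 0.5, with default weights (0.7, 0.3); the per-pixel confidence is
the same weighted sum evaluated at the assigned label, so full agreement
with a certain forest gives exactly 1.0 and weights (1, 0) reduce the
ensemble to the forest alone. Masking never touches the spectra; particle
regions are extracted by 4-connectivity with pixel counts and bounding
boxes. Classification downstream visits particle pixels only, so the
classified-pixel count equals (1 − substrate fraction) × total exactly —
the accounting basis for the masking speed-up. On synthetic images
(flat-noise substrate vs banded particles) CV accuracy exceeds 99%,
spatial coordinates contribute a small fraction of the importance mass,
and the recovered substrate fraction lands within 3 percentage points of
ground truth.

## Synthetic-data generator

Classes are sums of Gaussian bands (positions and relative heights chosen
to qualitatively mimic the strongest bands of PVC, PE, PS, PET, PP and,
for FTIR, PET/PE/ABS/PP/PS; ABS includes the nitrile stretch near
2240 cm⁻¹ that stress-tests CO₂ excision). Band FWHMs are 8–30 cm⁻¹ —
always above two grid steps, the invariant separating genuine bands from
rays. Baselines are linear ramps on a positive pedestal or broad Gaussian
fluorescence humps (σ 400–600 cm⁻¹); noise is white Gaussian, σ = 0.01 of
the signal scale for Raman and 0.002 absorbance for FTIR (ATR-FTIR
absorbance noise sits an order of magnitude below Raman shot noise).
Per-spectrum jitter: band heights ±10%, positions ±1 grid step.

Rays are injected as Gaussians with FWHM drawn from 0.31–1.15 cm⁻¹ at
non-overlapping positions, into the *raw* spectrum (cosmic rays hit the
detector before any correction), and each ray is rescaled so its realized
on-grid peak sits at the drawn multiple (5.7–19.5×) of the local median
background — a sub-pixel-width spike whose nominal amplitude fell between
samples would otherwise be invisible and untestable. CO₂ doublets are
Gaussian pairs at 2288/2392 cm⁻¹ (FWHM 14 cm⁻¹) with peak intensities
drawn from 0.20–0.90 and 0.15–0.71. Images place particle blobs as random
discs until the target substrate fraction is met within ±2% (the last blob
is trimmed), on a channel-decimated axis to keep cubes small. Every
generated artifact ships its ground truth (clean spectrum, positions,
widths, amplitudes, mask), and no evaluation in the repository uses labels
the generator did not emit.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: Lorentzian/Voigt band shapes, instrument
response and detector nonlinearity, wavenumber calibration error,
multiplicative scatter effects, weathering-induced band broadening and
carbonyl growth, mixed-composition pixels at particle boundaries, and the
long-tailed diversity of real environmental libraries. Results on the
synthetic suite demonstrate algorithmic correctness under the stated
conditions, not field performance.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 5 classes
× 60 spectra for the classifier fixtures, 100-spectrum / 2000-ray detection
campaigns, 100-spectrum CO₂ campaigns, 24–28-pixel-square images, and a
two-condition data-scaling comparison (20 seeds → 50/class vs 50 seeds →
800/class) that reproduces the direction of the accuracy-vs-data
relationship. The full run completes in a few minutes on one CPU.

## Known limitations

* Restoring a genuine band apex hidden beneath a cosmic ray is ill-posed
  at 3 cm⁻¹ spacing; the band-model patch mitigates but cannot eliminate
  this (see the correction section).
* The i-arPLS weight scheme assumes noise roughly symmetric below the
  baseline; strongly heteroscedastic noise would bias the negative-residual
  statistics.
* PCC screening uses full-spectrum correlation; a non-polymer contaminant
  occupying a narrow spectral window can pass the screen and must be caught
  by the uncertainty tier.
* The NumPy network engine is single-threaded BLAS-bound and intended for
  desk-scale models; it is not a substitute for a GPU framework at
  production library sizes.
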