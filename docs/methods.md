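# Methods

## The problem and the pipeline

Serum Raman screening asks whether the relative intensities of a few dozen
biomolecular bands in a patient's serum spectrum carry enough information
to separate breast cancer, benign lesions, and healthy controls. The raw
measurement is unfavourable: the Raman signal sits on an autofluorescence
background one to two orders of magnitude larger, the absolute intensity
scale drifts with laser power, and CCD detectors collect occasional
cosmic-ray spikes. The pipeline therefore has two halves: a deterministic
preprocessing chain that strips every nuisance component, and a
cross-validated PCA–SVM classifier evaluated so that no information leaks
from test to training data.

## Synthetic cohort model

No clinical spectra are distributed, so the package generates cohorts with
the statistical structure the analysis assumes. One scan is

  I(ν) = s·B(ν) + Σₖ aₖ·Lₖ(ν − δ) + ε(ν) + spikes,

where

- **B(ν)** is the autofluorescence background: an order-5 polynomial in
  t = (ν−200)/1800, positive and slowly decaying toward high wavenumber,
  scaled to ~1500–4500 counts (coefficients `(3, −4, 2, −0.6, 0.12, −0.02)`,
  scale 1500). The per-scan factor s is lognormal with σ = 0.10,
  emulating laser-power drift. Autofluorescence dominating the Raman
  signal by an order of magnitude is the realistic regime for raw serum.
- **Lₖ** are the 18 marker bands at 784…1650 cm⁻¹, Lorentzian by default
  (typical Raman lineshape; Gaussian selectable), HWHM 8 cm⁻¹. Band
  amplitudes aₖ for the control class are 60–140 counts, with the
  phenylalanine (1002), CH₂ (1437) and amide I (1650) bands largest.
- **Class structure**: directed bands differ between cancer and control
  by ±25% (at `effect_scale=1`), in the directions serum biochemistry
  dictates (nucleic-acid 784, tryptophan/glutamate 1020/1056/1367 and
  lipid 1114 up in cancer; amino-acid 835/986/989/1002, amide α-helix
  1285/1650 and β-carotene 1531 down). Bands without a reported direction
  get small ±6% offsets. The benign class is the midpoint of cancer and
  control, reflecting how closely malignant and benign serum fingerprints
  resemble each other. `effect_scale` multiplies all differences; 0 makes
  the classes identical. Since no absolute effect sizes in intensity
  units are available for serum cohorts, the ±25% figure was fixed once
  as the value that reproduces near-complete class separation at the
  study's sample size, which is the regime the clinical result sits in.
- **Biological and technical scatter**: per-sample amplitudes are
  lognormal around the class profile (σ = 0.08 between samples), then
  jittered per scan (σ = 0.03 within sample). A per-scan wavenumber shift
  δ ~ N(0, 0.3 cm⁻¹) emulates residual calibration error.
- **Noise and spikes**: i.i.d. Gaussian noise with σ = 5 counts;
  cosmic-ray spikes are single-channel additive outliers, Poisson(0.5)
  per scan, uniform amplitude 50–250 counts (10–50 × noise σ).
- **Grid**: 200–2000 cm⁻¹ at 1 cm⁻¹ (1801 channels); acquisition range
  from the study, step chosen as a typical dispersive-CCD resolution.

Ground truth (baseline curve, spike channels, true amplitudes, per scan)
is recorded for every scan and consumed only by tests.

What the simulator does **not** model: CCD response and etendue, Mie or
turbidity scattering, wavelength-dependent noise, band-shape changes
(only amplitudes carry class information), and inter-instrument
variation. Passing tests therefore demonstrate that the pipeline recovers
known signal from realistic nuisance structure — not that real serum
cohorts are classifiable at any particular accuracy.

## Preprocessing

Order of operations per scan: crop → despike → smooth → baseline
subtraction → area normalization; replicate scans are averaged last,
following the study's use of per-serum mean spectra as the analysis unit.
Whether smoothing precedes baseline removal is not fixed by the source
description; the default above smooths first so that the baseline fit
sees less noise. The chain contains no randomness.

- **Crop**: closed interval 600–1800 cm⁻¹ (1201 channels at 1 cm⁻¹) —
  the fingerprint window.
- **Despike** (method open; chosen here): a channel whose deviation from
  the rolling median (window 7) exceeds z = 8 × a MAD-based scale is
  replaced by that median. The scale is the MAD of the rolling-median
  residuals over the whole spectrum: a windowed MAD has a fat lower tail
  on 7 samples and flags noise channels. Despiking is applied per scan
  before averaging — averaging alone would dilute, not remove, spikes.
- **Smooth** (method open; chosen here): Savitzky–Golay, window 9,
  polyorder 3 — preserves band shape better than a moving average.
- **Baseline**: iterative modified-polyfit ("Vancouver") at order 7.
  Each round fits an order-7 polynomial P to the working spectrum by
  least squares (axis rescaled to [−1, 1] for conditioning), estimates
  the residual level DEV = std(working − P), and clips the working
  spectrum at P + DEV, so Raman bands are progressively excluded while
  baseline and noise survive. Iteration stops when |ΔDEV|/DEV < 0.005 or
  after 100 rounds (tolerances open in the source; these converge in
  ~10–30 rounds on serum-like input). Non-convergence is reported in the
  returned fit object, not raised. On a peak-free polynomial input the
  first fit is exact and the loop exits after ≤ 2 rounds.
- **Area normalization**: divide by the trapezoidal integral over the
  cropped window. Negative post-subtraction excursions are kept in the
  feature vector but floored at zero for the integral, so the normalizer
  is a positive measure of signal mass. This makes each sample's final
  feature row invariant to rescaling its raw scans (laser-power drift).
- **Common grid**: scans on a different axis than the first sample's
  cropped grid are linearly interpolated onto it.

## PCA–SVM model

PCA is fit by SVD on the training rows only (strict reading of
"applied to the training data"; fitting on all data would leak test-set
structure into the features). The smallest k with cumulative explained
variance ≥ 0.99 is kept; component signs are fixed by making each
component's largest-magnitude loading positive, so the decomposition is
deterministic.

Classification is one-vs-all: three binary soft-margin SVMs (RBF kernel
by default — the kernel is not pinned down by the source; linear is
selectable), prediction by maximal decision value with ties broken by the
fixed class order (cancer, benign, normal). Hyperparameters come from a
grid C ∈ {0.1, 1, 10, 100}, γ ∈ {0.001, 0.01, 0.1, 1}/k scored by mean
multiclass accuracy over stratified 5-fold inner CV on the training
portion; ties prefer the smallest C, then the smallest γ.

**Score scaling.** PCA scores of area-normalized spectra are O(10⁻⁴), far
from the unit scale the γ grid assumes; an RBF kernel on raw scores
degenerates (all pairwise distances ≈ 0, decision values near-constant,
rankings meaningless even when argmax classification still works). Scores
are therefore centred and divided by one global standard deviation
computed on the training portion — the scaling step standard SVM practice
prescribes. A single global factor is used rather than per-component
standardization: the latter would amplify the ~100 near-noise components
to the same scale as the leading PCs and demonstrably destroys the benign
class, whereas a global factor preserves PCA's variance weighting.

No class weighting is applied (imbalance 129/91/113 is mild) and no
probability calibration (decision values suffice for ROC).

## Cross-validation and the permutation control

The source describes both an 80/20 allocation and "each fold used once as
an independent test set"; these are reconciled as a stratified 5-fold
outer partition (each fold = 20%) redrawn 20 times, i.e. 100 model fits,
which also matches confusion counts spanning the whole cohort. The
literal repeated 80/20 holdout remains available as a config switch. Per
repeat every sample is predicted exactly once; confusion matrices, per
class sensitivity/specificity/one-vs-rest accuracy, and one-vs-rest AUC
(from the repeat's pooled out-of-fold decision values) are aggregated as
mean ± sample std with percentile (2.5/97.5) 95% CIs — percentiles rather
than a normal approximation because repeat distributions skew near
accuracy 1. Per-class "accuracy" is one-vs-rest, (TP+TN)/n. All
randomness derives from a single seed via spawned seed sequences, so
results are bit-reproducible across process restarts.

The permutation control permutes the label vector uniformly at random
(class frequencies preserved) before any model building and reruns the
entire nested CV per permutation with the same classifier settings. With
labels independent of spectra, the expected held-out overall accuracy of
*any* classifier is Σ_c p_c q_c ≤ max_c p_c, where p are the true class
frequencies and q the classifier's prediction frequencies — at this
cohort's composition, at most 129/333 ≈ 38.7%, and ≈ 35–36% measured for
the actual selected models. A published permuted-label figure above that
bound is only reachable by optimistically biased accounting (e.g.
reporting the model-selection CV accuracy, whose max-over-grid selection
carries upward bias); the package reports the unbiased held-out number.

## Numerical choices and degenerate inputs

- Polynomial fits use `numpy.polynomial.Polynomial.fit`, which maps the
  axis to [−1, 1] internally; order-7 fits on 1201 channels are then
  well conditioned.
- Spectra must be strictly increasing in wavenumber with ≥ 2 channels;
  file readers sort and deduplicate, and reject files with < 10 points.
- A spectrum whose floored integral is ≤ 0 cannot be normalized
  (degenerate-spectrum error).
- DEV = 0 in the baseline loop (exactly polynomial input) terminates
  immediately as converged.
- `despike` floors its robust scale at 10⁻¹² × max|I| so an all-constant
  spectrum passes through untouched.
- Metrics guard zero denominators (a class absent from both truth and
  prediction reports sensitivity from a 0/0-protected ratio).

## Problem sizes used in the shipped checks

The test suite and acceptance script run the study-sized cohort
(333 samples × 10 scans) for data-volume, permutation and PCA checks, and
a 40%-scale cohort (52/36/45 × 3 scans) for the effect-size response
sweep; the permutation control and quick runs use a coarse (2 × 2)
hyperparameter subgrid. These sizes were chosen so a full run completes
in minutes on one core while keeping every estimate comfortably inside
its Monte-Carlo tolerance.

## Known limitations

- The simulator's class effect is an amplitude-only model; real disease
  signatures also shift band positions and widths.
- Axis jitter is the only calibration error modelled; no neon/ethanol
  calibration procedure is implemented.
- The Vancouver baseline's small positive bias (≲ DEV) in crowded band
  regions is absorbed by area normalization but not explicitly corrected.
- ROC curves are built per repeat from pooled out-of-fold decision
  values and AUCs averaged across repeats; pooling across repeats would
  be an alternative convention.
- An optional per-channel Welch t-test with Benjamini–Hochberg correction
  for band-difference reporting was considered and deliberately left out:
  group mean/difference spectra are descriptive here.
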