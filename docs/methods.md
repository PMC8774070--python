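# Methods

## Problem and model

Glioblastoma infiltrates well beyond its contrast-enhancing core. The
voxels of interest (VOI) are those inside the T2-FLAIR hyperintense lesion
but outside the contrast-enhancing lesion — a mixture of non-enhancing
tumor and vasogenic edema. Amino-acid PET supplies the reference standard:
a voxel is "Met-PET high" when its tumor-to-normal activity ratio strictly
exceeds 1.5, the cut-off associated with high glioma cell density. The
package's statistic, LMPH (Likeliness of Met-PET high), scores each VOI
voxel from conventional MRI alone.

### rT1/T2 calibration

Weighted MR intensities are arbitrary units, so the T1w/T2w ratio is only
meaningful after both images are standardized. Calibration here is a
two-point affine intensity map per image: the modal in-mask intensity of
the eye (vitreous, the low reference) and of the temporal muscle (the high
reference) are mapped exactly to fixed targets, by default 0 and 100
arbitrary units. Any per-image gain and offset then cancels in the ratio,
which is the property that makes rT1/T2 comparable across scanners. The
absolute target values are immaterial: changing them applies a global
monotone transform to the ratio map, which the downstream histogram
binning absorbs. Nonlinear histogram standardization and segmentation-based
bias-field correction are upstream preprocessing concerns outside this
package; inputs are assumed bias-free (the synthetic fixtures are).

Reference peaks are located by a histogram with Freedman–Diaconis bin
width, refined by parabolic interpolation around the argmax bin. This is
deterministic, robust from hundreds to millions of samples, and returns
the exact value for a degenerate (constant) sample. A zero interquartile
range falls back to log2-scaled binning of the sample span.

### LMPH

For histogram bin k, with nH(k)/NH and nL(k)/NL the class-conditional
proportions of Met-PET-high and -low voxels,

    LMPH(k) = (nH(k)/NH − nL(k)/NL) / (nH(k)/NH + nL(k)/NL).

Properties relied on (and tested): bounds in [−1, 1] with the endpoints
attained exactly and only in one-sided bins; antisymmetry under class-label
swap; invariance to scaling either class's size; strict monotonicity in
the high-class proportion at fixed low-class proportion. A bin empty in
both classes has no defined value; voxels falling there, or outside the
histogram support, are removed from scoring — never clamped, imputed or
defaulted, because a fabricated score would contaminate the ROC.

Binning defaults: support [0.3, 1.3] — the range tumor-VOI rT1/T2 values
mainly occupy — with bin width 0.02 (50 bins). Both are configuration;
every validation stage runs at whatever width is configured. Bins are
half-open [lo_k, hi_k) with the top bin closed, so every in-range value has
exactly one bin.

### Validation

Leave-one-patient-out: the conversion table is learned from all other
patients' VOI voxels and applied to the held-out patient's ratio map;
scores are compared to the patient's own Met-PET labels by ROC. AUC uses
the Mann–Whitney convention with ½ credit for ties — binned scores
guarantee ties, and this is the unique convention matching the trapezoidal
area under the thresholded curve (verified against a brute-force all-pairs
count to 1e-12). Patient-level curves are averaged vertically on a fixed
grid of 101 false-positive-rate points via linear interpolation.

A patient whose VOI has no high voxels (NH = 0) has no defined ROC and is
excluded from validation with a recorded reason; the NL = 0 case is
handled symmetrically. Excluded patients' voxels still contribute to the
training folds of others. Voxels whose LMPH is undefined on the held-out
patient are excluded from that patient's ROC with a recorded count rather
than scored at a default.

Summary statistics: arithmetic mean and sample SD (ddof = 1) of the
included AUCs, and a classical two-sided one-sample t-test of the AUCs
against 0.5.

### Relaxation-time link

rT1/T2 relates to T1- and T2-relaxation time by a decaying exponential
r = a·e^(b·t). The fit is ordinary least squares of ln r on t (a =
exp(intercept), b = slope); the reported Pearson r and two-sided p refer to
the linearized pair (t, ln r). Fitting on the log scale is the only reading
under which a single correlation coefficient is well-defined for this
model; a nonlinear raw-scale fit with a separate raw-scale correlation
would decouple the printed coefficient from the printed model. Non-positive
ratios are a domain error (the log link is undefined), and at least three
observations are required.

## Synthetic cohorts

No clinical images ship with the package, so the generator emulates the
structure the analysis assumes:

* **rT1/T2 class distributions** — truncated normals on [0.3, 1.3];
  defaults high ~ N(0.9, 0.05), low ~ N(0.6, 0.15), making the high-class
  distribution markedly narrower than the low-class one, as observed in
  tumor VOIs. The truncated-normal family is the simplest one matching the
  stated support and narrow/wide contrast.
* **T/N ratios** drawn conditionally on class — high: 1.5 + 10⁻³ +
  |N(0, 0.4)|; low: uniform on [0.8, 1.5) — so the 1.5 threshold exactly
  reproduces the labels even after float32 storage (the 10⁻³ clearance
  guards the strict inequality against rounding).
* **Relaxation times** obtained by inverting r = a·e^(b·t) with
  multiplicative log-normal noise (σ = 0.2 by default) and the fitted-scale
  defaults a = 0.862, b = −2.13·10⁻⁵ ms⁻¹ (T1) and a = 0.951,
  b = −8.84·10⁻⁴ ms⁻¹ (T2). Because ratios are sampled first and the
  amplitude sits inside the ratio range, inverted "times" can be negative:
  they are link-consistent covariates for exercising the fit, not physical
  relaxation times.
* **Volumes** — a FLAIR ellipsoid with an interior contrast-enhancing
  core on a 32³ unit grid by default, constant-intensity eye and
  temporal-muscle reference spheres kept disjoint from the lesion, and raw
  T1w/T2w images built as per-patient random gain/offset distortions
  (gain ∈ [0.5, 2], offset ∈ [−20, 50]) of cal-space images whose ratio
  inside the VOI equals the sampled rT1/T2. Calibration therefore provably
  inverts the distortion; the round trip is exact to float32 (≈10⁻⁷).
  Reference regions are exactly constant so the modal estimate is exact;
  real reference regions have internal texture the peak finder must
  smooth over, which the Gaussian- and bimodal-sample tests cover instead.

Default cohort size is 34 patients, mirroring the scale of a typical
single-pair-of-institutions GBM cohort; tests and the acceptance script use
6–10 patients with a few hundred to ~1,600 VOI voxels each, and the
relaxation fit is exercised at 76,706 voxels — desk-scale sizes chosen so
the full suite runs in seconds while every statistical check retains
adequate power. The generator does not simulate scanner physics, bias
fields, partial-volume effects, or registration error, so passing tests
demonstrate correctness of the analysis given well-registered, bias-free
inputs — not robustness to those artifacts.

## Numerical choices

* Grid compatibility: identical shapes and affines within absolute 1e-4.
* Masks binarized at > 0.5 on read, with a warning for non-{0,1} values
  (interpolation artifacts), never an error; scalar volumes stored float32,
  masks uint8.
* T/N exactly at threshold → "low" (strict inequality).
* Non-finite or non-positive rT1/T2 voxels are dropped from the voxel
  table with a logged count — they indicate calibration failure, not
  signal.
* Ratio division guarded by ε = 10⁻⁶ · target_high; only true zeros in the
  calibrated T2w denominator are marked invalid.
* Zero-variance samples are a degenerate-test error, not p = NaN.

## Known limitations

**The t-test over LOPO AUCs is anti-conservative.** Per-patient AUCs are
unbiased under the null (grand mean 0.499 over 150 null cohorts), but fold
statistics are positively correlated — each patient's voxels sit in every
other fold's training set, and the measured inter-fold correlation behaves
like 1/(P−1) (≈0.16 at 6 patients, ≈0.08 at 12). The variance of the mean
AUC is therefore inflated by a roughly constant factor (~1.9 in variance)
relative to the independence assumption of the one-sample t-test, at every
cohort size and voxel count examined, and the test rejects a true null at
~13–17% instead of 5%. A control experiment scoring each patient with a
conversion trained on an independent cohort restores the nominal rate
(3.0% over 200 replicates), confirming the effect is the well-known
structural dependence of cross-validation fold statistics rather than an
implementation artifact. Interpret the reported p-value as optimistic;
no corrected variance estimator is attempted here because none is unbiased
for cross-validation in general.

Other limitations: no registration, resampling or reorientation (inputs
must share a grid); no morphological mask cleanup; no smoothing or
monotonic regression of the conversion curve; the PET normal-tissue
reference is an explicit input (contralateral normal brain by convention)
rather than an atlas-derived region.
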