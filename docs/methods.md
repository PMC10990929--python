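# Methods

This note documents the models and procedures implemented in msipipe,
the parameters that matter, what the synthetic phantom does and does not
emulate, and the design choices made where the processing chain admits
more than one reasonable construction.

## Phantom model

A phantom is a H × W pixel grid (origin top-left, row-major flattening
`index = row·width + col`) partitioned into named regions — by default a
tissue ellipse containing a smaller lesion ellipse on a background
frame. Each planted species contributes a Gaussian line per pixel:

    I(m) = baseline + Σ_s A_s(region) · exp(−(m − c_s·(1 + d/10⁶))² / 2σ_s²) + ε

* `A_s(region)` — region-wise apex amplitude (arbitrary intensity
  units). The amplitude is the configured region mean exactly, so
  region-conditional means on a noiseless phantom are exact by
  construction.
* `d ~ N(0, drift_ppm_sd)` — one multiplicative mass drift per pixel,
  applied to every line of that pixel. Drift is multiplicative (ppm
  scale) rather than additive because that is the error model lock-mass
  correction assumes over a 174–767 m/z range.
* `ε ~ N(0, noise_sd + noise_cv·signal)` — additive noise with an
  optional intensity-proportional term; the profile is floored at 0.
* Isotope satellites sit at `c_s + 1.00336` (the ¹³C–¹²C spacing) with a
  configurable relative intensity (default 0.3).
* Lock-mass calibrants (defaults m/z 174.0408, 255.2324, 766.5392) are
  present in every non-background pixel.

The m/z axis is a union of segments of step `0.25·σ` spanning ±6σ plus a
drift margin around each line, so the exact line centre is always
on-grid and the integral of a noiseless line equals `A·√(2π)·σ` to
better than 10⁻⁶ relative (trapezoidal integration of a smooth,
tail-decaying function).

**What the phantom does not emulate.** Instrument line shapes beyond
Gaussian, detector saturation, correlated chemical noise, within-region
intensity gradients, and plume chemistry. The last omission matters for
colocalization: real colocalized metabolites co-vary continuously across
a lesion, whereas phantom species are region-wise constant, so their
rank correlation over sample pixels is capped by the block structure of
the ranks (~0.3–0.4 for a lesion occupying ~16 % of the tissue). Tests
passing on the phantom therefore demonstrate the statistics and
book-keeping of each stage, not field performance on real tissue.

## Peak picking

Noise and baseline are estimated by a double sliding-window median:
`baseline = med_w(y)`, `noise = 1.4826·med_w(|y − baseline|)` (window 51
points, reflect boundaries). The MAD is robust to the sparse tall peaks
that dominate real spectra; 1.4826 makes it consistent for Gaussian
noise. Candidates are local maxima with
`(apex − baseline)/noise ≥ snr_min` (default 3); where the noise
estimate is exactly zero any positive net apex counts as detected
(noiseless data must not be undetectable). Peaks closer than `min_dist`
axis steps (default 3) merge keeping the taller, ties toward lower m/z —
for well-resolved Gaussian lines a `min_dist` near the FWHM in axis
steps also suppresses flank maxima riding on a peak's shoulders.
Centroids are intensity-weighted means of the baseline-subtracted
profile over apex ± FWHM-estimate (min 3, max 25 points). The wide
window is deliberate: with a narrower window the centroid snaps toward
the apex grid point and sub-step mass shifts (a few ppm at typical
sampling) are attenuated by ~70 %, which would defeat drift estimation.
Because SNR is a ratio of two quantities linear in intensity, detection
is invariant to uniform intensity scaling.

## Lock-mass recalibration

Per pixel, two steps: (1) each reference mass is matched to the nearest
observed centroid within `lock_tol_ppm` (default 30); (2) a least-squares
affine map `m/z → (1+α)·m/z + β` over the matched pairs is applied to
all centroids. With exactly one match the correction degrades to a pure
ppm rescaling (β = 0); with none the pixel keeps its centroids and is
flagged, falling back to a run-level model pooled over all pixels when
one exists. Least squares guarantees post-correction lock-mass residuals
never exceed pre-correction ones. On a 5 ppm-drifted phantom the mean
recovered calibrant centroid lands within a small fraction of 1 ppm of
the reference, and per-pixel residuals shrink by more than an order of
magnitude.

## Common axis, cube

Pooled, sorted centroids are clustered greedily: a peak opens a new
feature when its distance from the running intensity-weighted bin centre
exceeds `bin_tol_ppm` (default 10). The pooled sort makes the result
invariant to pixel order; the algorithm is O(P log P) and deterministic,
which is why it was chosen over density clustering. Axes of separate
runs are intersected — a feature survives only if matchable within
tolerance in every run, its centre becoming the mean of the matched
centres. Cube entry (pixel, feature) is the summed intensity of the
pixel's peaks assigned to that feature; total intensity is conserved
exactly when every peak is assigned.

## ROI annotation and off-sample filtering

Sample/background annotation is semi-supervised nearest-centroid: seed
pixels (manual, or automatically the brightest/dimmest TIC deciles)
define class centroids of TIC-normalized spectra; other pixels take the
label of the most cosine-similar centroid, ties toward the first-listed
class, seeds immutable. Nearest-centroid was preferred to graph label
propagation because it is deterministic and parameter-light, and the
sample/background split is spectrally easy. TIC normalization makes the
propagation invariant to per-pixel intensity scaling.

Tissue-unrelated features are removed by thresholding the Pearson
correlation of each feature's ion image with a tissue reference image
(default: the mean ion image; optionally the unmixing tissue-abundance
map) at `min_corr` (default 0.2). Constant ion images are removed by
convention. Any feature whose image is a positive affine transform of
the reference has correlation 1 and is never removed.

## SSIM / MS-SSIM refinement

Single-scale SSIM follows the standard windowed definition with
population window statistics, uniform (unweighted) windows of size 7,
K₁ = 0.01, K₂ = 0.03, and dynamic range = per-pair maximum (ion images
are min-max scaled per feature before scoring, since SSIM is
range-dependent). MS-SSIM combines contrast-structure terms over dyadic
2 × 2 block-mean downsamplings with the canonical five-level exponents
truncated and renormalized to the configured level count (default 3);
the coarsest scale contributes the full SSIM including luminance, so a
single level reduces exactly to SSIM. Negative terms are clipped to 0
before exponentiation. A feature is retained when
`w·SSIM + (1−w)·MS-SSIM ≥ τ` with defaults w = 0.5, τ = 0.3; τ is a
perceptual knob without a principled value, so it is recorded in every
manifest. Removed features carry an informational guess — "isotope" when
the feature sits one ¹³C spacing above another feature, else
"background". The implementation is verified to 10⁻¹⁰ against a literal
brute-force windowed-formula oracle and cross-checked against
scikit-image's uniform-window SSIM.

The reference image defaults to the mean ion image. The two-pass
alternative (`ssim_reference: unmix`) feeds the first-pass tissue
abundance map back as the reference; it is opt-in because the k = 2
abundance split can vary qualitatively between random restarts on
small cubes, making the filter outcome less stable than the mean image.

## Spectral unmixing

Non-negative matrix factorization X ≈ WH by multiplicative updates
minimizing the Frobenius error, k = 2 by default (tissue + background).
Multiplicative updates keep factors non-negative and make the error
sequence non-increasing, which the result records per iteration; 5
seeded random restarts keep the best final error. Endmembers are
normalized to unit sum with the scale pushed into the abundances (the
product is invariant). The tissue component is the one whose abundance
map best correlates with the sample ROI, or with the TIC image when no
ROI is attached. NMF was chosen because it is the standard non-negative
formulation for spectral unmixing and its monotonicity property makes it
directly verifiable; no claim is made that it reproduces any specific
published unmixing variant beyond the k = 2 tissue/background behaviour.

## Colocalization

Spearman rho (Pearson on midranks) with p-values from the t
approximation with n − 2 degrees of freedom, computed over sample-ROI
pixels only — background pixels share zeros across features and would
inflate correlations. Zero-variance features are recorded as missing and
excluded from testing. The upper triangle is Benjamini–Hochberg
adjusted; a pair is reported when q ≤ α (default 0.05) **and**
rho ≥ `min_rho` (default 0.5). Both gates are exposed because
"significant" alone admits weak correlations at imaging sample sizes;
on phantoms whose lesion signal is block-structured the rho gate is the
binding one (see the phantom caveat above).

## Classification

Binary weighted logistic regression: features standardized on the
training fold (zero-variance features dropped with a warning), L2
penalty of strength `ridge` = 1 on standardized features, class weights
inverse to class frequency by default. Validation is leave-one-group-out
where a group is one imaging run / tissue section — per-pixel random CV
would leak spatial structure; with singleton groups the scheme reduces
to classical LOO. Folds whose training set lacks a class are skipped
with a warning and reported. The ROC curve and AUC come from the pooled
held-out probabilities (trapezoidal), which is stabler than per-fold
averaging with few folds. RFE refits on the full data each round and
drops the 10 % of remaining features with the smallest standardized
|weight| (at least one, stable ties toward lower index) until the target
count remains; model validity is assessed by refitting on the selected
subset under the identical folds and comparing ROC/AUC.

## Pipeline, determinism, problem sizes

One global seed fans out to per-stage seeds via `SeedSequence`, so
stages are independently reproducible; reruns with the same config
produce an identical manifest hash (the output directory is excluded
from the hash). The manifest records every applied parameter — notably
τ, w, tolerances and the seed — plus per-stage row/feature counts, so no
default is silent. The built-in demonstration and regression phantom is
32 × 32 pixels (1,024 spectra, ~540 axis points, 9 spectral lines), and
the test batteries use 8–32 pixel grids, 60–200 sample matrices and
200–1,000 Monte-Carlo replicates: sizes chosen so the full suite runs on
a laptop-class single core in well under a minute per module while still
exercising every statistical property at meaningful power.

## Known limitations

* Continuous-mode (shared-axis) profile input only; processed-mode
  imzML must be resampled upstream.
* Binary classification only (one-vs-rest multiclass is out of scope).
* Calibration is affine; nonlinear (TOF-style) mass laws are not
  modelled.
* The off-sample filter is a reference-correlation criterion; it
  captures the intent of dedicated off-sample tools without reproducing
  any specific package's scoring.
* k is fixed by the user (default 2); no automatic model-order
  selection.
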