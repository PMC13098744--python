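# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic phantoms do and do not
emulate, and the known limitations.

## Data model

A study is a registry of specimens, each tied to a patient and carrying two
class labels: the pathologist's (ground truth) and the clinician's initial
call. The *effective* class is the pathologist's unless they could not
classify the specimen, in which case the clinician's label is used; this
fallback is logged. The emulated cohort reproduces the published study
structure: 45 specimens from 26 patients (20 normal / 14 cancer /
11 metaplasia, six of them Barrett's), ten clinician/pathologist
disagreements, seven pathologist-unclassifiable specimens, and eight
patients contributing both normal and cancer tissue. Patient assignment
within those constraints is deterministic (patients 1–8 normal+cancer,
9–14 cancer+metaplasia, 15–19 normal+metaplasia, 15–26 one normal each);
any assignment honoring the marginals would do, and this one is fixed for
reproducibility.

Features live in a pandas DataFrame keyed by specimen id with
`modality.descriptor` column names, so downstream per-modality operations
need no side tables. Missing measurements are NaN and serialize as empty
CSV cells — never sentinel numbers. Class-mean imputation (used for
classification and ranking only, not for significance testing) replaces
each hole with the mean of the observed values of that feature in the same
class, which preserves per-class means exactly; a (feature, class) group
with no observed value raises an explicit error.

## Saturation and ROIs

Pixels with intensity ≥ 0.95 × detector capacity are excluded everywhere
("within 5% of capacity" read inclusively, the conservative choice).
Detector capacity is a required per-modality configuration value because
bit depths differ between instruments. ROIs are circles that must fit
inside the grid; extraction defaults to a centered circle just inside the
image when no ROI is supplied.

## Autofluorescence

Flat-field correction computes `(image − dark) / (flat − dark)` and
rescales by the mean gain so a scene equal to the flat maps back to its
original intensity level. An emission long-pass filter is *admissible* for
an excitation line only when its cut-on lies strictly above the excitation
wavelength (a long-pass at or below the line passes excitation light); the
647-nm excitation therefore has no admissible filters in the published set
and produces no narrowband or phasor features. Narrowband values for
consecutive admissible cut-ons c_i < c_{i+1} are mean(c_i) − mean(c_{i+1}),
so they telescope: their sum equals the first minus the last long-pass
mean. The pseudo-spectrum anchors each band value at its interval midpoint
and interpolates linearly onto a uniform 32-point grid (configurable); the
phasor terms are raw forward-DFT coefficients (F₀-normalization available
by flag, off by default since the zeroth-order intensity is kept as its own
feature). ROI standard deviations use the population form (divide by N):
the ROI pixels are the whole region, not a sample from it.

## Hyperspectral

Reflectance is sample/white per band and pixel. Binned means tile
[470, 900) nm into 43 half-open 10-nm intervals and are computed *before*
unit-interval normalization, preserving the original intensity scale.
Normalization maps the mean spectrum to [0, 1]; constant spectra map to
zero with a warning. The phasor, polynomial and Fourier descriptors are
computed on the full-resolution normalized mean spectrum (not the binned
one — the alternative reading; a flag switches the phasor to the raw
spectrum). The fourth-order polynomial is fit in a [0, 1]-rescaled
wavelength coordinate for conditioning and its coefficients are reported in
that coordinate, lowest order first. "First 10 frequency terms" means
harmonics k = 1..10; the DC term is excluded because it duplicates the
phasor I. The resulting HSI inventory is 150·2 + 43 + 5 + 5 + 10 = 363
features; the originating study reports 365 without an enumerable
breakdown, so the inventory here is the derivable one and is configurable.

## OCT

Texture slices are min–max quantized to 64 gray levels (configurable; a
balance between co-occurrence stability and sensitivity) and symmetric
normalized GLCMs accumulated at distance 1 along 0°/45°/90°/135°. The 13
classical Haralick statistics are computed per direction and averaged over
the directions where they are defined; correlation is undefined (NaN) when
a direction's co-occurrence marginals are degenerate. Sum variance uses the
sum-average-centered form. Entropies are base-2.

Annular frequency features take the centered 2-D FFT magnitude of a
fixed-size ROI (the fixed size is enforced as a contract so frequency axes
are comparable across specimens) and average it over 10 equal-width radial
bins from 0 to the Nyquist frequency (0.5 cycles/pixel); the annulus count
is configurable since no canonical value exists.

The attenuation coefficient tiles the lateral plane into non-overlapping
10×10-pixel tiles and assembles each tile's mean depth profile. The tissue
surface is the profile argmax; the noise floor is mean + 2·std of the
above-surface samples; the fit region runs from the surface to the first
depth below the floor. A log-linear least-squares slope gives μ in mm⁻¹
via the z pitch — deterministic and closed-form, preferred over nonlinear
refinement. Tiles with fit R² < 0.5 are discarded; the sample value is the
mean over surviving tiles, or missing with a diagnostic if none survive.
Under the fully developed speckle model, the logarithm of a tile-mean
profile keeps the true slope (the speckle factor has unit mean), which is
why log-linear fitting is unbiased here; recovery is ~0% error noiseless
and ~1% mean error under default speckle at 100 tiles.

## Mueller-matrix polarimetry

Generator states default to the canonical full-rank six: horizontal,
vertical, ±45° linear and the two circular states (the instrument's actual
states are accepted via configuration). Per pixel, M solves
min‖O − M·S‖ in least squares over the stacked input/output Stokes
vectors; the solve is exact for noiseless data and pixels producing
non-finite entries or m₀₀ ≤ 0 are marked invalid — mirroring the way real
reconstruction software drops wavelengths it cannot process.

The Lu–Chipman factorization uses the original order M = M_Δ·M_R·M_D:
the diattenuation vector is the first row of the m₀₀-normalized matrix;
M' = M·M_D⁻¹; the depolarizer submatrix comes from the eigenvalues of
m′(m′)ᵀ with its sign from det m′; Δ = 1 − |tr m_Δ|/3; the retarder is
M_Δ⁻¹·M′ with R = arccos(tr M_R/2 − 1), the standard element combinations
for linear retardance and the circular component, and the fast axis from
the antisymmetric part, reported in [0, π) with the branch tie resolved to
0. Physicality screening is minimal by design (m₀₀ > 0 and
|m_ij|/m₀₀ ≤ 1 + 10⁻⁶); out-of-range recovered properties invalidate the
pixel rather than being clipped, so range violations are visible, and pure
polarizers (|D| = 1) report D and P but flag the retarder/depolarizer split
degenerate. Cloude filtering is out of scope.

## Screening

The preliminary ranking p-value for correlation reduction is the paired
Wilcoxon p, falling back to the unpaired p for features without paired
coverage (logged). Pearson correlations use pairwise-complete specimens
because imputation is reserved for classification. The reduction is
iterative — always the currently largest |r| above 0.85, ties broken
lexicographically, the member with the larger p removed (equal p keeps the
earlier column) — making the output deterministic and guaranteeing the
postcondition max pairwise |r| ≤ threshold, which is asserted on every run.
Features with fewer than three complete observations are excluded from
correlation and retained by default.

Exact test distributions are used when the smaller group has ≤ 12
observations and no ties; otherwise the tie/continuity-corrected normal
approximation. All-zero paired differences give p = 1 with a warning.
Benjamini–Hochberg runs separately per modality and separately for the
paired and unpaired p families, at q = 0.1. (The level is an FDR level:
BH controls the false discovery rate, not the family-wise error rate.)

## Ranking, classification, evaluation

Gini importance is the forest's normalized mean decrease in Gini impurity
(100 trees, unlimited depth, √p candidate features per split, fixed seed —
the classical defaults, since no canonical hyperparameters exist for this
problem). The scatter ratio S_B/S_W is affine-invariant per feature;
S_W = 0 with distinct class means is flagged infinite and sorts above all
finite scores, ties lexicographic.

Feature ranking runs *inside* each leave-one-out training fold by default,
so selection never sees the held-out specimen (a structural test asserts
this); a "global" mode reproduces the alternative protocol in which
features are ranked once on all data — the two can differ noticeably at
this sample size, which is why both are exposed. LDA uses the lsqr solver
with automatic shrinkage because top-k covariances are routinely singular
at LOO fold sizes. The positive class is cancer (or the pooled abnormal
group). ROC curves sweep unique scores with simultaneous steps on ties;
AUC is trapezoidal and equals the Mann–Whitney U statistic divided by
n₁n₀, an identity the tests check to 10⁻¹².

## Synthetic phantoms

The generators produce the statistical structure the analysis assumes, not
biophysically realistic images:

- **Spectral phantom** — a smooth two-Gaussian latent emission spectrum
  (the simplest shape with a nontrivial phasor signature), shifted per
  class, sampled into HSI bands under a smooth lamp spectrum (removed again
  by white-reference correction) and integrated above each long-pass cut-on
  for the AF images; per-pixel multiplicative amplitude jitter (default 5%)
  and a configurable fraction of pixels forced to detector capacity.
- **OCT phantom** — Beer-law decay below a tissue surface at 15% depth,
  multiplied by fully developed speckle (unit-mean exponential), optionally
  smoothed to a class-dependent correlation length; additive noise floor
  above the surface. Volume 60×60×120 voxels over 2.6 mm depth by default.
- **Mueller phantom** — per-pixel depolarizer ∘ linear retarder media with
  small spatial parameter jitter; Stokes outputs for the six canonical
  states plus additive Gaussian noise (σ = 0.01 default). Wavelengths with
  missing Mueller data are injected at the published incidence (8/45 at
  405 nm, 1/45 at 473 nm, 6/45 at 632 nm) and recorded in ground truth.

Default class effects (attenuation 1.5/2.0/2.5 mm⁻¹, retardance
0.2/0.35/0.5 rad, depolarization 0.35/0.45/0.55, texture scale 1/1.5/2 px,
spectral shift 0/10/20 nm for normal/metaplasia/cancer) are chosen to be
comfortably detectable at the cohort's sample size, since the originating
study reports no quantitative effect sizes; `null()` and `pli_only()`
presets zero them out entirely or confine them to polarization. Image
grids are kept small (32² AF, 24²×150 HSI, 60×60×120 OCT, 24² Mueller) —
the analysis consumes ROI statistics, so grid size buys runtime, not
fidelity. A feature-level generator (Gaussian features with a configurable
class shift and mixed paired/unpaired patients) supports statistical
calibration experiments where image content is irrelevant.

Because the phantoms have Gaussian/exponential noise, no spatial
heterogeneity within a specimen, no inter-patient random effects and no
cross-modality correlation, passing tests demonstrate the *pipeline's*
correctness and selectivity — not that real tissue is separable, nor the
realism of any particular feature's distribution.

## Calibration checks and problem sizes

The suite verifies: type-I error of the unpaired test in [0.03, 0.07] at
α = 0.05 over 500 null features (40 specimens); mean leave-one-out AUC of
null feature studies within 0.5 ± 0.1, measured over 15 replicates at 20
specimens per class — at much smaller fold sizes LOO with per-fold
selection shows the well-known pessimistic bias (the training fold is
imbalanced against the held-out specimen's class), which is a property of
the estimator, not a bug; end-to-end AUC ≥ 0.9 with PLI-dominated feature
selection when class effects are confined to polarization; attenuation
recovery within 1% noiseless and 10% under speckle over 20 seeds; and the
Lu–Chipman round trip within 10⁻⁸ over 1000 random media.

## Known limitations

- Feature totals are phantom-inventory totals (661 with the default
  configuration); published per-modality totals (90 AF / 365 HSI / 49 OCT
  / 170 PLI) are not exactly derivable from the described operators and
  filter sets, so inventories are configurable rather than forced.
- No image co-registration across modalities; features are ROI aggregates
  by design.
- No instrument-specific demodulation (e.g. Savart-plate channeled
  polarimetry): PLI input begins at Stokes images or Mueller fields.
- Reproducing the originating study's screening counts on its deposited
  dataset requires downloading that dataset; the loader and per-modality
  reduction driver are in place, and the corresponding test reports the
  expected retained-feature counts when the data are present locally.
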