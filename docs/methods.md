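# Methods

This note documents the models, the synthetic data, the numerical choices and
the limitations of `rsipipe`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute.

## Four-compartment RSI model

The diffusion-weighted signal at voxel v and b-value b (s/mm²) is modeled as

    S_v(b) = Σ_{i=1..4} c_i(v) · exp(−b · D_i),   c_i(v) ≥ 0,

a linear combination of exponential decays over four tissue compartments —
restricted intracellular water (C₁), hindered extracellular water (C₂), free
water (C₃), vascular/pseudo-diffusion (C₄). The compartmental coefficients
D₁..D₄ are fixed, not estimated. Their default values
(1.0·10⁻⁴, 1.8·10⁻³, 3.6·10⁻³, 1.0·10⁻² mm²/s) are **externally sourced**
from the prostate RSI literature, are not a result of this package, and are
overridable in `RSIFitConfig`.

Per-voxel coefficients are the exact nonnegative least-squares solution,
computed by enumerating all 2⁴ coefficient supports: for each support the
restricted unconstrained least-squares problem is solved for every voxel in a
single matrix product, and the feasible (all-nonnegative) candidate with the
smallest residual is kept. Since the NNLS optimum coincides with the
restricted LS solution on its own support, this enumeration is exact; it is
also fully vectorized over voxels, which is what makes whole-volume fits
cheap. A plain least-squares mode (`nonnegative=False`) exists for testing.
Voxels with all-zero signal fit to exact zeros (not NaN) to keep downstream
map arithmetic safe. Magnitude data are fit as-is; no Rician bias correction
is applied.

RSIrs(v) = `rsirs_scale` · c₁(v) / median{T2W(u): u in prostate mask};
RSIrs_max is its maximum over the mask. `rsirs_scale` defaults to 1.0: the
absolute scale convention used for published biomarker thresholds (values
near 200) is not recoverable from the printed material, so the scale is
exposed rather than guessed. Empty masks and nonpositive T2W medians are
errors rather than silently propagated NaNs.

## Synthetic multi-center cohort

The generator emulates the structure the evaluation machinery assumes:

- **Sites.** Each `SiteProfile` carries a patient count, csPCa prevalence,
  BN-BC fraction (biopsy-naïve at MRI with subsequent biopsy confirmation —
  the evaluation subset) and a Rician noise scale. The default seven profiles
  use the published per-center counts (1846 patients; 721 csPCa; 876 BN-BC);
  prevalence and BN-BC mix are the exact count ratios, so summing expected
  per-site counts reproduces the published totals.
- **PI-RADS.** Drawn from two label-conditional 5-vectors, chosen once so
  that the implied marginal distribution at 39% prevalence approximates the
  published overall PI-RADS distribution. The conditional pair implies a
  PI-RADS AUC of ≈0.84 against the label. Per-site conditionals are not
  public; all sites share the default pair.
- **Anatomy.** The prostate is a centered ellipsoid (semi-axes 0.35 of the
  field of view); csPCa-positive patients receive one spherical lesion placed
  fully inside the mask (radius drawn from `lesion_radius_range`, shrinking
  over retries, error after bounded attempts). Inside the lesion the C₁
  fraction is multiplied by `lesion_c1_contrast` (default 2.5) and fractions
  renormalized. These are deliberately the simplest shapes that make mask
  logic and the biomarker separation property testable.
- **Signals.** Compartment-fraction fields are the configured background
  fractions plus a small smooth random field, clipped and renormalized so
  fractions are nonnegative and sum to one at every voxel. DWI volumes follow
  the forward model above with S₀ = 100; the T2W volume is a deterministic
  smooth radial profile (so that, at zero noise, the in-mask median is
  identical across patients and biomarker separation is exact). Noise is
  magnitude-MRI Rician: √((S+n₁)² + n₂²) with n ~ N(0, σ·S₀), σ the site's
  `noise_sigma` as a fraction of S₀.
- **Geometry.** Default grid 32×32×24 at 1×1×3 mm (the analysis drivers use
  16×16×12 at 2×2×3 mm); voxel indices 0-based, world coordinates via the
  NIfTI affine, masks resampled nearest-neighbor. b-value default set
  {0, 200, 1000, 2000, 3000} s/mm² — at least four b-values are required for
  a determined four-compartment fit; the real acquisition protocol is not
  public.

**What this does not emulate** — and therefore what passing tests do *not*
establish about clinical data: realistic anatomy and lesion morphology,
scanner artifacts (eddy currents, B₀ distortion, gradient nonlinearity),
variability in lesion conspicuity, Gleason grade beyond the binary label, and
inter-reader PI-RADS variability. Because every synthetic lesion carries the
same strong multiplicative C₁ contrast, RSIrs_max separates the classes
essentially perfectly at the default noise level — synthetic model-2 AUCs
saturate near 1.0, unlike the ≈0.73 reported on clinical data. The synthetic
cohort validates the *machinery* (fitting, training, leak-free evaluation,
statistics), not clinical effect sizes.

## Classifiers

`DenseNet3d` is a 3D densely connected network: a 3×3×3 stem convolution
(width follows `in_channels` from config), four dense blocks whose layers
each apply BN→ReLU→3×3×3 convolution adding `growth_rate` channels, and
1×1×1 compressing transitions (factor 0.5) with average pooling. The
full-size configuration reproduces the published channel schedule
(64, 256, 128, 512, 256, 1024, 512, 1024); the `tiny` preset
(8 stem features, growth 4, blocks 2/2/2/2) keeps the same topology at test
scale. After adaptive average pooling, the head is either a direct linear map
to the two-way output, or — for the RSI variant — linear(final→5), concat of
the RSIrs_max scalar, linear(6→2). The scalar is z-scored on the training
set before fusion (flag `standardize_scalar`).

Training: two-way softmax cross-entropy (equivalent to binary cross-entropy
for a 2-class output, which is how the binary objective is implemented
here), AdamW with decoupled weight decay 0.01 (conventional default; not
dictated by the source design), base learning rate 10⁻³, linear warm-up over
10% of total steps (a conventional choice, exposed as `warmup_steps`) then cosine
annealing to zero. A stratified `internal_val_fraction` (10%) is withheld
strictly for best-epoch selection; the default selection metric is validation
AUC (`val_loss` available). Training is deterministic under the seed
(numpy generator; single-threaded BLAS kernels are deterministic).

The networks run on a minimal reverse-mode tensor autograd engine written in
numpy (`rsipipe.nn.autograd`): im2col 3D convolution, batch normalization,
average pooling, concatenation, fused softmax cross-entropy. Gradients are
verified against central finite differences in the test suite. This keeps the
package runnable on a single CPU with no deep-learning framework; the cost is
speed, which is why the analysis uses the `tiny` preset on small grids.

## Image preparation

All modalities are resampled to the T2W grid (trilinear; masks
nearest-neighbor and re-binarized; non-overlapping fields of view are an
error). ADC is the per-voxel least-squares slope of −log S over the b ≤ 1000
s/mm² subset (conventional clinical ADC; configurable), with nonpositive
signals clamped to ε before the log. The high-b channel is the acquired
volume with the largest b-value (simplest defensible choice; an extrapolated
alternative can be substituted). Classifier inputs are cropped/padded around
the prostate-mask bounding-box center and z-scored per channel using
bounding-box statistics (with a σ floor, so constant channels normalize to
zero); bounding-box rather than whole-volume statistics stabilizes
normalization across synthetic "sites". Augmentation is conservative and
label-safe: left-right flips, integer translations ≤2 voxels, ±5%
multiplicative intensity jitter, all drawn from a seeded generator.

## Fusion models

Models 1, 2, 5, 6, 7 are maximum-likelihood logistic regressions (statsmodels,
unpenalized) with Wald 95% CIs; PI-RADS enters as a numeric 1–5 covariate
(nonlinearity deliberately not modeled, matching how such fusions are
reported clinically — a documented limitation). Under (quasi-)perfect separation — which a saturated
synthetic biomarker can produce — the fit falls back to a weakly L2-penalized
solution (scikit-learn, C=10) and the spec is flagged. Fusion coefficients
are refit within every LOCO fold on training patients only; fitting on any
patient from the current held-out site is a hard `LeakageError`. Predicted
probabilities are clipped to (10⁻⁹, 1−10⁻⁹).

## Evaluation statistics

- **AUC**: tie-corrected Mann–Whitney statistic (ties count ½), computed via
  ranks; cross-checked in tests against pair counting and scikit-learn.
- **Average precision**: step-wise sum of precision × recall increments.
- **Operating point**: the *largest* threshold c (positive call at score ≥ c)
  with sensitivity ≥ 0.90, specificity reported there. This rule reproduces a
  discrete PI-RADS cutoff without interpolation and applies identically to
  continuous scores. The threshold is re-derived inside every bootstrap
  resample, so the threshold itself gets a CI.
- **NRI**: the continuous (category-free) variant — no clinical risk
  categories are defined for these scores, and NRI values depend on this
  choice, so it is called out here: [P(up|event) − P(down|event)] + [P(down|nonevent) −
  P(up|nonevent)], ties contributing zero.
- **IDI**: change in discrimination slope (mean predicted probability in
  events minus nonevents).
- **Bootstrap**: percentile method, 2.5th–97.5th percentiles, default 10 000
  resamples (drivers) / reduced counts in tests for runtime; patients are
  resampled freely or within site strata (`clustering='by_site'`; whole-site
  cluster resampling deliberately not the default — the sites are the
  inference target, their strata are preserved). Resamples that lose a label
  class are redrawn and counted. The paired-difference p-value is
  2·min(frac ≤ 0, frac ≥ 0), floored at 2/n_boot. Point estimates report the
  bootstrap median as primary alongside the full-sample value.
- **Bonferroni**: α/m for the seven model comparisons, 0.05/7 → 0.007.
- **Heterogeneity**: fixed-effect inverse-variance pooling with per-site
  bootstrap SEs; Q = Σw(θ−pooled)², I² = max(0, (Q−(k−1))/Q)·100, clamped to
  [0, 100]. Sites lacking a label class in the BN-BC subset are excluded from
  forests.

## LOCO protocol

Each rotation holds out one center entirely; a stratified 10% of the
remaining patients (matched by csPCa label) is the internal validation set
for best-epoch selection; the rest trains the networks. The smallest center
is kept permanently in training when there are more than two sites (the
`always_train="smallest"` policy; explicit site lists supported). The three
id sets partition the cohort; aggregated held-out predictions contain each
rotatable-site patient exactly once, enforced by a duplicate check that
raises `LeakageError`. Evaluation is restricted to BN-BC patients, with
model 1 (PI-RADS) as the ΔSpec/NRI/IDI/p-value reference.

## Problem sizes

The analysis drivers use a 281-patient, seven-site cohort on 16×16×12 grids
with the tiny network preset and 6 training epochs per fold; the test suite
uses 2-site, 60-patient cohorts on 12×12×8 grids with 4 epochs, 150–1000
bootstrap resamples depending on the statistic, and a 200-dataset coverage
simulation at n=300. These sizes were chosen so the complete analysis and
suite run in minutes on one CPU while still exercising every 3D code path.

## Known limitations

- The clinical effect sizes are not reproducible from synthetic data by
  design; only arithmetic identities (count sums, Bonferroni, self-reference
  nullity, the channel schedule) and statistical properties are asserted.
- The RSIrs scale convention (published thresholds near 200) is not
  recoverable; `rsirs_scale` is exposed instead.
- PI-RADS is modeled as numeric/linear in the logistic fusions.
- The numpy networks are CPU-bound; the full-size DenseNet configuration is
  provided for fidelity of the architecture definition, not for training at
  clinical scale.
- I² with few sites and imbalanced samples is unstable; it is reported for
  structure, not inference.
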