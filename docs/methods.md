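# Methods

## What the package models

`ovotrait` implements a comparative analysis of avian eggshell pigmentation:
how the concentrations of the two dominant eggshell pigments —
protoporphyrin IX (red-brown background and spotting) and biliverdin IXα
(blue-green background) — relate to a species' phylogeny, its egg coloration
as measured from photographs, and its life-history and nesting ecology. The
statistical core is (1) Pagel's λ as a measure of phylogenetic signal and
(2) phylogenetic generalized least squares (PGLS) with all-subsets AIC
model averaging. Because no suitable multi-species pigment dataset is openly
deposited, the package ships a synthetic-data generator with known ground
truth; every downstream stage is validated against that truth.

## Trait evolution model

Under Brownian motion (BM) with rate σ², the trait values at the tips of a
rooted phylogeny are multivariate normal with covariance σ²·V, where
V[i,j] is the branch length shared by tips i and j (root to their most
recent common ancestor). Pagel's λ multiplies the off-diagonal of V:
λ = 0 is phylogenetic independence, λ = 1 full BM covariance. For a trait
vector x the mean μ and rate σ² are profiled analytically
(μ̂ = (1ᵀV⁻¹x)/(1ᵀV⁻¹1), σ̂² = rᵀV⁻¹r/n), leaving a one-dimensional profile
likelihood in λ that is maximised over [0, 1] by a 21-point grid followed by
bounded scalar refinement to 1e-6; both boundaries are evaluated explicitly,
since BM-like traits typically place λ̂ exactly at 1. The confidence
interval is the profile-likelihood set {λ : ℓ(λ) ≥ ℓ(λ̂) − χ²₁(0.95)/2},
found by bisection and truncated to [0, 1]. A star phylogeny (all shared
branch lengths zero) makes λ unidentifiable; the fit is returned flagged
with λ̂ = 0. Likelihoods use a dense Cholesky factorisation — problem sizes
here are at most a few hundred tips, so no pruning algorithm is needed.
λ is fitted to species means, consistent with the regression stage.

## PGLS and multimodel inference

PGLS estimates β̂ = (XᵀV(λ)⁻¹X)⁻¹XᵀV(λ)⁻¹y with Gaussian errors of
covariance σ²·V(λ). The ML σ̂² (divisor n) enters the likelihood; standard
errors use the unbiased divisor n − p and t-based confidence intervals with
n − p degrees of freedom. By default λ is re-estimated by joint ML within
each candidate model (a fixed value can be supplied instead); the AIC
parameter count is then k = p + 2 (σ² and λ), or p + 1 with fixed λ. AIC
(not AICc) ranks models, matching the averaging protocol implemented here;
AICc is available on the results object.

The candidate set is all subsets of the predictors (guarded at 12), with an
optional set of always-included terms. For the life-history analysis the
response is a log10 pigment concentration; the six optional covariates are
nest location (ground/off ground), brood parasitism (yes/no), nest type
(cavity/open), log10 adult body mass, clutch size, and eggshell thickness in
mm, and the *other* pigment's concentration is forced into all 2⁶ = 64
models. This reproduces the published table structure: the co-pigment term
has relative importance 1.00 and its "N containing models" equals the size
of the confidence set. For the colorimetric analysis the predictors are
background L*, a*, b* and maculation % (16 models, no forced term), with
pigment concentration as the response.

Akaike weights w_i ∝ exp(−Δ_i/2) are computed over the full candidate set;
the confidence set is the smallest weight-ranked prefix with cumulative
weight > 0.95 (ties broken by fewer parameters, then enumeration order).
Averaging is conditional ("natural"): each term is averaged over the models
containing it with weights renormalised over those models; the
unconditional standard error follows Burnham & Anderson,
SE = Σ w̃_i·sqrt(SE_i² + (β_i − β̄)²), with normal-quantile 95% and 90%
CIs. Relative variable importance is the summed (set-renormalised) weight of
containing models. Significance is CI-based only (95% bold, 90% asterisk in
the report); no multiple-testing adjustment is applied, as the inference is
interval-based.

Choices worth flagging: body mass is log10-transformed before fitting
(passerine masses span orders of magnitude); shell thickness is stored in µm
in the trait table but modelled in mm, where effect sizes of order 1–10 are
physically sensible; binary covariates enter as 0/1 indicators (open = 1,
off-ground = 1, parasitized = 1); conditional averaging was chosen over
zero-substitution full-model averaging because "N containing models" and
variable importance are native to it.

## Colorimetry

Images are linear RGB (Rec. 709/sRGB primaries) in [0, 1]; the reader
decodes 8/16-bit PNG/TIFF and can optionally apply sRGB gamma decoding.
The stages are:

- **Segmentation.** Otsu's threshold (256 bins, lowest threshold on ties
  within a 1e-9 relative tolerance) on Rec. 709 luminance; the brighter
  class is the egg; the largest connected component is kept. Dark spots can
  fall below the threshold: interior ones become holes and rim ones
  notches, so a morphological closing (disk radius 6 px) precedes hole
  filling — the egg is a solid object.
- **Pose.** Eggs are analysed long-axis-horizontal with the broad end at
  lower x. Inputs are auto-corrected with exact transforms only: a 90°
  rotation when the mask's vertical coordinate variance exceeds the
  horizontal, and a mirror flip when the heavier half (0.5% tolerance) lies
  at high x. Arbitrary-angle rotation is out of scope.
- **Subsample.** A circle of radius sqrt(A/(3π)) — one third of the egg
  area A — centred at the egg centroid with x replaced by 0.88·centroid-x,
  which moves it toward the broad end and away from rim curvature. Members
  are clipped to the mask and the achieved fraction logged. Note the 0.88
  rescale is a property of the standardized framing, so pipeline output is
  invariant to translation only up to ~0.12 of the shift in circle
  placement (a fraction of a percentage point of maculation in practice).
- **Color conversion.** Linear RGB → XYZ (matrix) → CIELAB (CIE 1976,
  6/29 knee), D65 reference white by default and configurable.
- **Maculation.** 2-means clustering of the subsample's (L*, a*, b*)
  pixels, Lloyd iterations to 1e-8 with a deterministic
  permutation-invariant initialisation (means of the bottom/top L*
  deciles). The darker-centroid cluster is the maculation. If the converged
  centroids are closer than ΔE = 8 the subsample is treated as a single
  population (no maculation): without this guard a spotless egg would be
  split in half by pixel noise. The threshold sits far above the noise
  spread (< 1 ΔE at the default noise level) and far below the
  background–spot separation (~28 ΔE).
- **Summary.** Maculation % of subsample members; background mean/SD of
  L*, a*, b* over non-maculated members (population SD); egg area as mask
  pixels × pixel_scale², with the scale configured rather than read from a
  scale bar.

Clustering on L*a*b* rather than grayscale was a deliberate choice — it
uses the full chromatic separation between spots and background.

## Synthetic data generator

The generator's defaults mirror the emulated study: 71 species, 3 eggs per
species, an ultrametric pure-birth tree (birth rate 1 per unit time), both
pigments with full phylogenetic signal (λ = 1, σ² = 0.05 on the log10
scale, giving across-species SDs of ~0.5 dex on trees of height ≈ 4.8), a
cross-pigment correlation of 0.6 in the independent components, and target
repeatabilities of 0.76 (protoporphyrin) and 0.62 (biliverdin).

- **Tree.** Pure birth: while k lineages exist the next speciation waits
  Exp(k·b); after the n-th lineage appears one further Exp(n·b) interval is
  simulated and tips are extended to it (the convention of standard tree
  simulators; it avoids zero-length cherries, which would make V singular
  at λ = 1). Expected stem-inclusive height is Σ_{k=1..n} 1/(k·b).
- **Covariates.** Six independent unit-rate BM liabilities; binary traits
  (nest type, nest location, parasitism) threshold their liability at the
  median, guaranteeing balance and phylogenetic plausibility; thickness,
  clutch size and log10 mass are affine transforms of standardised
  liabilities (0.09 ± 0.02 mm, 4.5 ± 1.2 eggs, 1.2 ± 0.35 log10 g).
- **Pigments.** log10 biliverdin = linear predictor (its default effects) +
  BM error; log10 protoporphyrin adds 0.36 × biliverdin. The default effect
  sizes are the model-averaged estimates of the emulated study's
  life-history table (e.g. thickness 6.47 per mm for biliverdin, nest type
  0.19 for protoporphyrin). Replicate noise is i.i.d. Gaussian on the log10
  scale, with SD back-computed from the target ICC and the realised
  between-species variance. Gaussianity on the log scale is an assumption;
  nothing in the emulated protocol pins the within-species distribution.
- **Per-area concentrations** = per-mass × thickness × shell density
  (2.0 g/cm³) × 10^N(0, 0.06), which yields mass-vs-area Spearman
  correlations near the published 0.94–0.97 range.
- **Images.** Background CIELAB and spot coverage are driven by
  standardised replicate pigment values with the study's observed sign
  structure: L* = 70 − 12 z_p − 10 z_b, a* = 12 + 6 z_p − 9 z_b,
  b* = 25 + 3 z_p − 4 z_b, coverage = 0.12 + 0.10 z_p (clipped). Eggs are
  plain ellipses (no ovoid asymmetry — sufficient for every downstream
  operator) spanning ~84% × 76% of a 400 × 300 px canvas at 0.1 mm/px;
  spots are random disks (radius 2–4.5 px) added until ground-truth
  coverage is within ±0.02 of target (coverage above 0.9 is refused);
  Gaussian pixel noise (SD 0.004) is added after the masks are frozen, so
  masks are exact for the noise-free rendering. Spot colors derive from the
  background (ΔL* = −28, Δa* = +8, Δb* = −8).
- **Determinism.** The tree, trait and image streams are spawned from the
  master seed via `SeedSequence`; identical configs give bit-identical
  outputs, including rendered TIFFs (checksummed in the run manifest).

What the generator does **not** emulate: real eggshell texture and gloss,
UV reflectance, camera optics and calibration, ovoid egg geometry,
collection-age fading, or realistic covariate distributions beyond their
phylogenetic structure. Passing recovery tests therefore demonstrates the
correctness of the algorithms under the stated generating model, not
field-readiness for arbitrary photographs.

## Repeatability and correlation

Repeatability is the one-way ANOVA ICC,
(MS_B − MS_W)/(MS_B + (k₀ − 1)·MS_W) with k₀ the harmonic-mean-adjusted
replicate count; negative estimates clip to 0. The 5th/95th percentiles
come from a percentile bootstrap over species (default 2000 draws,
seeded). Spearman's ρ is Pearson correlation of average ranks (scipy);
constant inputs return NaN with a warning.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single CPU: 100-replicate λ-recovery batches on 71-tip trees, 200-replicate
coverage checks for the regression stage, a 4 × 4 color-by-coverage grid
for colorimetry, and Monte-Carlo oracles of 1000–6000 replicates for the
closed-form checks. Dense Cholesky factorisations are used throughout;
covariances are validated for positive definiteness and a condition-number
diagnostic accompanies singular-matrix errors. Otsu ties resolve to the
lowest threshold within 1e-9 relative tolerance (exact ties are common on
coarse histograms under floating-point reordering).

## Known limitations

- Arbitrary-angle pose correction is unsupported (exact 90°/mirror
  transforms only).
- The 180°-rotation invariance of the pipeline is exact only when the broad
  end is detectable; on the generator's symmetric ellipses re-orientation
  is a no-op and the subsample lands on the mirrored spot field, so
  summaries agree only to sampling precision.
- Conditional model averaging can bias averaged estimates away from zero
  for weakly supported predictors relative to zero-substitution averaging;
  importance values and N-containing-models counts are the intended
  inferential quantities.
- The λ CI uses the χ²₁ profile cutoff, which is conservative at the λ = 1
  boundary.
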