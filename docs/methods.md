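# Methods

`plantnni` implements an image-based pipeline for diagnosing the
nitrogen (N) status of a rosette-forming leafy vegetable (pakchoi,
*Brassica campestris* ssp. *chinensis* L.) from top-view RGB
photographs. This note documents the models, the defaults and their
rationale, the synthetic data the package is validated on, and the
known limitations.

## The nitrogen nutrition index

The critical N concentration Nc(DM) is the minimal shoot N
concentration (g·kg⁻¹ DW) that sustains maximal dry-matter
accumulation at shoot biomass DM (g·plant⁻¹). It is modeled as a
power function

    Nc = a · DM^b

fitted by ordinary least squares in log-log space. The nitrogen
nutrition index of a sample with measured shoot N concentration Nt is

    NNI = Nt / Nc ,

with NNI < 1 indicating deficiency, NNI ≈ 1 optimal nutrition and
NNI > 1 surplus. Two points deserve emphasis:

* **The exponent b may be positive.** Under a frequent-small-dose
  fertilization regime, shoot N concentration can *rise* with biomass
  rather than dilute; the fit does not constrain the sign of b.
* **Which treatments feed the fit.** Following the Justes-type
  procedure, a treatment is *N-limiting* at a date when some higher
  dose shows significantly greater shoot biomass (omnibus one-way
  ANOVA across treatments, then one-sided Welch comparisons against
  every higher dose, both at α = 0.05); per-date labels are aggregated
  across dates by majority. We deliberately compare against *every*
  higher dose, not only the adjacent one: the operational definition is
  "extra fertilizer increases biomass", and with closely spaced doses
  the adjacent contrast often has no power while the top-dose contrast
  does. The dilution curve is then fitted on the records of the
  **highest-dose N-limiting treatment only**. That treatment sits
  closest to the critical boundary, so its N concentration tracks Nc;
  pooling the unfertilized control in would drag the curve toward
  deficiency-driven concentrations far below the boundary.
* **Reference biomass.** Nc at a date is evaluated at the mean biomass
  of the non-N-limiting treatments at that date (configurable to a
  named treatment).

Reported NNI values are rounded half-up to two decimals (the reporting
convention of agronomic NNI tables); classification uses a tolerance of
0.005 around 1 for "optimal", i.e. exactly the values that print as
1.00.

The package also bundles the published summary tables of the pot
experiment it emulates (per-treatment biomass and N concentration at
six dates, the per-date critical concentrations, the resulting NNI
table and the 23-feature screening outcome) as machine-readable
constants; `plantnni fixtures` writes them to CSV. One cell of the
bundled published NNI table (unfertilized control, day 21, printed
0.57) is inconsistent with its own printed inputs, which give
39.07 / 69.16 = 0.56; the package reproduces the arithmetic, not the
misprint.

## Segmentation

The segmentation flow is the classic excess-green pipeline for plants
on a near-white background, in this order:

1. ExG = 2G − R − B per pixel in signed arithmetic, kept inside the
   band [40, 200] (inclusive at both ends);
2. BT.601 grayscale (0.299 R + 0.587 G + 0.114 B, rounded), pixels
   with gray ≥ 240 rejected;
3. intersection of the two masks;
4. morphological opening with a 3 × 3 square element;
5. removal of 8-connected components smaller than 1/10 of the mask
   area, then filling of 4-connected background holes (components of
   the complement not touching the border) smaller than 1/20 of the
   mask area. "Mask area" is recomputed at the moment each filter
   runs.

Boundary inclusivity, the structuring-element size and the
object/hole connectivities are under-determined by the verbal recipe;
they are pinned here and in the config for reproducibility. An empty
mask at any stage raises a "no plant detected" error rather than
returning silently.

## Phenotypic features

Exactly 65 features per plant, in a fixed order.

**Color (45).** Mean, population standard deviation, median, range and
coefficient of variation for each of R, G, B, L, a, b, H, S, V,
computed over plant pixels only — a white background would otherwise
dominate every statistic. Channel scalings follow the common 8-bit
toolchain conventions: H on the half-degree scale [0, 180), S, V and L
scaled to [0, 255], a and b offset by +128. CV is defined as 0 when
the channel mean is 0 (flagged).

**Texture (6).** Haralick features — contrast, dissimilarity,
homogeneity, energy, correlation, angular second moment — from a
grey-level co-occurrence matrix at distance 1, averaged over the four
canonical directions (0°, 45°, 90°, 135°), symmetric and normalized,
256 grey levels: the canonical configuration. Background pixels inside
the mask bounding box are assigned a sentinel level and all pairs
touching the sentinel are discarded before normalization, so only
plant-plant pixel pairs count. With a single occupied grey level the
matrix is degenerate and correlation is 1 by convention. The
implementation is checked against an exhaustive pair-enumeration
oracle on small patches at 1e-12 precision.

**Geometry (14).** Computed on the largest connected component:
area, perimeter, axis-aligned bounding-box width/height, convex hull
area, minimum-area rotated rectangle sides (reported long, short),
ellipse major/minor axes, minimum enclosing circle radius, equivalent
diameter √(4A/π), aspect ratio, extent and solidity. The ellipse axes
come from the moment-equivalent ellipse of the region (the standard
regionprops definition) rather than a contour least-squares fit; for
solid leaf silhouettes the two agree closely, and regions too small
for an ellipse fall back to the rotated-rectangle sides. Lengths scale
with `mm_per_px` and areas with its square; the default calibration of
1.0 reports pixel units, since no camera calibration is assumed.

## Feature screening

Features are z-scored (population SD; constant columns map to 0 with a
warning) and screened by a per-date one-way ANOVA across treatments.
A feature is selected only if p < α (strict) at *every* sampling date;
p-values are floored at 1e-300 before the −log10 transform used for
plotting against the threshold line −log10(0.05) = 1.301. The omnibus
F p-value is what the rule consumes — post-hoc grouping is not needed
to decide selection. No multiple-testing correction is applied across
the 65 features, deliberately: the all-dates conjunction is itself a
severe filter (null calibration in the test suite shows the per-date
rejection rate at the nominal 5% and essentially zero features
surviving all six dates by chance). The published 23-feature outcome
(16 color, 3 texture, 4 morphology) ships as the preset `paper23`
usable without re-screening.

## NNI regression

Three regressors of NNI on the screened features, each tuned by
10-fold cross-validation on a 75/25 train/test split (train size
rounded half-up), selecting the candidate with minimal mean CV RMSE;
exact ties go to the most parsimonious candidate (smallest
mtry/cost/size first). One seed drives the split, the fold assignment
and every stochastic learner, and the fold assignment is shared across
algorithms.

* **RF** — 300 trees, `mtry` ∈ {2, 5, 8} features per split.
* **SVR** — RBF kernel; cost and gamma each over the 17 powers of two
  2⁻⁸ … 2⁸ (289 candidates); ε fixed at 0.1.
* **NN** — a single-hidden-layer feed-forward network with logistic
  hidden units, weight decay ∈ {0, 0.1, 0.01} and hidden size
  ∈ {2, 5, 9}, trained by L-BFGS on the sum of squared errors plus the
  decay penalty from a small uniform random initialization. The output
  unit is logistic by default, so predictions live in (0, 1) and
  saturate at 1.000 — adequate below the optimum but a hard ceiling
  under N surplus, where NNI reaches ≈ 1.1; this is a documented
  limitation, and `nn_output="linear"` removes it. The network is
  implemented in-package (numpy forward/backward pass, scipy L-BFGS)
  because no installed library provides this exact
  single-hidden-layer/logistic-output/decay configuration.

Features are z-scored with training-set statistics which are then
applied to test data. Normalizing before splitting (as statistical
packages often do) leaks test information into the scaler; the
stricter order is the default here and the difference is negligible at
these sample sizes.

Feature importance is permutation-based for all three algorithms:
%IncMSE = 100 · (MSE_permuted − MSE_base) / MSE_base, averaged over a
configurable number of permutations. Using one mechanism across
algorithms makes scores comparable; algorithm-native importances
(e.g. out-of-bag %IncMSE for RF) differ in detail.

## Evaluation

Goodness of fit is the adjusted determination coefficient of the
linear regression of measured on simulated NNI with one predictor,
R²adj = 1 − (1 − R²)(n − 1)/(n − 2), alongside RMSE and MAE of the raw
predictions. Scenario agreement uses the same regression: RE is its
residual standard error (n − 2 denominator) divided by the mean
measured value (in percent), and accuracy is the Pearson correlation.
Both RE and accuracy are invariant under affine transformation of the
predictions.

The test set is stratified by N status (measured NNI > 1 surplus,
< 1 deficient; exactly 1.00 belongs to neither and is flagged) and by
growth stage (default: final sampling date = harvest, all earlier
dates = seedling; the mapping is configurable because "seedling
period" can also be read as a single early date). Narrowing the
measured range inside a stratum attenuates R² and accuracy by plain
variance restriction even when absolute errors are unchanged — this is
the mechanism behind poor apparent performance under N surplus, and
the package's synthetic experiments reproduce exactly that signature
(low R²/accuracy with small RE in the surplus stratum).

## Synthetic data

No images from the emulated study are deposited, so the generator
provides the ground truth every stage is tested against.

**Trajectories.** For relative supply s = dose / 0.191 g N·pot⁻¹,
biomass grows geometrically from 0.02 g toward 0.62 + 0.75 s^0.8 g
over 42 days, and latent NNI relaxes exponentially (rate 0.09 d⁻¹)
from 0.77 + 0.29 √s toward 0.26 + 0.82 √s — unfertilized plants
decline from ≈ 0.77 to ≈ 0.26 while fertilized treatments hover around
1 to 1.12, matching the emulated experiment's ranges. N concentration
follows the generative link n = NNI · a · DM^b with a = 76.0 g·kg⁻¹,
b = 0.12, chosen once by a log-log fit of the published critical
concentrations against the published non-limiting biomass trajectory.
Because the link is exact (and re-imposed after noise), the nitrogen
module recovers (a, b) to machine precision on noiseless data — a
strong parameter-recovery check. Noise is multiplicative Gaussian with
a configurable CV (default 0.05) on biomass and N concentration.

**Images.** A plant is a rosette of 6–12 overlapping filled ellipses
radiating from the canvas centre with angular jitter, on a
near-white/grey background (≈ 232 ± 2 grey). Leaf color interpolates
in HSV from pale yellow-green (hue 80°, low saturation) to deep green
(hue 120°, higher saturation, lower value) as a logistic function of
NNI; with this ramp the mean ExG over the plant rises strictly from
≈ 82 to ≈ 168, inside the default segmentation band. Within-leaf
texture is per-pixel Gaussian *intensity* noise (equal in all three
channels, amplitude decreasing with NNI), which perturbs the grey-level
co-occurrence structure while leaving per-pixel ExG untouched.
Projected size scales with √biomass, so mask area is proportional to
biomass. Elliptical leaves exercise all 14 geometry features
(convexity deficits between leaves, elongation, rotated rectangles).

What the renderer does **not** model: illumination gradients, shadows,
specular highlights, soil or pot pixels, leaf venation, occlusion by
neighbouring plants, perspective. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline and the
qualitative transferability of its statistical behaviour — not
photographic-grade segmentation accuracy on real greenhouse images.

## Problem sizes and numerical choices

The packaged experiments use a 4-treatment × 6-date design with 16
replicates (384 images, 240 × 240 px) for model-recovery runs, 50
renders for the segmentation fidelity suite, 200 Monte-Carlo
repetitions for the ANOVA null calibration, and 2 replicates
(48 images) for end-to-end smoke/determinism runs. Degenerate inputs
are mapped, not crashed: CV with zero mean → 0, GLCM with one grey
level → correlation 1, constant features → z-score 0, zero-variance
regressions → R² 0 / accuracy undefined, all flagged with warnings.
All randomness flows from one seed through `numpy` `SeedSequence`
spawning, and a pipeline run writes a manifest whose hash covers the
configuration and every output file digest; equal seeds give
bit-identical runs.
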