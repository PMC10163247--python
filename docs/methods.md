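# Methods

## Scope and data model

The package classifies pixels of two deciduous tree species from 4-band
multispectral reflectance (blue, green, red, NIR; values in (0, 1]).  Its
inputs are either labeled pixel tables (CSV: `label, b1..b4`), labeled
rasters (4-band float TIFF plus a label TIFF), or the built-in synthetic
scene generator.  All reported accuracies are validation accuracies under
a deterministic equidistant split: pixels at 0-based positions 2, 5, 8, …
form the validation third, the rest the modelling two-thirds.  The split
is positional, so the caller controls independence assumptions through
sample ordering; pixels are treated as independent samples.

## Spectral index set

Twenty-two formula categories over the band reflectances are enumerated
across bands: the seven single-band transforms (identity, square, cube,
square root, cube root, exp, ln) over 4 bands give 28 features; of the
two-band categories, three are symmetric in the band pair (sum, product,
product-over-sum) and contribute the 6 unordered pairs each; the remaining
ten are order-sensitive and contribute all 12 ordered pairs.  Two of the
printed two-band categories are character-for-character duplicates of
ln R_i/(R_i − R_j) and are collapsed onto a single canonical category —
the only reading under which the total 28 + 18 + 120 = 166 is
arithmetically consistent.  Antisymmetric categories keep both band
orders as distinct features (they differ by sign, and both orders appear
in practice among the sensitive indices).  Natural logarithms are used
throughout.

Numerical guards: any evaluation whose denominator magnitude falls below
1e−12 on the reflectance scale, or whose log argument is ≤ 0, yields NaN
rather than ±inf.  NaNs propagate to screening as pairwise-complete
exclusions and mark rows unclassifiable for the SVM (cloud models drop
the affected dimension from the joint product, with a warning).

## Association screening

The default score is the point-biserial correlation — the Pearson
correlation between the feature and a 0/1 label coding (the
lexicographically larger species codes as 1, making the sign convention
reproducible).  The alternative `logistic` method fits a univariate
logistic regression on the standardized feature and reports
sign(β)·√(McFadden pseudo-R²); it is a documented interpretation, bounded
in [−1, 1] and sign-consistent with the point-biserial score, provided
for fidelity to the description of the screening as a logistic-regression
correlation analysis.  Strength categories follow the |r| bands
[0, 0.30) micro, [0.30, 0.50) real, [0.50, 0.80) significant,
[0.80, 1] high.  Ranking is by |r| descending with lexicographic
tie-breaks; the default sensitive set is the top 10.  No multiple-testing
correction is applied (deliberately: the screen is a ranking device, not
an inference procedure).

## Cloud-model classifier

Backward generator: Ex is the sample mean; En = √(π/2) · mean absolute
deviation from Ex (for a normal population this estimates the standard
deviation); He = √(S² − En²) with S² the unbiased (n−1) sample variance.
For light-tailed samples S² < En² occurs routinely and He is clamped to 0
(with a warning at the call level; classifier fitting silences it since
clamping there is expected behaviour, not an anomaly).

Membership of a query x₀ is exp(−(x₀ − Ex)²/(2 En′²)).  The default
inference mode is **deterministic** (En′ ≡ En): reported accuracies are
then exact functions of the data, which matches the fixed accuracy
figures such classifiers report in practice and makes reruns
bit-identical.  **Stochastic** mode draws En′ ~ |Normal(En, He²)| m times
(seeded) and averages the kernel; with m = 1,000 the estimate is stable
to < 0.01 against a 10×-larger draw at moderate He/En.  En = 0 yields
membership 1 at Ex and 0 elsewhere (warned).

Multi-dimensional membership is the axis-aligned product of per-dimension
memberships — equivalently exp(−Σ (x₀k − Exk)²/(2 En′k²)) — with no
cross-feature covariance, matching the construction of separate
per-feature cloud models.  All species in one classifier share the same
feature set; the 3-D feature triple is chosen by 1-D validation accuracy
(not by r), with lexicographic tie-breaks.  Maximum determination assigns
the species with the largest joint membership; exact ties go to the
lexicographically smallest species id and are flagged.  In deterministic
1-D form the decision rule is provably "minimize (x₀ − Ex)²/(2 En²)",
which the test suite checks against an independent brute-force oracle.

## GLCM texture

The source band (NIR by default — the most discriminative band) is
quantized to 32 equal-width levels over its observed range; each pixel's
window (3×3, 5×5 or 7×7, reflect-padded at borders) yields a
co-occurrence matrix accumulated over the four distance-1 offsets
(0,1), (1,0), (1,1), (1,−1), symmetrized and normalized.  Quantization
depth, offsets, symmetry and source band are config-exposed since the
method description fixes none of them; the defaults are standard Haralick
practice.  Eight parameters are computed per window (mean, variance,
homogeneity = Σp/(1+(i−j)²), contrast, dissimilarity, entropy with
0·ln 0 = 0, second moment = Σp², correlation with NaN where a marginal is
degenerate).  "Uniformity" and "homogeneity" name the same parameter Y3.

## SVM baseline

C-support-vector classification with an RBF kernel, gamma 0.5, C 1,
shrinking on; degree 3, coef0 0.001, nu 0.5, epsilon 0.001 and p 1 are
carried in the config for fidelity but are inert under C-SVC + RBF.
Features are standardized to zero mean and unit training variance before
the kernel — gamma 0.5 presumes a standardized scale.  Rows with missing
features are dropped at fit time (warned) and marked unclassifiable at
prediction.

## Synthetic scene generator

The generator emulates the statistical structure the analysis assumes,
not radiative physics.  Per species, band reflectances are independent
truncated normals on (0, 1]; rasters are vertical-strip mosaics of
single-species patches whose within-patch variation is a Gaussian-kernel-
smoothed noise field (kernel sigma = the species' `texture_scale`, in
pixels), renormalized to unit marginal variance so the correlation length
does not alter per-pixel spread, then clipped to (0, 1].

Preset parameters (chosen once, with the rationale below):

| preset | band means Q | band means R | sd | texture scale Q/R |
|---|---|---|---|---|
| autumn | 0.080, 0.100, 0.070, 0.350 | 0.085, 0.105, 0.085, 0.320 | 0.02 | 8 / 4 px |
| winter | 0.120, 0.140, 0.160, 0.280 | 0.125, 0.150, 0.210, 0.220 | 0.02 | 8 / 4 px |

* Standardized NIR separation is 1.5 (autumn) vs 3.0 (winter), and winter
  adds a 2.5-sd red-band separation of opposite sign — leaf fall exposes
  trunk/branch signal — so red/NIR difference and ratio indices become the
  strongest discriminators in winter, with a combined separation near
  3.9 sd.  Autumn keeps only weak blue/green/red differences (0.25–0.75
  sd).  This reproduces the intended ordering of phase difficulty without
  claiming the original imagery's numbers.
* Texture scales are several pixels for **both** species (stand-scale
  patchiness from crown size and canopy density, not per-pixel sensor
  noise).  This matters: if within-class variation were spatially white,
  window-averaged texture statistics such as the GLCM mean would cancel
  it and the texture branch would out-discriminate per-pixel spectra,
  inverting the relationship the study design assumes.  With correlation
  lengths of 8 px (Q) and 4 px (R), a 3×3–7×7 window cannot average the
  variation away, the class signal stays predominantly spectral, and the
  2:1 scale difference still gives GLCM contrast/homogeneity genuine
  discriminative power.

What the generator does **not** emulate: band-to-band correlation within
a pixel (supported structurally but off by default), mixed pixels at
stand boundaries beyond window overlap, topographic/illumination trends,
sensor noise models, and any phase-dependent *texture* change —
`texture_scale` is identical in both presets.  A consequence worth
stating plainly: in the autumn preset the texture branch can match or
exceed the weak autumn spectral signal (texture difficulty is
phase-independent here, spectral difficulty is not), whereas the original
imagery showed spectral features ahead in both phases.  Passing tests on
these presets therefore demonstrate correctness of the machinery and the
winter-phase orderings, not performance on real imagery.

## Pipeline and evaluation

Stages run in order: split → 166 indices → screening on the modelling
partition only (no validation leakage) → one 1-D cloud model per
sensitive index → 3-D cloud model on the accuracy-ranked triple → texture
branch (per window: 8 texture features from the labeled raster, split,
1-D models per parameter, 3-D on the top triple) → SVM baselines (1-D per
sensitive index, 3-D on the cloud-selected triple) → one comparison table
row per fitted model.

Overall accuracy is micro-averaged (correct/total); the macro average is
reported alongside because validation class counts need not be equal.
Per-species texture window selection follows validation accuracy per
species.  Everything downstream of the seed is deterministic in
deterministic membership mode; reruns are bit-identical.

## Problem sizes and numerical choices

Default study sizes — 1,000 pixels per class for the spectral branch and
a 96×96 raster (4,608 pixels per class) for the texture branch — were
chosen so Monte-Carlo error on a validation accuracy is a few tenths of a
point (binomial SE ≈ 0.6 points at n = 666), small against the effects of
interest (winter−autumn ≈ 17 points; spectral−texture ≈ 5 points in
winter).  Denominator guard 1e−12; He clamp at 0; NaN policy as above;
all tie-breaks lexicographic and deterministic.

## Known limitations

* Two classes only in the shipped presets (the types support more).
* The logistic screening score is one defensible reading of an
  under-specified description; the point-biserial default is used for all
  headline results.
* Cloud models are univariate-product classifiers; strongly correlated
  feature triples add little over the best single feature — visible in
  the results as 3-D ≈ best 1-D.
* TIFF raster I/O carries no georeferencing; coordinate metadata is out
  of scope.
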