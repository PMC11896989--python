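# Methods

`chlorotex` implements a complete retrieval chain for leaf chlorophyll
content (LCC, SPAD units) of banana canopies from hyperspectral imagery:
vegetation/soil segmentation, spectral and textural feature extraction,
correlation screening, a two-pair feature-combination search, multivariable
regression under cross-validation, and per-pixel mapping. Because the kind
of UAV campaign this pipeline targets rarely ships with public imagery, the
package includes a first-class synthetic scene generator with known
per-pixel truth; every downstream stage is validated against that truth.

## Synthetic scene model

A scene is a two-plot banana field: circular plant crowns on a regular
planting grid (pitch 50 px, matching the 50×50 px ROI protocol) over bare
laterite soil. Plot 1 (left) draws crown LCC from the lower part of the
SPAD range, plot 2 (right) from the upper part, emulating a leaf-development
and a fruit-development stage; at the default 74 ground points the split is
30/44. A ground point's SPAD value is its crown-mean LCC plus meter noise
(sd 1.2 SPAD — the field protocol averages hundreds of readings, so the
residual is small).

**Leaf optics.** Reflectance is a visible baseline (0.34) with Gaussian
absorption wells at 446, 550 and 682 nm scaled by a saturating response
`1 − exp(−LCC/18)`, blended into a 0.55 NIR plateau by a logistic red-edge
ramp (width 7 nm) whose midpoint sits at 730 nm at the reference SPAD 57.5
and shifts +0.25 nm per SPAD unit. The choice over a full radiative-transfer
model keeps the generator dependency-free and analytically checkable: red
reflectance is provably strictly decreasing in LCC, the red-edge inflection
strictly increasing, and soil (a dim featureless ramp) is separable from
vegetation by NDVI with a wide margin (soil < 0.12, vegetation > 0.55).
The strong saturation constant (18 SPAD) encodes that over 45–70 SPAD the
pigment wells are nearly full — which is exactly why red-band indices
saturate and red-edge indices, driven by the midpoint shift, retain
sensitivity; it also concentrates the sweep-detectable information at the
730 nm midpoint.

**Information structure.** Three spatial fields decide what each feature
family can measure:

* *Optical-expression mismatch* (sd 6 SPAD, correlation length ≈ 30 px):
  the chlorophyll the spectra express differs from the SPAD-measured
  content by a smooth leaf water/thickness/surface term. Because it moves
  spectra along the same manifold as LCC itself, no combination of spectral
  indices can remove it; it caps purely spectral models at a pooled R²
  around 0.6, the regime such campaigns report.
* *Brightness level and roughness*: a multiplicative brightness field and a
  fine-scale (3×3) jitter whose local amplitude ("crown roughness") both
  correlate with the LCC map at `texture_corr` (default 0.6) — vigorous
  crowns are brighter and rougher. The independent components of both
  drivers are smooth at ROI scale (correlation length 25 px), so ROI
  averaging cannot silently turn either channel noise-free. Roughness is
  readable at first order only by local texture statistics (CON, DIS, VAR,
  ENT), which is why texture features add genuine information beyond
  ROI-mean indices rather than merely duplicating them.
* *Ambient light*: a long-range additive field (amplitude 0.012) plus
  per-band sensor noise (sd 0.004) as ordinary nuisances.

All randomness flows from one seeded generator; identical configurations
reproduce scenes bit-for-bit. What the generator does **not** emulate:
BRDF, cast shadows, atmospheric effects, sensor PSF, mosaicking seams, or
real banana leaf biochemistry beyond the qualitative red/green absorption
and red-edge behavior. Tests passing on these scenes therefore demonstrate
that the pipeline recovers what it is pointed at under a controlled, fully
specified forward model — not that any specific accuracy transfers to a
particular field campaign.

## Segmentation

NDVI from the 802/682 nm bands; the statistic-based threshold minimizes the
misclassification count over candidate cuts at midpoints of the pooled
sorted labeled sample, ties toward the larger cut. Classification is strict
(`NDVI > threshold` is vegetation; boundary pixels are soil). Fixed
operating points (e.g. 0.48/0.5 per plot) can be supplied instead of the
derived cut. No morphological cleanup is applied.

## Features

Twenty vegetation indices are registered — eleven original forms and nine
red-edge analogues — with band requirements at the nominal centers 802,
770, 710, 706, 682, 550, 510, 446 nm, resolved to the nearest cube band at
run time. Formula conventions worth noting: MSR = (N/R−1)/√(N/R+1), the
MDVI family is the renormalized difference (N−R)/√(N+R), the OSAVI family
is (1+0.16)(N−R)/(N+R+0.16), RDVI is the plain difference N−R, and
CI_green uses 770/510 nm. Indices are evaluated on vegetation pixels only;
zero denominators yield NaN, which ROI averaging excludes with a count
rather than silently dropping points.

Texture features come from the gray-level co-occurrence matrix of a 3×3
window around each pixel of the first three principal-component images
(PCA fit on vegetation-pixel spectra; sign convention: the peak loading
element is positive). Defaults the source protocol leaves open, fixed here
and exposed in configuration: 32 gray levels from a *global* min–max
quantization over vegetation pixels (so ROI means are comparable across
points); the four distance-1 offsets accumulated into one symmetric
matrix; entropy in bits; the Haralick correlation with COR := 1 at zero
marginal variance. Per-pixel windows (rather than one matrix per ROI) match
the local-detail rationale of a 3×3 window; the per-ROI alternative would
trade locality for smaller estimator variance. The fast numba path is held
to 1e−10 agreement with a naive pair-counting oracle.

The 50×50 ROI window of a point at (r, c) spans rows [r−25, r+24] and
columns [c−25, c+24], clipped at image borders; masked-out and NaN pixels
are excluded from means and counted, and points with empty ROIs are dropped
into a report.

## Screening

Pearson |r| and the maximal information coefficient, both against point
SPAD, with strict selection above 0.8. MIC follows the original MINE
estimator (α = 0.6, c = 15): for each grid shape within the budget
n^α, one axis is rank-equipartitioned and the other optimally cut by
dynamic programming over clumps; the normalized maximum over shapes and
orientations is the statistic. The DP is exact for the quantity it
optimizes (verified against exhaustive cut enumeration at small n), and at
n = 74 the 0.8 cutoff is stringent: independent uniforms exceed it in well
under 1% of replicates.

## Two-pair combinations and multivariable models

Every VI×TF pair is combined as a ratio (TF/VI), a normalized difference
((VI−TF)/(VI+TF)) and a plain difference (VI−TF) and regressed linearly
against LCC — 160 combinations per form per PC image with the full
registries. RMSE uses 1/n; ties in the ranking break lexicographically so
reports are deterministic.

Four regression families run under seeded 10-fold cross-validation with
pooled out-of-fold scoring (pooled rather than fold-averaged: stable at
n = 74 and matching a single predicted-vs-measured scatter):

* **PLSR** — latent-variable count by inner 5-fold CV over 1..min(10, p);
* **ARS** — additive piecewise-linear adaptive regression splines, forward
  hinge-pair selection to at most 21 terms, backward pruning by GCV
  (penalty 3);
* **SVR** — RBF kernel, (C, γ, ε) by inner grid search
  (C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.1, 1, 10}, ε ∈ {0.01, 0.1, 1})
  on standardized features;
* **GPR** — constant × RBF + white-noise kernel, marginal-likelihood
  maximization with 5 restarts; returns a predictive sd per sample.

All standardization and hyperparameter selection happen inside training
folds only; a shuffled-target probe keeps the pooled null R² at zero. The
default CV seed is 20240426 and is recorded with every result.

## Auxiliary analyses

The red-edge sweep substitutes each cube band in 702–742 nm into the
red-edge slot of every red-edge index (fixed slots untouched), refits the
linear LCC model and reports the R² profile and argmax band. On default
scenes most red-edge indices peak within one band of the generator's
730 nm information center; the simple-difference and soil-adjusted forms
(REDVI, OSAVI_re) deviate, as their formulas respond more to band level
than to midpoint position.

SPAD verification converts 95%-ethanol extract absorbances at 649/665 nm
into chlorophyll a + b (Ca = 13.95·A665 − 6.88·A649,
Cb = 24.96·A649 − 7.32·A665; solvent-specific coefficients are
configuration-swappable) and fits lab_chl = a·e^(b·SPAD) by nonlinear least
squares initialized from the log-linear fit. At the 18-sample scale typical
of a lab calibration the rate parameter is recovered within three standard
errors.

LCC maps apply either the best two-pair linear model (closed form:
slope·combination + intercept) or a trained multivariable model per
vegetation pixel; soil is nodata, and GPR maps carry a per-pixel predictive
sd layer. Map-time textures reuse the training scene's global quantization
bounds so feature semantics are identical between calibration and mapping.

## Problem sizes and numerical choices

The default scene is 300×700 px × 164 bands — the smallest grid that
places 74 non-overlapping 50×50 ROIs in the 30/44 plot layout — and runs
the full pipeline in a few minutes on one core. PCA uses the exact
eigendecomposition of the 164×164 band covariance. Degenerate cases are
explicit errors rather than silent results: constant images quantize to
zero with a warning, constant combinations are skipped and recorded,
windows with no accumulable pixel pairs yield NaN textures, and
non-separable segmentation samples warn. Known limitations: the MIC
estimator's equipartition approximation can differ from an unrestricted
two-axis grid optimum (as all MINE-family estimators do); ARS fits an
additive basis (no interaction terms); and the generator's simplified
optics mean absolute accuracies on synthetic scenes say nothing about any
specific sensor or crop beyond the mechanisms modeled.
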