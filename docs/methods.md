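# Methods

This note documents the models implemented in `islandcarbon`, the
defaults and why they were chosen, what the synthetic scenes do and do
not emulate, and the numerical choices made where the design was open.

## Pipeline model

The package implements LiDAR-sample-to-full-coverage carbon mapping on a
shared 30 m grid (0.09 ha cells, projected meters, top-left origin,
cell-center registration, half-open cell intervals; codecs enforce this
contract and never resample silently).

**Ground classification.** Candidate ground seeds are the lowest return
in each 10 m × 10 m kernel (kernels anchored at the cloud's min corner;
elevation ties break by x then y so the result is deterministic). The
ground set then grows by progressive densification: for every
unclassified return, a local plane is estimated from its `neighbors`
(default 8) nearest classified returns and the return is admitted when
it lies less than `vertical_tolerance` (1.5 m) above that plane,
iterated to a fixed point. Two plane estimators are available behind
`plane=`: a least-squares fitted plane (default; batched 3×3 normal
equations with a 1e-6 ridge so degenerate neighborhoods degrade smoothly
toward the horizontal case) and a literal horizontal plane at the
neighbor-mean elevation. Raising the tolerance only ever admits more
returns, never fewer.

*Known limitation:* vegetation whose height is within roughly the
vertical tolerance of the ground (≈ 1.5–2 m shrub) is not separable
from terrain by any filter of this family — returns from 0–1.5 m
vegetation are legitimately admitted and lift the local plane, after
which slightly taller returns follow. On scenes whose canopy clears the
tolerance by a margin, classification is exact (tests assert zero
admitted canopy there, and ≥ 95 % ground recall everywhere).

**Surfaces.** The DTM linearly interpolates classified ground returns
on their Delaunay triangulation (nearest-neighbor fill inside hull
gaps), with cells farther than 2 × kernel size (20 m) from any ground
return set to nodata — ground returns are sparse under dense canopy, so
a wide support radius is appropriate. The DSM interpolates all first
returns at 1.12 m. Because first returns are dense (sub-meter spacing at
≥ 4 pulses m⁻²), the DSM support cutoff is 2.5 × its resolution; a wide
cutoff here would extrapolate the surface tens of meters past the flown
footprint and leak biased height into edge cells of the aggregated
product. TCH = DSM − DTM clamped at zero, then block-averaged to 30 m by
assigning each fine cell to the coarse cell containing its center
(handles the non-integer 30/1.12 ratio exactly as a mean); coarse cells
under 50 % valid coverage become nodata.

**Scaling model.** `HoldoutForestRegressor` is an ensemble of CART
regression trees (scikit-learn trees underneath). Per tree, a 250-row
holdout is drawn without replacement and set aside; the tree trains on a
bootstrap of the remaining rows. Defaults: 250 trees, ⌈p/3⌉ features per
split, min leaf 5, unlimited depth — conventional regression-forest
settings. When the training table has ≤ 250 rows the holdout shrinks to
⌊n/5⌋ with a warning. Ensemble predictions are means over trees, so they
are bounded by the training response range; mapped predictions are
clamped at zero and any cell with an invalid predictor is nodata.
Feature encoding: the categorical vegetation layer is one-hot expanded;
circular aspect becomes a sin/cos pair. Each original layer is one
*factor*: permutation importance shuffles a factor's full column block
jointly (per-column shuffling of one-hot classes is available by
permuting single-column groups). Importance of factor f is
mean over trees of (MSE\*ᵢ − MSEᵢ)/MSEᵢ computed on each tree's private
holdout — the relative increase in holdout MSE under permutation. A tree
with a perfect holdout fit contributes MSE\*ᵢ scaled by the holdout
response variance instead (logged edge case). A sum-normalized share
over positive importances is reported alongside the raw statistic.

**Carbon conversion.** ACD = a·TCH^b with a = 3.744 Mg C ha⁻¹ m⁻ᵇ,
b = 1.391 (the regional plot-aggregate calibration; both are config
values). `fit_tch_acd` refits the law from (TCH, plot-ACD) pairs:
log-log OLS provides starting values and is reported alongside the
nonlinear least-squares fit, with R² and RMSE on the original scale.
When calibration error is multiplicative (lognormal), the log-scale fit
is the maximum-likelihood estimator and should be preferred; unweighted
NLS is unbiased but markedly less efficient there. The simulation tests
therefore judge exponent recovery on the log-scale estimate.

**Inventory cascade.** Tree AGB (kg) comes from a species-specific
diameter model when the species is listed *and* the dbh is inside the
model's declared validity range; otherwise from the pantropical general
model AGB = 0.0673·(ρD²H)^0.976 with wood density resolved species →
genus mean → 0.5 default, and height taken from the record, else a
species height model, else the general ln-quadratic diameter–height
model ln H = 0.893 − E + 0.760 ln D − 0.0340 (ln D)² with environmental
stress E (default 0.1; larger E, shorter trees). Every estimate carries
a provenance code so the cascade is auditable. The bundled species
model/wood-density tables are *synthetic placeholders* (filenames say
so): coefficients are data, not code, and real deployments must supply
their own CSV bundle. Cluster plots follow the FIA geometry — four
subplots; microplot r = 2.07 m (stems < 12.7 cm dbh), subplot r = 7.32 m,
macroplot r = 17.95 m (stems ≥ 12.7 cm under the EXPFOR protocol). Each
size class expands by its own cluster area 4πr²; summed per-hectare AGB
× 0.48 gives plot ACD. Tree ferns pass through the same cascade.

**Uncertainty.** Paired (predicted, reference) ACD over the LiDAR
footprint are split into 30 equal-width bins on the predicted value
(quantile bins behind a flag); per-bin RMSE is smoothed by a
count-weighted polynomial (degree 2 by default, 1–4 allowed; persisted
in the JSON model file). Bins with fewer than 5 pairs merge rightward.
Applied to a map the polynomial is clamped at zero; a percent layer
(RMSE/ACD) is optional. The fit has no random element, so refits are
identical.

**Validation and accounting.** Map ACD at each plot is the mean of
valid cells in a 3 × 3 window (~1 ha) centered on the plot's cell
(windows truncate at edges; all-nodata windows drop the plot with a log
entry). R² is the squared Pearson correlation of the paired values —
the convention in LiDAR–plot comparisons — with the 1 − SSE/SST variant
reported alongside. Zonal reports give per-zone area (cells × 0.09 ha),
mean ± sd density, and stock in Tg (10⁶ Mg); zones rasterize from
polygons by cell-center containment, and stocks are exactly additive
under any zone partition. The forest mask is configurable
(vegetation-class list by default, TCH ≥ 2 m fallback) and every
area/stock number depends on it. The protection summary assigns
unlabeled tenure to "unprotected" (logged) and reports the protected
share of total stock.

## Synthetic scenes

The generator emulates the statistical structure the pipeline needs:
terrain as Gaussian-filtered white noise plus a planar trend (roughness
amplitude 40 m, correlation length 80 m over the scene); 30 m predictor
layers as smooth latent fields with plausible couplings (precipitation
partly tracks elevation; humidity and cloud track precipitation; covers
are a softmax on the simplex, FC + NPV + bare = 1; six vegetation
classes from a thresholded latent, including native- and
alien-dominated forest labels; four fire layers); canopy height built
*from* those layers — intercept 10 m plus configured effects on
standardized predictors (defaults: FC 8 m, MAP 4 m, per-class offsets)
plus Gaussian noise (sd 1.5 m), clipped to [0, 60] m and zeroed where
bare cover exceeds 0.55, so bare patches exist. With noise 0 the canopy
is an exact function of the stack, which is what makes oracle tests
possible. Canopy is block-constant within each 30 m cell.

LiDAR simulation: pulses on a jittered grid at 0.5 m spacing (4 m⁻²
floor enforced). A pulse over canopy intercepts it with probability
equal to local FC (first return at canopy top + 7 cm Gaussian noise) and
additionally reaches the ground with probability max(1 − FC, 0.05) — the
floor guarantees a recoverable DTM everywhere. Gaps mean a
DSM-minus-DTM map measures the *gap-weighted* mean canopy height FC·h,
not the stand top height; the scene therefore exposes both `canopy`
(top height h) and `canopy_mean_coarse` (FC·h), and plot targets follow
the latter, since stand carbon also scales with cover. A
`full_coverage` acquisition (every canopy pulse returns canopy and
ground) is provided for noise-free oracle checks, where 30 m TCH matches
block truth to < 0.25 m RMSE.

Inventories: cluster centers are uniform over the scene interior; per
subplot, large-stem records (diameters 12.7 cm + a gamma variate scaled
with local canopy height, heights ~ local canopy ± 12 %) accumulate
until the subplot's per-hectare carbon reaches the power-law target at
the local FC·h, perturbed by lognormal noise (sd 0.10); a Poisson
handful of microplot stems is added. The plot's reference ACD is then
recomputed through the same cascade used for real inventories, so
generated plots honor the power law to within the stated noise plus
one-tree granularity.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: sensor trajectories, waveform or
multi-return physics beyond first/last, occlusion and terrain shadowing,
species-level allometric error structure, co-registration error between
plots and imagery, temporal offsets between acquisitions, and the
spatial covariance of real Hawaiian landscapes. Real-data performance
claims require real validation plots.

## Problem sizes and sampling design

Test and demo scenes are sized for a single-CPU workflow: the end-to-end
demonstration island is 360 m × 360 m (12 × 12 accounting cells,
~300k returns), which exercises the small-table holdout-shrink path by
construction; the importance experiments use 900 m × 900 m scenes
(900 training cells, 250-row holdouts) where LiDAR simulation is not
needed. The demo acquisition covers half the scene as two parallel
north–south strips rather than one contiguous block: a sampling design
must intersect the island's environmental gradients, or the model is
asked to extrapolate into canopy strata it never saw — the same reason
real campaigns spread flight lines across all major forest types.

## Numerical choices

- Ties for kernel-lowest points break by (x, y); all stochastic stages
  consume explicit named seeds; forests, scenes and importance are
  bit-reproducible under a fixed seed.
- GeoTIFF I/O (via tifffile, with pixel-scale/tiepoint/nodata tags)
  round-trips float64 payloads bit-exactly; NaN is the in-memory nodata,
  −9999 the on-disk sentinel.
- Misaligned grids are an error naming both georeferencings; an explicit
  `align` step is the only way to regrid.
- Degenerate inputs: collinear ground points raise; clouds under 3
  points raise; empty plots yield ACD 0; zero-variance responses yield
  constant forests; identity permutations yield exactly zero importance.
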