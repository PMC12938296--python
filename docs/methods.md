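# Methods

## Vulnerability model

The unit of analysis is the pixel-window: a five-year (60-month) slice of
monthly NDVI, temperature, and precipitation, advanced in one-year steps.
Within each window and pixel, every variable is deseasonalized by
subtracting its within-window month-of-year mean and then scaled to zero
mean and unit (population) standard deviation. Deseasonalizing before
z-scoring is a deliberate choice: without it, the regression coefficients
are dominated by the shared seasonal cycle rather than by anomaly coupling.
A switch (`deseasonalize=False`) restores plain z-scoring of raw monthly
values for comparison.

The window regression is ordinary least squares of the standardized NDVI
anomaly on the contemporaneous temperature and precipitation anomalies and
the one-month NDVI lag, over the 59 usable months. An intercept is included;
with centered inputs it is numerically near zero and only guards against
drift. Rank-deficient or non-finite fits are flagged invalid, never raised.

Coefficients are min-max normalized to [0, 1] **across pixels within each
window**. The scope matters: per-window normalization keeps each annual map
internally comparable, at the cost of making every index *relative to the
landscape in that window* — a drift shared by every pixel is invisible by
construction. A pooled mode (min-max across all pixel-windows jointly) is
available via `normalization_scope="pooled"`. Degenerate channels
(max = min, including a single valid pixel) map to 0.5 with a logged
warning. T_norm and P_norm are the window means of *raw* temperature and
precipitation, min-max normalized across pixels in the same way.

The indices follow the exposure–sensitivity–resilience composition
(EI = α+β, SI = α·T_norm+β·P_norm, RI = 1−γ, VI = EI·SI/(1+RI)); under the
normalized-input contract VI is finite and bounded by [0, 4]. Negative raw
coefficients are not truncated before scaling — min-max itself maps the most
negative value to 0, preserving rank information.

## Regime classification

Each pixel's 36-value annual VI series is summarized by its coefficient of
variation (sample sd / mean, percent; bins [0, 20), [20, 30], (30, ∞)) and
classified by a three-model cascade:

- **Linear:** OLS on year; slope t-test; AIC = n·ln(RSS/n) + 2k with k = 3.
- **Piecewise:** continuous two-segment fit, exhaustive search over breaks
  leaving ≥ 5 points per segment (the knot belongs to both); per-segment
  slope p-values from separate OLS t-tests; AIC with k = 5. Significance
  requires *both* segment slopes at p < 0.05. Continuity is imposed; a
  discontinuous variant is not provided (single connected line only).
- **Pettitt:** K = max_t |Σ_{i≤t} Σ_{j>t} sign(x_j − x_i)|, change point at
  the argmax, ties handled by sign(0) = 0. For AIC comparability a two-mean
  step model split at the change point is scored with k = 4 — Pettitt is
  nonparametric, and the step-model likelihood is the minimal device that
  makes the cross-model AIC comparison well-defined.

**Pettitt significance.** The classical asymptotic approximation
p ≈ 2·exp(−6K²/(n³+n²)) is measurably conservative at the series lengths
this pipeline produces (empirical null rejection ≈ 2.5% at a nominal 5% for
n = 36, still ≈ 3.6% at n = 100). Because K is a rank statistic, its null
distribution is distribution-free, so the default p-value is taken from a
seeded Monte Carlo table of K under random permutations (4000 draws, cached
per series length, deterministic). This restores calibration (empirical
rejection 4.2–6.1% at the 5% level in our checks) at negligible cost. The
asymptotic formula remains available (`p_method="asymptotic"`) and is used
automatically for n > 100, where the table would be slow and the
approximation is adequate.

**Cascade.** No significant model → no trend. One significant → that model.
Several → lowest AIC, ties to the simpler model (linear ≺ piecewise ≺
Pettitt-step). If the winning turning point falls within five years of
either series end (inclusive: turning year in [first, first+5] ∪ [last−5,
last]), the pixel is re-evaluated with the simple linear fit — significant →
linear by slope sign, else no trend. An abrupt regime is *defined* by two
significant opposite-signed segment trends (I–D or D–I); a winner whose
segments are same-signed or not both significant (e.g. a pure mean shift)
falls through the same linear re-fit rule. AICc is not applied (plain AIC
throughout); the small-sample correction is a one-line change if wanted.

Turning years of abrupt pixels are binned into 5-year intervals
([1990, 1995), …, [2010, 2015] with the final edge closed); the boundary
rule guarantees surviving turning years lie strictly inside 1990–2015.

## Driver analysis

Thirteen candidate drivers are screened iteratively: each round computes
every feature's VIF (1/(1−R²) from an intercept-included OLS of the feature
on the rest) and drops the single worst if ≥ 10, until all pass; ties break
toward the later column. Screening is idempotent and the per-round VIF
tables are reported.

The regression is XGBoost (`tree_method="hist"`, squared error), with
hyperparameters chosen by 5-fold cross-validation on the 80% training split
only and metrics (R², MSE, RMSE, MAE) reported on the untouched 20% test
split. The default desk-scale grid is trees {100, 300, 500} × depth
{3, 5, 7} × learning rate {0.05, 0.1} × subsample {0.8, 1.0}; a reduced grid
(`SMALL_GRID`) is what the examples, tests, and acceptance script pass, and
is entirely adequate on the synthetic tables (held-out R² ≈ 0.96–0.98 at the
default signal-to-noise).

Attribution uses the exact TreeSHAP algorithm built into XGBoost
(`pred_contribs=True`): per-sample additive contributions whose row sums
plus the base value reproduce the prediction (checked to 1e-4). Importance
is mean |contribution| per feature, normalized to sum to 100.

Partial dependence defaults to the **at-means profile** — other features
held at their sample means — because that is the stated convention this
pipeline reproduces; the conventional averaged-over-data curve is available
(`mode="averaged"`), and the two coincide up to a constant for additive
fits. The grid spans the feature's [1st, 99th] percentile range (50 points).
Thresholds are read off each curve by fitting continuous piecewise-linear
models with 0–2 knots at grid abscissae and selecting the knot count by BIC
(k = 2 + 2 per knot); detected thresholds are the knot positions ordered by
magnitude of slope change. A flat or straight curve yields no thresholds. A
sharp step in the underlying response typically yields two knots bracketing
the jump one grid cell apart — both are reported.

The sampling unit is the pooled pixel-year by default; per-ecosystem
analyses run the identical chain per stable land-cover class, skipping
classes with fewer than 500 samples (flagged, not silently dropped).

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code; every one returns its ground
truth.

- **Land cover:** a grassland-dominated mosaic (58% grassland, 29% forest,
  small shrubland/cropland/wetland shares, 5% nodata) with an exact,
  seed-deterministic fraction of vegetated pixels converting class once at a
  random interior year.
- **Climate-vegetation cube:** fixed 12-month sinusoidal climatologies plus
  white-noise anomalies; NDVI anomalies evolve by the generating recursion
  (defaults α = 0.4, β = 0.3, γ = 0.2, residual sd 0.1 — a strongly coupled,
  stationary regime in which OLS refit of the recursion is unbiased to
  < 0.01 per coefficient at 60 months). Fixed spatial climate gradients
  (temperature along rows, ±6 °C; precipitation along columns, ±20 mm/month)
  give each pixel a persistent hydrothermal rank, as real terrain does —
  without them T_norm/P_norm would be re-randomized every window.
- **Planted vulnerability trends.** Because each window is z-scored, a bare
  drift of (α, β) is invisible: shrinking the coupling shrinks the NDVI
  anomaly variance proportionally, leaving standardized coefficients almost
  unchanged. The drift is therefore planted as a change in the *share* of
  anomaly variance explained by climate — coefficients scaled by the drift
  factor, residual variance compensated to keep the total fixed — which the
  standardized regression recovers in proportion to the drift. The drift is
  applied to a random fraction of pixels (default 0.6) against a backdrop of
  per-pixel baseline coupling heterogeneity (pipeline default scale 0.5–1.0,
  also variance-compensated); both are needed because min-max normalization
  measures pixels *relative to the landscape*: a drift shared by all pixels
  cancels, and drifting pixels necessarily push the non-drifting remainder
  the other way within the frame (a mirrored, weaker opposite pattern in
  anchor pixels is an intrinsic feature of the method, not a generator bug).
- **Driver tables:** features uniform on realistic native-unit ranges;
  collinearity built the way real driver sets acquire it — derived
  quantities regenerated from their physical parents (TEM from TMX+TMN, PET
  from TMX+SR+VPD, AI from PRE+PET, RHU from VPD+PRE, NTL from GI+TMX) — so
  the derived member is unambiguously the high-VIF one; planted responses
  are a grazing plateau at 0.90 SU/ha, soil-moisture and VPD steps at 79 mm
  and 0.39 kPa, and a weak linear precipitation effect, with Gaussian target
  noise (default sd 0.1, ~10% of the combined signal).

Not emulated: spatial autocorrelation of noise fields, sensor radiometry or
inter-sensor harmonization artifacts, lagged/cumulative climate effects
beyond the one-month NDVI lag, and land-cover transition dynamics beyond a
single conversion. Passing tests therefore demonstrate the *machinery* —
recovery of known signals under realistic noise — not performance on any
particular satellite product.

## Numerical choices and problem sizes

Zero-variance series are flagged invalid rather than raised; any non-finite
month invalidates the pixel-window; degenerate min-max ranges map to 0.5
with a warning; Pettitt ties contribute sign(0) = 0; AIC uses
RSS floored at 1e-300 to tolerate exact fits. Resampling is
containing-cell lookup (categorical-safe, idempotent at equal geometry).
Area is pixel count × cell area with no geodesic correction — synthetic
grids are planar; users with real geographic rasters should correct areas
upstream.

The test suite and acceptance script use desk-scale sizes chosen as
representative rather than exhaustive: 500 pixel-windows for coefficient
recovery, 200 replicates for classification rates, 1000 for calibration,
2000–5000-sample driver tables over 10 seeds, and a 20×20 × 480-month
landscape for the end-to-end run. The reduced hyperparameter grid is used
wherever the full grid would add fit time without changing conclusions.

## Known limitations

Min-max scope makes all indices landscape-relative; cross-study VI values
are not comparable. The boundary rule trades sensitivity near the record
ends for robustness. Threshold detection reports knots of a piecewise-linear
readout — for smooth sigmoidal responses the "threshold" is a summary, not
an estimate of a structural break. Only one breakpoint per series is
considered, and no multiple-testing correction is applied across pixels.
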