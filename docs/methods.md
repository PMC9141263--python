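# Methods

## The estimation problem

A national monitoring network observes daily PM2.5 at a few thousand points;
an exposure assessment needs a concentration estimate everywhere. Pure
covariate regression (land-use regression, LUR) captures the deterministic
part of the surface but leaves a spatially correlated residual; pure
interpolation (kriging) captures the correlation but ignores the covariates;
tree ensembles capture non-linearity but know nothing about space. The hybrid
implemented here feeds both a kriged spatial feature and the LUR-selected
covariates into a boosted-tree regressor, so each component does the job it
is good at.

## Pipeline and assumptions

**Screening.** Bivariate Pearson correlation of each candidate against
observed PM2.5, two-sided t-test, primary level α = 0.01 with a secondary
0.05 tier. This assumes a monotone marginal association is a reasonable
relevance filter; interactions are left for the trees.

**Stepwise LUR.** Bidirectional selection with p_enter = 0.05 and
p_remove = 0.10 (classical defaults; an AIC mode is provided). The procedure
is deterministic: ties break on larger |t|, then name order, and selection
stops once the fit is numerically exact (zero residual variance), since
every further p-value would be spurious. The road-length sum `hm` is removed
from the candidate pool whenever both addends `hig` and `maj` are present —
they are exactly collinear by construction, and keeping all three would only
force the rank check to reject arbitrary subsets. Only the selected variable
set is forwarded; the linear fit's predictions are not used as a feature,
so the trees see raw covariates rather than a pre-digested index.

**Semivariogram.** Empirical semivariance
γ̂(h) = mean of ½(Rᵢ − Rⱼ)² over station pairs binned by great-circle
distance; 12 equal-width bins to half the maximum pairwise distance by
default. Distances are haversine kilometres because the intended extents are
national and planar degrees would distort. Parametric families: spherical
(default), exponential, gaussian, all in the practical-range convention
(95% of the sill at the nominal range for the asymptotic families). Fitting
is weighted least squares with weights equal to pair counts, nonnegativity
bounds, and a small multi-start grid to avoid the shallow local minima these
objectives have. γ(0) is reported as the nugget; the kriging system itself
uses the standard zero diagonal, so a zero-nugget model interpolates the
data exactly while a positive nugget smooths.

**Ordinary kriging.** The augmented (n+1)×(n+1) semivariance system with a
ones border enforces Σωᵢ = 1 via a Lagrange multiplier φ, whose sign follows
from that standard bordered form. Exactly coincident stations are averaged
before solving (they make the system singular). The estimation variance
reported is Σωᵢγ(x₀, xᵢ) + φ, clipped at zero against roundoff.

**Rd without leakage.** For model-training rows the spatial feature Rd is
computed leave-one-out: the row's own station is removed from the same-day
system. Including it would make Rd equal the training target whenever the
nugget is zero and the model would learn nothing but an identity. For
prediction targets (grid cells, or held-out records under sample- and
site-style folds) Rd is kriged from the training-fold stations observed that
day. Time-based folds hold out entire days, so no same-day training
observation exists; there Rd is kriged leave-one-out from the *other*
stations' same-day readings. The distinction is deliberate: at deployment
time the monitoring network keeps observing, so concurrent readings of other
stations are prediction-time inputs, while a record's own observation is the
label and is never allowed to reach its own estimate. Inside
cross-validation one pooled variogram is fitted per calendar month from
training rows only (per-day fitting is available but noisy at a few dozen
stations); a fold whose month has no training rows falls back to the
variogram pooled over all training records.

**Boosted trees.** LightGBM GBDT with the fixed configuration 100 trees,
31 leaves, learning rate 0.05, feature fraction 0.9, bagging fraction 0.8
every 5 rounds, single-threaded and deterministic given the seed. An
optional stopping rule ends tree addition when the training-RMSE gain of a
new tree falls below a threshold; the default keeps the full 100 trees,
which reproduces the fixed configuration while still exposing the stated
mechanism. Rt enters as an ordinal integer (trees split ordinals natively;
one-hot would only fragment the splits). Predictions are not clamped to
nonnegative values by default. Per-feature importance is the total split
count and total gain accumulated over the ensemble; per-tree contributions
are exposed and sum exactly to the ensemble prediction.

**Metrics.** RMSE = √(Σ(PMF − PMT)²/N); MAE = Σ|PMF − PMT|/N;
MAPE = 100·mean(|PMF − PMT|/PMT); R² is the squared Pearson correlation of
predicted against observed — the conventional reading for
predicted-vs-observed scatter. MAE deliberately uses the absolute rather
than squared form: a squared "MAE" could never sit below RMSE, while every
published comparison this package reproduces has MAE < RMSE. MAPE is flagged
undefined when an observed value is zero. The relative-improvement report
uses (ref − base)/base·100 for R² and (base − ref)/base·100 for RMSE/MAE,
with multi-scheme headlines being arithmetic means of per-scheme changes,
rounded to two decimals.

**Cross-validation.** k = 10 throughout. Sample folds are a balanced random
partition of records; site folds deal shuffled stations round-robin so every
station's records stay together; time folds deal contiguous calendar blocks
(months by default, days available) round-robin. The 70/30 repeated-split
protocol defaults to 10 seeded repeats with per-repeat metrics logged.

## The synthetic generator

The generator emulates exactly the structure the method assumes: on a
regular grid (default 16×16 cells of 25 km),

    PM2.5(cell, day) = intercept + Σ β·covariate
                       + spatially correlated residual(day)
                       + A·sin(2π(m − 1)/12) + noise at stations.

The residual field is a Gaussian random field with covariance
sill − γ(h) of a configurable variogram (default spherical, sill 25 (µg/m³)²,
range 150 km — well beyond the ~70 km mean station spacing, so the kriged Rd
has signal to find), drawn independently each day by exact Cholesky
factorisation of the cell-covariance matrix. Land-use fractions come from a
per-cell Dirichlet; altitude, meteorology and AOD are smooth gradients plus
smoothed noise, giving the screening stage realistic mixed-sign
correlations. Defaults: intercept 35 µg/m³, seasonal amplitude 10 µg/m³,
observation noise 2 µg/m³, 36 stations over January–February 2016, with
linear effects on industrial land (+25 µg/m³ per unit fraction), forest
(−10), altitude (−0.004 per m), temperature (+0.6 per °C), AOD (+20) and
wind (−1.5 per m/s) — magnitudes chosen so covariate signal, spatial
residual, seasonality and noise all contribute visibly without any one
dominating.

What it does **not** emulate: real pollution magnitudes or dust-storm
extremes, temporally persistent residuals (each day's field is independent),
anisotropy, station dropout/missingness, or instrument error structure
beyond iid Gaussian noise (the error structure of real monitors is
unpublished; iid Gaussian is our choice). Passing tests therefore show the
chain is correct and that its qualitative orderings (sample-CV optimism,
Rd's contribution to spatial generalisation) emerge under the assumed
structure — not that real-data accuracy figures would be reproduced.

## Numerical choices and degenerate inputs

* Buffers use a local equirectangular plane about the buffer centre
  (kilometre-scale radii make Earth-curvature error negligible); cell
  membership is cell-centre-in-disc, which keeps every buffer operator
  checkable by exhaustive enumeration. Road clipping uses a 256-segment
  polygonal disc (relative length error ~1e−5).
* The GRF Cholesky adds a 1e−10·sill diagonal jitter against roundoff;
  a covariance that still fails factorisation is rejected with the offending
  variogram parameters named.
* Kriging weight systems are solved densely; weight vectors are cached per
  (month, source set, target), which collapses the cost of site-style folds
  where source sets repeat across days.
* Constant covariate columns are excluded from screening as undefined
  correlations; duplicate candidate columns are rank-blocked during
  stepwise; duplicate (station, day) rows are averaged at load with a
  logged count; records with negative or missing PM2.5 are dropped with a
  logged count.
* Records whose Rd cannot be computed (fewer than 2 same-day source
  stations) are excluded from training and reported as dropped; held-out
  records in that position are excluded from the pooled metrics with a
  logged count.

## Problem sizes used in tests and the acceptance script

Simulations are desk-scale: grids of 8×8 to 20×20 cells, 14–36 stations,
one to two months of days, chosen so the full suite and the acceptance
script each run in minutes on a single core while keeping ≥ 2000 pairs per
variogram bin where parameter recovery is asserted and ten seeded
replicates where orderings are asserted.

## Known limitations

* One isotropic variogram per month (or day); no anisotropy, no space-time
  covariance beyond the (Rd, Rt) factorisation.
* Time-based CV measures temporal generalisation of the *regression*; since
  Rd is recomputed from concurrent network readings, it does not measure
  extrapolation to periods when the network itself is dark.
* Stepwise selection inherits the usual instabilities of greedy subset
  search; the AIC mode and the exhaustive best-subset oracle (≤ 16
  candidates) are provided for auditing.
* The comparison report consumes published per-scheme metrics for the
  baseline estimators (BPNN, DNN, RF, XGBoost, LightGBM); those models are
  not re-trained here.
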