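# Methods and design notes

This note documents the models implemented in `mocsat`, the assumptions they
make, the defaults and why, and what the synthetic-data tests do and do not
establish about real data.

## Boundary-line capacity

The mineralogical capacity is modelled as `MOC_max = k(type) · CS` with CS
the clay+silt mass percentage and `type ∈ {HM, LM}`. The envelope slope is a
quantile-regression slope through the origin at level τ (default 0.95). A
high quantile rather than the maximum is used because size-fractionation
carbon recovery varies by roughly ±20% across studies, so the observed
scatter's extreme points carry measurement error; the 95th quantile is a
conservative envelope, which is also why saturation values above 100% are
legitimate and are flagged rather than rejected.

For one covariate with a forced zero intercept, minimising the pinball loss
Σ ρ_τ(yᵢ − βxᵢ) over β has a closed form: the τ-th x-weighted quantile of
the ratios yᵢ/xᵢ. At quantile jumps, where the minimiser is an interval,
the lower endpoint is returned (left-continuous convention) — deterministic
and directly checkable against a dense grid search of the objective, which
the test suite does.

Fitting conventions: natural-ecosystem records only (managed soils sit well
inside the envelope and carry no information about it), records from the
<63 μm fraction cutoff (clay+silt; the <2 μm clay-only fraction measures a
different operational pool and is excluded), layers pooled across depths
(the capacity is a property of the mineral matrix, not of depth). The 90%
confidence interval is a percentile bootstrap over profiles (site
identifiers), not layers, to respect within-profile dependence; 1000
resamples by default, seeded. The choice of estimator for the CI and the
pooling of depths were genuinely open design points; both are recorded here
as package conventions.

Unit conversion: 1% CS is 10 g mineral per kg soil, so a slope in
g C kg⁻¹ soil per % equals 100× that value in mg C g⁻¹ mineral.

## Mineral-type and management classification

HM/LM assignment is a total function over the 11 mineral-soil USDA orders ×
{topsoil, subsoil}: Oxisols and Ultisols are LM at all depths; Alfisols,
Aridisols, Gelisols, Inceptisols, Mollisols, Spodosols and Vertisols are HM;
Andisols and Entisols are HM in topsoil and LM in subsoil. An explicit
statement of dominant clay composition (2:1 vs 1:1) in the source study
overrides the order-based default. Histosols (organic soils) are rejected at
ingest. Croplands are "managed"; forests, grasslands (savannas grouped with
grasslands) and shrublands are "natural/less-managed".

The topsoil/subsoil boundary is 30 cm. Source intervals that straddle 30 cm
are assigned by their midpoint — a package convention, since reported
intervals do not always nest inside the 0–30/30–100 cm scheme.

Records where MOC exceeds 1.25 × SOC (beyond fractionation-recovery
tolerance) are kept and flagged; they participate in boundary fitting (the
envelope estimator is insensitive to inflating already-interior points and
the quantile level was chosen with this noise in mind) but are excluded from
saturation ratio statistics.

## Saturation statistics

Group summaries report the mean with a t-distribution 95% CI (deterministic,
unlike a bootstrap) plus median and quartiles for box summaries. In
ecosystem-by-depth groupings, groups with ≤5 observations are suppressed.
The managed-vs-natural contrast uses Welch's unequal-variance two-sample
t-test, two-sided; the choice of test is a package convention.

## Random-forest ensemble

Attribution uses features (CS, MAT, MAP, POC, vegetation, mineral type);
prediction replaces POC with SOC (no gridded POC product exists to predict
from); a compact (SOC, CS) spec imputes MOC for accrual records. Default
ensemble: 300 members × 400 trees, each member trained on its own random
75% subset with metrics (MAE, MSE, R²) evaluated only on its held-out 25%.
Other tree hyperparameters are scikit-learn defaults and are recorded in run
manifests. Categorical features are encoded as fixed-order integer codes;
trees are invariant to monotone recoding, so nothing more is needed, and an
unseen level at prediction time is a hard error.

Partial dependence is computed exactly as the background average of the
ensemble-mean predictor — the ensemble mean, not a representative member,
is "the model". Conditional partial dependence restricts the background to
low/medium/high regimes of a conditioning variable; breakpoints default to
the median and third quartile of that variable's distribution. Permutation
importance permutes one encoded feature at a time within each member's test
set and averages the MSE increase.

Prediction intervals are the 5th–95th percentiles of member predictions.
These quantify ensemble spread, not full predictive uncertainty: they omit
residual noise, so their empirical coverage on noisy targets sits below the
nominal 90%. The tests assert stability of this coverage rather than
nominal calibration, and downstream stock ranges inherit the same caveat.

Spatially buffered leave-one-out CV excludes all training points within a
great-circle buffer radius of each test point (haversine distance, Earth
radius 6371 km) and regresses R² on radius; a slope indistinguishable from
zero indicates spatial autocorrelation is not inflating apparent skill. At
desk scale the test points are subsampled (≤500, seeded). Hold-out CV
withholds entire soil orders (or studies) in turn; groups under 10 records
are skipped with a warning.

## Gridded upscaling

Input rasters must arrive co-registered on a regular lat-lon grid (default
0.5°); regridding heterogeneous products is out of scope and mis-registered
layers are a hard error. Raster I/O is NetCDF through xarray (float32, NaN
nodata); this is the package's raster format. Cells are excluded when the
Histosol+Gelisol areal fraction exceeds 50% (strict) or the land cover is
tundra, desert, barren, ice or water; the land-cover code table and the
excluded-class list are configuration, since satellite land-cover legends
differ and are collapsed onto the package's classes by a lookup.

Stocks: concentration (g C kg⁻¹) × bulk density (g cm⁻³) × thickness (m)
gives kg C m⁻² exactly. Thicknesses are 0.30 m (topsoil, 0–30 cm) and
0.70 m (subsoil, 30–100 cm). Cell areas use the exact spherical band
formula R²·Δλ·(sin φ₂ − sin φ₁); totals are in Pg C (10¹² kg) and are
additive over any domain partition, which the tests assert to 1e-9.

The environmental-limit deficit is max(0, s_nat · MOC_max − MOC) with s_nat
the natural-land mean saturation per depth (defaults 0.51 topsoil, 0.19
subsoil, configurable): the carbon a soil could plausibly gain if managed
to the saturation level natural ecosystems achieve, as opposed to the
mineralogical limit itself. An optional pre-processing step blends two SOC
products by cellwise mean.

## Accrual synthesis and asymptotic fit

Filters: studied depth <15 cm rejected; organic amendments rejected when
annual, one-time >20 t ha⁻¹ without a control plot, or of unknown
intensity; records whose initial/final texture classes differ rejected;
when CS differs within the same class, the mean is used. Paired profiles of
unequal depth are standardized by truncating the deeper cumulative-stock
profile (linear interpolation) at the shallower maximum.

Rates are (final − initial)/duration in t C ha⁻¹ yr⁻¹, negative values
(losses) permitted. Initial %C saturation is the initial MOC stock over the
MOC_max stock (capacity slope × CS × BD × depth); unmeasured MOC is imputed
from SOC and CS with the compact ensemble.

The asymptotic model is rate(s) = asym + (r0 − asym)·exp(−exp(lrc)·s) with
s the saturation as a fraction (percent/100; this choice affects only the
lrc parameterisation, not predictions, and is fixed here). The mean curve
is nonlinear least squares over a deterministic multi-start grid
(asym ∈ {0, min rate}, r0 = max rate, lrc ∈ {−2…2}), emulating a
self-starting routine with reproducible behaviour; quantile curves (10th,
90th) minimise the pinball loss from the same starts via Nelder–Mead. R² is
1 − SSE/SST in all cases. A negative fitted asymptote (net losses at high
saturation) is allowed but logged prominently. Degenerate constant-rate
inputs return a flat fit. Sensitivity refits under named exclusion sets
(mine soils, Andisols, the single high-saturation record, …) report
parameter deltas and whether the declining trend persists.

Potential accrual maps apply the mean curve to the topsoil saturation map
over cropland cells; totals are area-weighted in Pg C yr⁻¹.

## The synthetic generator

The generator is the package's test bed: it embodies the structural
assumptions above with known latent truth, at sizes that run in seconds.

- **Envelope**: true slopes default to 0.86 (HM) / 0.48 (LM) g C kg⁻¹ per
  %CS. Each record's MOC is saturation × true MOC_max × a Langmuir factor ×
  multiplicative noise (sd 0.10).
- **Saturation**: beta-distributed per (management, depth) group with target
  means 0.46 (natural topsoil), 0.31 (managed topsoil), 0.19 (subsoil),
  concentration 30, modulated by MAP^0.8 (normalised) so that part of the
  within-group spread is carried by an observable covariate. The draw is
  scaled so the 95th percentile over natural records is 1, then — because
  the Langmuir and noise factors would otherwise shift the realized
  envelope — a final per-mineral-type renormalisation pins the 95th
  percentile of realized MOC/MOC_max over natural <63 μm records at exactly
  1. By construction the nominal slope *is* the 95th-quantile boundary of
  the generated scatter, which is what lets 2000-record simulations certify
  the estimator (slope recovery bias <5% over 20 seeds). The per-type
  anchor is needed because LM records skew to subsoil, whose lower
  saturation would otherwise thin the LM envelope. Occasional latent
  saturation slightly above 1 (cap 1.1) mimics recovery noise.
- **Langmuir link**: factor K·POC/(1 + K·POC) with K = 2.0 per g kg⁻¹ at
  10 °C declining by 8%/°C — sorption affinity falls with temperature, so
  temperature sensitivity concentrates where POC is low (unsaturated
  regime) and vanishes near saturation. POC is lognormal with median 4 and
  third quartile 10 g C kg⁻¹, so the default conditional-PD breakpoints
  fall at those values.
- **Covariates**: MAT in [−2.9, 29] °C, MAP in [79, 3806] mm yr⁻¹, CS in
  [1.5, 100]%; soil orders and land covers drawn with mineral-soil
  frequencies; 80% topsoil records, matching the depth mix of fractionation
  syntheses; fraction cutoffs 63/20/2 μm at 70/25/5%, the 20 μm MOC scaled
  by 0.97 (the envelope is robust to the cutoff choice) and the 2 μm
  clay-only MOC by 0.55.
- **Noise shares**: chosen so the attribution feature set explains ≈0.6 of
  MOC variance and the prediction (SOC) set ≈0.8 on held-out data.
- **Spatial structure**: optional exp(−d/range) correlated residual
  (Cholesky of the haversine covariance) to make buffered-CV behaviour
  controllable; off by default (iid residuals, flat R²-vs-radius).
- **Grid**: a small stack (default 20×40 at 0.5°) of smoothed random
  fields, with deliberately constructed organic-majority, tundra and desert
  cells so masking is exercised, plus `truth_*` layers for stock oracles.
- **Accrual**: saturations right-skewed over (0, 1.05] (revegetation and
  soil-formation sites populate the low end, which also identifies r0 and
  lrc); true curve asym 0.2, r0 1.8, lrc ln 4 — its rate at 10% saturation
  is ≈3.05× its rate at 50%. Noise is heteroscedastic,
  sd = √((0.35·rate)² + 0.10²), shrinking as rates tend to zero near
  saturation. A configurable handful of records violate each filter rule,
  labelled so rejection bookkeeping can be reconciled exactly.

Everything is driven by one seed; identical seeds give bitwise-identical
outputs.

**What the synthetic tests do not show.** The generator draws covariates
independently (no real geography, no covariate collinearity beyond the
built-in links), its accrual scatter is milder than field syntheses (fit R²
≈0.7 versus ≈0.2 on real compilations, a consequence of requiring stable
curve recovery at n = 103), and its grid is a toy domain, so absolute Pg
totals are not comparable to global products. Passing tests certify the
estimators and bookkeeping — unbiased envelope recovery, exact partial
dependence, conservation of stock totals, correct filter logic — not the
field accuracy of any fitted value.

## Problem sizes

Tests and the acceptance script run deliberately scaled-down analyses:
2000-profile syntheses, ensembles of 4–12 members with 30–100 trees,
buffered CV over ≤60 test points, a 20×40-cell grid. These sizes were
chosen so the full certification runs in a few minutes on a single core
while keeping every statistical property being asserted (quantile recovery,
R² bands, trend flatness, ratio stability) comfortably inside its
tolerance. Production-scale defaults (300×400 ensembles, 0.5° global
grids) are plain configuration.
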