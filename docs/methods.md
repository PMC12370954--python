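# Methods

## Scope and data model

`selfthin` works on tidy permanent-plot inventories: per-census tree records
(plot, date, tree id, DBH at 1.3 m, status alive/dead/removed, species) plus
plot metadata (area, disturbance flags) and per-plot annual climate series
(MAT in °C, precipitation in mm, optionally VPD in kPa). From these it builds
stand summaries per census — quadratic mean diameter `D = sqrt(mean(DBH²))`,
live density `N = N_raw·10⁴/area` — and intercensus periods carrying the dead
count ΔN, removal count, net QMD increment ΔD, and the QMD of the trees that
died. Removals (thinning) are never counted as mortality; a plot is treated
as an unthinned control iff it never has a removal. Period selection follows
the standard protocol for pure even-aged stands: plot area ≥ 400 m²,
census interval ≥ 0.5 yr, annualised growth ΔD/interval ≥ 0.1 cm yr⁻¹,
target-species basal-area share > 0.80, no disturbance flag. All rules are
evaluated jointly, so the retained set is order-independent and every
excluded period records the full list of rules it violates.

One open point in period construction: ΔD is the change in live-tree QMD
between the two censuses (computed over each census's live trees), not the
growth of the cohort surviving the whole period. The two differ when
mortality is size-biased; with the field's convention of stand-level
summaries this is the natural observable, and it is what the synthetic
generator emits, so the choice is internally consistent.

## Climate covariates

Spatial and temporal climate variation are separated through the
decomposition `MAT_ij = MAT_lt,j + MAT_anom,ij`: the plot's long-term mean
over a reference window (1960–2000 by default) and the per-period deviation
from it. Period values are duration-weighted means of annual values over the
period's overlap with each calendar year (the data carry no sub-annual
resolution, so weighting by month is not attempted). The aridity index
AHMI = (MAT+10)/(P/1000) and VPD are carried as alternative covariates; VPD
exists only from 1980 on and is never imputed. Before fitting, MAT and VPD
are centred and P and AHMI centred and scaled; scaling uses the sample
(n−1) standard deviation, and the constants are stored with the fit so
predictions on new data reuse the training transform. Centring defaults to
the fitting-dataset mean; parameter-recovery runs pass the generator's
known centre (11 °C) so recovered intercepts sit on the truth scale.

## Static allometry (spatial variation)

On control plots, `log N_ij ~ N(α₀ⱼ + α₁ log D_ij + α₂ x_j, σ)` with
`α₀ⱼ ~ N(α₀, σ_α₀)` is fitted by REML (statsmodels MixedLM). All retained
periods' start snapshots enter as observations. Uncertainty draws for
downstream transforms are parametric samples from the estimated fixed-effect
covariance; σ and σ_α₀ are reported at their point estimates. At the
zero-variance boundary (noiseless data, σ_α₀ → 0) the mixed model
degenerates and the implementation falls back to ordinary least squares,
which is the exact limit. The stand density index SDI is the predicted
maximum stocking at the reference QMD of 25 cm; with the log-linear form its
ratio across covariate values is exactly `exp(α₂·Δx)`.

## Mortality GLMM (growth–mortality allocation)

The dynamic model treats per-period dead counts as negative binomial,
`ΔN_ij ~ NB(μ_ij, θ)` (variance μ + μ²/θ), with

    log μ_ij = β₀ij + β₁ log D_ij + β₂ log N_ij + log ΔD_ij + log N_raw_ij

The two offsets carry fixed coefficient 1: mortality is allocated per unit
of stand growth and scaled by the number of trees at risk. The intercept
carries a plot random effect `β₀ⱼ ~ N(β₀, σ_β₀)` plus climate terms in two
variants: `eq_space_time` (β₃·MAT_lt + β₄·MAT_anom) and `eq_composite`
(β₅·MAT_ij). Periods with ΔN = 0 are retained (the NB handles zeros);
periods failing the growth filter are excluded upstream because log ΔD is
undefined. All retained periods — thinned plots included — enter the
mortality fit; removals affect the state variables but not the response.
An interaction between long-term MAT and its anomaly is supported but off by
default.

Estimation maximises the marginal likelihood, integrating the plot random
intercept by adaptive Gauss–Hermite quadrature: for each plot a damped
Newton solve finds the conditional mode of the random effect (the integrand
is log-concave, so this is global), the curvature there scales the
quadrature grid, and 15 nodes integrate the remainder. BFGS with numerical
gradients maximises over (β, log σ_β₀, log θ); convergence is judged by the
gradient norm actually reached, since BFGS often reports "precision loss" at
the optimum with finite-difference gradients. The observed-information
covariance (finite-difference Hessian, eigenvalue-floored inversion) yields
parametric draws on the (β, log σ, log θ) scale; all derived quantities are
computed draw-wise from these, exactly as they would be from posterior
samples. On common test fixtures the fit agrees with R's glmmTMB (Laplace
approximation) to four significant figures, and that agreement is asserted
in the test suite with glmmTMB as an independent oracle.

## Derived line, effect sizes, projections

With β₂ > 0 and β₁+1 > 0 the thinning line follows in closed form:
`intercept = β₀/(−β₂) + (log β₂ − log(β₁+1))/(−β₂)`, `slope = (1+β₁)/(−β₂)`.
The log terms are kept exactly (they contribute ≈ 0.21 to the intercept at
reference coefficients — small, not negligible). The identity behind the
derivation is checked numerically in the tests: along the derived line the
expected per-tree mortality per cm of QMD growth equals −slope/D at every
size, which is precisely the condition for the stand to track the line.

A climate coefficient β_k shifts the intercept by `β_k/(−β₂)` per °C, so a
temperature change ΔT multiplies carrying capacity by `exp(ΔT·β_k/(−β₂))`.
Every derived summary (intercept, slope, effect, multiplier) is produced by
applying the transform to each joint parameter draw and summarising with
the mean and central 95 % interval — never by transforming summary means,
which would be wrong for these nonlinear maps. A transform undefined on any
draw (e.g. β₂ ≤ 0) aborts loudly with the offending draw indices rather
than silently dropping them.

Carbon projection is deliberately plain arithmetic: a capacity drop
fraction f over area A at stock density c loses `f·c·A` tonnes of carbon,
equivalent to `f·A` hectares of standing forest; an optional car-equivalence
divides by per-person lifetime driving emissions (146 g C km⁻¹ ×
10,000 km yr⁻¹ × 75 yr). Percent changes are reported at full precision with
rounding left to the caller; the acceptance script rounds to the integer
percent at which such figures are conventionally quoted.

Trajectory simulation iterates growth and expected mortality (deterministic
mean mode, or NB draws in stochastic mode) at dt = 0.25 yr. Under a
permanent ΔT the trajectory converges to the shifted line, so density at
matched D approaches `exp(ΔT·effect)` times baseline; under a transient
shift the stand dips below, then holds nearly constant density while it
grows back into the restored line, recovering the baseline trajectory — the
line is an attractor of the growth–mortality dynamics. Both behaviours are
asserted quantitatively in the tests (5 % and 0.02 log-density tolerances).

## Relative size of dying trees (k factor)

For each period with dead trees, k is the dead-tree QMD at the period's end
over the live-tree QMD at its start. Only events with more than three dead
trees enter (strictly; a three-dead event is excluded) to limit the
dispersion of the dead-QMD estimate. The pooled k is the slope of a
zero-intercept least-squares regression of dead QMD on live QMD —
consistent with k being a ratio and with the 1:1 reference line; an
intercept variant is available behind a flag. Climate/time/height effects
on k are tested one covariate at a time with a linear mixed model (plot
random intercept); dominant height is defined as the mean height of the 100
largest-diameter trees per hectare and is only computed when heights were
measured. A covariate with no variance across events is flagged as
degenerate rather than fitted.

## Cross-validation

Leave-one-plot-out: each fold refits without one plot and predicts it with
the random effect at its population mean — the only defensible choice for a
never-seen plot. Metrics are R² = 1 − SSE/SST, RMSE = √(SSE/n) and
BIAS = Σ(y−ŷ)/n over the pooled out-of-sample predictions; mortality is
scored as count, count per hectare, and rate (count/N_raw). With strong
plot-level variance (σ_β₀ ≈ 0.84) and few plots, out-of-sample rate metrics
are legitimately poor; they stabilise as the plot network grows.

## Synthetic data generator

The generator emulates the structure of a mid-century silvicultural
experiment network: 112 plots (40 controls) with log-uniform areas
400–8000 m² (mean ≈ 2600 m²), censuses every 2–3 yr from a start between
1955 and 1975 until 2000, a spatial MAT gradient uniform on 9.5–12.5 °C, a
linear warming trend totalling 0.71 °C across 1947–2000 (centred so the
window mean stays at the plot baseline, putting the dataset mean near
11 °C), interannual MAT anomalies with sd 0.4 °C, plot mean precipitation
1000–1600 mm, and VPD affine in MAT with noise chosen to keep their
correlation near 0.96. Non-control plots receive one thinning (30 % of
stems removed) at a random mid-record census — a placeholder schedule, since
real thinning intensities vary.

Stand dynamics follow the mortality model in the generative direction:
per period, a growth increment ΔD is drawn, μ is evaluated from the period's
start state and climate, and ΔN ~ NB(μ, θ) is drawn (truncated at the live
count; at realistic μ/N_raw ≤ ~0.2 the truncated mass is negligible and the
likelihood ignores it). Because no growth model is part of the estimated
system, the generator supplies one: annual QMD increment
`g = g_max·exp(−D/D_scale)·max(1 − c·N/N_max(D), g_floor)` with lognormal
noise (defaults g_max = 1.2 cm yr⁻¹, D_scale = 80 cm, c = 0.5,
g_floor = 0.1), where N_max comes from the truth line at the plot's climate.
This produces growth that slows with size and crowding and keeps the
fraction of periods failing the ΔD filter under 10 %, so filtering does not
distort recovery tests. Initial states are D₀ ~ U(10, 20) cm at a relative
density 0.3–0.8 of the population-level line for the plot's climate —
deliberately the population line, not the plot's own: establishment density
in a real experiment is independent of the plot's latent mortality
intercept, and coupling them induces a random-effect/covariate correlation
that biases β₂ in recovery tests (observed before the change, gone after).

Dead-tree size is summarised directly at the period level:
dead QMD = k_true·D_start·exp(N(0, 0.1²)) with k_true = 0.62, since only
QMDs enter the k-factor analysis. When tree-level records are materialised,
all live trees carry the stand QMD as their DBH and the trees that died
carry the period's dead QMD: a deliberately degenerate size distribution
that makes tree records exactly consistent with the stand-level dynamics
(the QMD is insensitive to which equal-sized tree dies). Consequently the
generator exercises every pipeline stage faithfully at the stand level but
says nothing about within-stand size structure, height–diameter relations,
or spatial pattern; passing tests validate the estimators and plumbing, not
the realism of individual-tree detail.

Randomness derives from a single master seed through per-plot substreams
(`SeedSequence(entropy=seed, spawn_key=(plot,))`), so enlarging the network
leaves existing plots' trajectories bit-identical.

## Problem sizes and numerical settings

Default fits use 2000 parametric draws; recovery tests use 1000. The
coverage gate refits the composite model on 10 independent 112-plot
realisations (~1500 periods each; about 2 s per fit). The k-factor check
uses 500 events from a default-size study. Quadrature uses 15 nodes;
increasing to 30 changes reference-fit log-likelihoods by < 10⁻⁶. The
Hessian uses step 10⁻⁴ on the transformed scale; non-positive curvature
directions (possible at variance boundaries) are eigenvalue-floored before
inversion, which widens rather than narrows the resulting intervals.

## Known limitations

* Wald/parametric draws approximate the parameter distribution; with 112
  plots the approximation is excellent (coverage checks pass), but with very
  few plots intervals for σ_β₀ and θ can be optimistic.
* The NB truncation at the live count is ignored in the likelihood
  (documented approximation, negligible at realistic mortality fractions).
* The generator's equal-DBH tree lists make any within-stand size-structure
  analysis trivial by construction; only QMD-level conclusions transfer.
* Dynamic-panel feedback (state variables depend on past mortality draws)
  is inherent to the design; at the default conditions it does not
  measurably bias recovery, but much longer records with stronger plot
  effects could reintroduce bias.
* The year-effect mortality trend and any water-yield or fire-regime
  consequences are out of scope.
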