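# Methods

This note records the modeling assumptions, parameter defaults, numerical
schemes and design choices behind `lapsched`, in the order the pipeline
runs them.

## In vitro pharmacodynamic model

Viable and dead cells follow the logistic birth-death system

    dY1/dt = b Y1 (1 - Y1/K) - d Y1
    dY2/dt = d Y1 - c Y2

with all rates per day and restricted to non-negative values. The carrying
capacity `K` is treated as concentration-invariant and estimated as the
maximum untreated viable count on day 5. The dead-cell clearance rate `c`
is fixed at 0 in the selected model (a range of constant clearance values
0–0.5/day changes the fitted birth/death rates only marginally; the
simplest assumption wins). Note that the day-5-max estimator of `K` is
biased upward under multiplicative noise (the expected maximum of three
CV-10% lognormal replicates sits ~6% above the mean), which propagates
into a small downward bias in the fitted `b0`; this is a property of the
estimator itself, retained deliberately, and is why parameter-recovery
checks are scored on the scale of the published standard errors rather
than the fitted ones (see below).

**Grid search.** Per concentration, `(b, d, c)` minimize the summed squared
distance between observed and simulated viable *and* dead counts over all
days and replicates (replicate-level summation, unweighted). Default grid:
`b` in [0, 2] step 0.005, `d` in [0, 0.8] step 0.0025, `c` in {0}. The
death-rate range extends to 0.8 (not 0.5) because the default concentration
panel reaches 4000 nM where the published dose-response implies
d(4000) ≈ 0.63; a 0.5 cap would clip it and bias the downstream fit. Ties
break toward the smallest `b`, then `d`, then `c`. The trajectory for each
grid point uses the closed-form logistic solution for Y1 and composite
Simpson quadrature (4 subintervals per day) for Y2, vectorized over the
whole grid; this reproduces an ODE-solver-based objective to ~1e-4 relative
and makes the full search run in tens of milliseconds per concentration.

**Dose-response laws.** b(L) = b0·exp(b1·L) and d(L) = d0·exp(d1·L) are
fitted by unweighted nonlinear least squares (`scipy.optimize.curve_fit`)
with log-linear starting values; standard errors come from the asymptotic
covariance and slope p-values from a t-distribution with n−2 df. Because
the rates span two orders of magnitude, the unweighted residual-based SEs
understate the sampling error of the intercepts; recovery experiments
therefore compare estimates to the truth on the scale of the published
coefficient SEs (3·SE), which is the uncertainty attached to the values
being recovered.

## Synthetic in vitro data

The original SF268 count data are not deposited, so the generator emulates
the experimental design: 150,000 cells seeded, triplicates, days 0–5, and
a concentration panel {0, 125, 250, 500, 1000, 2000, 4000} nM chosen to
bracket the growth-arrest concentration (~2.2 µM); the true panel and
replicate variance of the original experiment are unrecoverable from the
text, so these are explicit stand-ins. Ground-truth rates default to the
published dose-response estimates with K = 1e6 cells and c = 0. Noise is
multiplicative lognormal with mean 1 and CV 0.1 by default (counts are
positive and heteroscedastic; a Poisson option exists); each observation is
rounded to a non-negative integer. What passing recovery tests show is
that the fitting pipeline is consistent *under this noise model and
design*; they cannot validate the noise model against the real assay, nor
do they emulate assay artifacts (e.g. a transient mid-experiment dead-cell
peak, treated as technical artifact and deliberately not modeled).

## Toxicity frontier

The three clinical maximum-tolerated-dose points (5 d/cycle at 3000 mg/d
continuous; 2 d at 5250 mg/d; 1 d at 7000 mg/d from clinical expertise)
are fitted by OLS on the natural scale (linear model) and on the log scale
(exponential model). AIC uses the Gaussian maximum-likelihood convention
with k = 3 (intercept, slope, error variance): AIC = 2k + n(ln(2π·RSS/n)+1).
On these points the linear AIC is 49.48 and the exponential −5.712, so the
exponential curve is selected; a zero-residual fit makes the Gaussian ML
AIC diverge and raises a dedicated error. Schedule doses use the observed
clinical MTDs at 1/2/5 treatment days and the fitted exponential curve at
3/4 days (4475 and 3642 mg rounded), since the clinical values — not the
curve — are the binding constraints where they exist.

## Pharmacokinetics

Serum peaks follow serum = (τ0 + τ1·ln(oral mg)) with the published τ
coefficients; the raw formula lands on the µg/mL scale despite its ng/mL
label, so the implementation rescales by 1000 and documents the mismatch.
Even so, the curve slightly underpredicts the published per-schedule serum
peaks (e.g. 1772 vs 1972 ng/mL at 3000 mg), so the packaged schedule table
carries the published serum/tumor peaks verbatim and these are canonical
for all simulations. Tumor concentration is the linear conversion
0.61 · serum · 1000 / 943.5 (tumor/serum ratio × unit conversion at the
lapatinib molar mass); the packaged tumor peaks reproduce this conversion
exactly, and one published fixed-total-dose row that contradicts it (1881
vs 1181 nM at 1826 ng/mL) is stored conversion-consistent.

Each treatment day contributes one pulse: linear rise from 0 to the tumor
peak over t_Cmax = 4 h, then exponential decay with half-life 24 h.
Pulses from successive doses add (standard PK superposition; a reset mode
keeping only the most recent dose is available via `superpose=False`).
Twice-daily clinical splitting is ignored: one pulse per treatment day at
the daily peak. Treatment days occupy the first k days of each 5-day cycle
(loading-dose-first), matching the short-term dynamics the schedule
comparison assumes.

## ODE schedule comparison

The logistic model runs with b(L(t)), d(L(t)), c = 0, Y1(0) = 150,000 and
K = 1e6 over twenty 5-day cycles (100 days). The percent-reduction
contrasts are attractor ratios and are insensitive to Y1(0) and K (tested:
<2 percentage points of movement across a 10× range of Y1(0)); the
integrator is LSODA with rtol 1e-8 and a max step of 1 h so no pulse is
stepped over. Headline outputs: continuous dosing ends ~57% below control;
the best pulsatile schedule ends ~29% below control; final viable counts
order strictly schedule 1 < 2 < 3 < 4 < 5 < control.

## Reaction-diffusion model

Geometry is spherically symmetric: fields live on cell centers of a
uniform radial grid (default spacing 0.25 mm for single runs, 0.5 mm for
the comparative sweeps — grid-halving moves final radii by <1%), domain
radius 60 mm, with a conservative finite-volume discretization of the
radial Laplacian: face fluxes D·x²·Δc/Δx divided by shell volumes, no-flux
at both ends. Diffusion advances by Crank-Nicolson (banded solves),
reaction explicitly (first-order splitting, default dt 0.01–0.02 days);
under pure diffusion the discrete mass Σ cᵢVᵢ is conserved to round-off by
construction. A planar-geometry option exists for validation: traveling
fronts reproduce the Fisher-KPP speed 2√(Dρ₀) within ~2% once the slow
(~1/t) front-speed transient has passed, which is why the speed check uses
the larger ρ₀ value (0.387/day) where the transient is short.

Defaults: D = 0.03 mm²/day, κ = 1e6 cells/mm³, detection threshold 8000
cells/mm³, fatal radius 30 mm (one source sentence says "3 cm diameter";
the radius reading is used, configurable). The initial tumor has a solid
core at 0.8κ out to 15 mm falling to 0.16κ at 25 mm; the tail continues
*linearly* to zero (~27.5 mm) by default. An exponential (log-linear) tail
is available, but continuing that shallow log-slope outward would place
the initial detection radius at ~44 mm — beyond the fatal radius — so the
linear tail is the default for anything radius- or survival-based; the
initial detection radius is then ~27.4 mm, between the isolated-cell and
fatal radii.

**Baseline proliferation rate.** The source text prints both ρ₀ = 0.387
and 0.0387/day. The package defaults to **0.0387/day** and exposes both.
Measured behavior drove the choice: with 0.387 the untreated front moves
0.216 mm/day, so every simulated patient dies within ~2-3 weeks, and in
the resistant-subpopulation variant the resistant front overruns all
treatment arms before day 100 — competition release then makes continuous
dosing finish (marginally) *largest*, inverting the expected ordering.
With 0.0387 the untreated time-to-fatal-radius is ~38 days (against a
clinical no-treatment median of ~9 weeks), schedule-4/5 trial medians land
in the tens of days, and all four model variants rank continuous dosing
strictly best, with the between-schedule differences shrinking as
pre-existing resistance grows — the qualitative pattern the platform is
meant to reproduce.

**Variants.** (i) Heterogeneity: sensitive and resistant fields share one
carrying-capacity term; the resistant field proliferates at ρ₀ regardless
of drug. (ii) Blood-brain barrier: the drug signal is scaled by Q before
entering ρ(L). (iii) Go-or-Grow: migratory cells diffuse but do not
divide, proliferative cells divide but do not move; switching rates are
f_MP = λ₂σ and f_PM = max(λ₁−σ, 0) (clipped — negative rates are
unphysical). Oxygen obeys ∂σ/∂t = D_σ∇²σ + h₁v(σ₀−σ) − h₂(c_M+c_P)σ with
σ₀ = 2.068 nmol/mm³, λ₁ = 4.134 nmol/mm³ (twice σ₀), D_σ = 151 mm²/day,
h₁ = 0.337/day, h₂ = 1e-2 mm³/cell/day, v = 12, all in a single consistent
oxygen unit (nmol/mm³). The printed "v=12" is taken at face value: with
v = 0.5 the supply term h₁v is ~5 orders below the consumption term at any
appreciable cell density, the whole domain goes hypoxic and growth stops,
so schedules cannot be compared. The oxygen sink is stiff (h₂c ~ 1e4/day
inside the tumor), so oxygen advances by backward Euler with the sink
implicit; cells start fully proliferative and oxygen at σ₀.

## In silico trial

Per patient: (b0, b1, d0, d1) ~ Normal(estimate, SE), with b0, d0
resampled until positive; absorption ~ Beta(2.3, 1.5) replacing the
population-mean 0.61 tumor/serum ratio; optionally D ~ Gamma(1,1)
truncated to [0.55, 4.23] mm²/month ÷ 30. The same draws are reused across
schedules (paired design). Death is the first time the detection radius
reaches the fatal radius, found by linear interpolation of the per-step
radius series; survivors are censored at the 365-day horizon. Events are
extracted from the reaction-diffusion model only — the ODE model has no
spatial state and hence no radius-based death criterion. Kaplan-Meier and
log-rank use `lifelines`; the motility regression
V = ν₀ + ν_D·D + ν_S + ν_int,S·D (schedule 1 baseline, volume =
(4/3)π·radius³) uses `statsmodels` OLS. Log-rank p-values from any
particular simulated cohort are seed-dependent and are not treated as
reproducible constants; the platform's claims are the orderings and the
interaction signs.

## Problem sizes and tolerances used in the test suite

Unit and property tests run the PDE at 0.5–1 mm spacing on short horizons;
the comparative sweeps behind the schedule-ranking checks use 0.5 mm /
0.02 days over 100 days (Go-or-Grow at dt 0.005), sizes at which the
rankings are converged (grid-halving < 1% radius movement). The
parameter-recovery experiment runs 500 seeds of the full
generate-fit-regress pipeline at the default design. The explicit-Euler
oracle for the PDE core runs on a 10 mm toy domain at a 20× finer time
step and agrees to 1e-3 (normalized).

## Known limitations

- No anatomical brain geometry, white/gray matter anisotropy, necrotic
  core, imaging I/O, or protein binding; no compartmental PK fit.
- The synthetic-data generator defines the only available ground truth for
  recovery experiments; real-assay noise may differ.
- The toxicity frontier rests on three clinical points; its extrapolation
  to 3- and 4-day schedules inherits that fragility.
- Survival times are model times; the platform compares schedules, it does
  not predict absolute patient survival.
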