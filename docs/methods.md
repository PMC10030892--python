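# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `zfbmd`, in the spirit of the methods notes that
accompany statistical packages. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

The unit of observation is an embryo well: one zebrafish embryo in one
well of a 96-well plate, exposed to one substance at one concentration,
scored 0/1 for each endpoint at 24 or 120 hours post-fertilization (hpf),
with a viability flag. A *series* is one (substance, endpoint) pair; its
dose groups pool all wells at one concentration across the retained
plates, giving counts (d, n, y) and fractional response f = y/n.
Concentrations are canonically rounded to 6 significant digits before
grouping so float noise cannot split a dose group.

### Denominators

The fractional response divides responders by *living* embryos. For
endpoints whose definition includes death (MO24, MORT, TOT_MORT, ANY24,
ANY120) that denominator would be circular — a dead well *is* a response —
so those endpoints use all assayed wells as n. Morphology endpoints
(including the ANY_MORT aggregate) keep the living-embryo denominator:
wells dead at 24 hpf never enter it, and wells dead by 120 hpf are
excluded from 120 hpf morphology endpoints. This is the only reading under
which y ≤ n holds by construction for every endpoint.

### Control-plate filter

A plate is removed when responding control embryos / total control embryos
exceeds 0.5 *strictly* ("more than 50%"); a fraction of exactly one half
is retained. The rule is evaluated per endpoint, using that endpoint's
control incidences — the conservative scope, since a plate may have clean
controls for one endpoint and contaminated ones for another. Plates with
no control wells are retained with a warning rather than silently judged.

### Summary endpoints

Per well, by OR-aggregation of raw endpoints: ANY24 = MO24 ∨ DP24 ∨ SM24 ∨
NC24; TOT_MORT = MO24 ∨ MORT; ANY_MORT = OR of all 120 hpf morphology
endpoints (mortality codes excluded; whether 24 hpf non-mortality
endpoints should contribute is ambiguous in the endpoint vocabulary, and
this package includes only 120 hpf morphology); ANY120 = OR of every raw
24 h and 120 h endpoint including mortality. Missing components are
treated as 0 with a coverage warning. The operation is idempotent and
monotone in its components.

## QC gate

A series is fitted only if it has at least 3 distinct concentration groups
(the vehicle control counts) and Spearman rank correlation ρ(d, f) ≥ 0.2,
computed on group-level pairs with average ranks for ties. ρ is rounded to
12 decimals so the documented boundary — ρ exactly at the threshold passes,
only "below" fails — is immune to float noise. A series with constant f
has undefined ρ and fails as trendless (a flat curve is explicitly a
no-fit case). Gated series are scored **Poor** and skip fitting entirely.
The control group participates in ρ; leaving it out would discard the
strongest anchor of the trend.

## Quantal models and fitting

The eight families use the standard regulatory parameterizations (table in
`zfbmd/models.py`), each with background g ∈ [0, 1), non-negative
slope-type parameters, and positive power parameters, so every admissible
curve is non-decreasing in dose with p ∈ [0, 1]. Log-dose families return
g at d = 0 by continuous extension. Power parameters are unrestricted
above 0 by default; `restrict_power` constrains them to ≥ 1 (the common
regulatory restraint) for users who want to exclude supralinear shapes.
The multistage family is fixed at degree 2, keeping every family at ≤ 3
parameters.

Fitting maximizes the grouped binomial log-likelihood (probabilities
clamped to [1e-10, 1 − 1e-10]) with L-BFGS-B under box constraints.
Doses are normalized by the series maximum before optimization; fitted
parameters are converted back per family. This conditions the problem
(all slopes are O(1)) and makes BMD and BMDL *exactly* equivariant under a
change of dose units, which the test suite asserts at 1e-6.

Starts are one data-driven start (background from the control response,
slope from the top-dose response), a fixed 5-point grid per family, and 5
seeded log-normal jitters of the data-driven start; optimization stops
early once the best optimum has been replicated twice, and the best point
is polished with tightened tolerances (ftol 1e-15, gtol 1e-10). The
multi-start design makes the optimum independent of the jitter seed to
< 1e-4 in well-conditioned problems (tested).

Diagnostics per fit: scaled residuals r_i = (y_i − n_i p̂_i)/√(n_i p̂_i
(1 − p̂_i)); χ² = Σ r_i² with upper-tail p at df = max(groups − k, 1) (the
df floor avoids an undefined p when parameters ≥ groups and is flagged via
the stored df); AIC = 2k − 2LL with k the family's parameter count
(parameters pinned at bounds still count — simple and reproducible).

## Selection and scoring

Among converged fits the lowest AIC wins; ties break by fewer parameters,
then a fixed canonical family order. Scoring uses the flatness t-test:
with groups sorted by dose, Δ_i = f_{i+1} − f_i and the two-sided
one-sample t-test of mean(Δ) = 0 gives p_flat; p_flat ≤ 0.32 scores
**Good**, larger **Moderate**. Degenerate cases: zero variance with zero
mean gives p = 1 (flat); zero variance with nonzero mean gives p = 0 with
a warning (a perfectly regular trend). Series where no family converges
are demoted to **Poor**.

## Benchmark doses

Extra risk defines the BMD: (p(d) − p(0))/(1 − p(0)) = BMR, solved by
Brent root finding on [0, 10 × top tested dose] at machine precision; a
curve that never reaches the BMR in that bracket yields an undefined BMD,
reported as empty. BMD is computed at BMR = 0.10 and 0.50; the BMDL is
profiled for BMD10 only (the screening point of departure).

The BMDL reparameterizes each family so the BMD is explicit: the
slope-type parameter is solved from the extra-risk equation in closed form
(e.g. quantal linear b = −ln(1 − BMR)/β; multistage splits the pinned
total hazard between its two coefficients by an auxiliary t ∈ [0, 1]),
and the remaining parameters are re-optimized at each candidate β. The
bound is the β below the BMD where the profile deviance 2(LL_max −
LL_profile(β)) crosses χ²₁(0.90) = 2.70554 — the standard construction for
a one-sided 95% limit — located by a geometric walk (factor 0.75, warm-
started nuisance optima) and Brent root finding to 1e-8 relative
precision. If the profile never reaches the cutoff down to a negligible
dose the BMDL is undefined and flagged. Profiling can only tighten the
running LL_max, never loosen it, so the deviance is non-negative by
construction.

Curve XY coordinates sample the fitted curve on a uniform grid from 0 to
the top tested dose (100 points by default, endpoints included). The AUC
is the trapezoidal integral over the same range on a 2049-point grid,
divided by the range — a normalized [0, 1] potency summary comparable
across substances with different dose ranges. Both deliberately avoid
extrapolation beyond the tested range.

## Synthetic screens

The simulator emulates the screen's structure: 4 plates with 8 vehicle
control wells each and 32 wells per non-zero dose split round-robin across
plates; a dose ladder up to 50 µM (the chemical screening maximum) or a
percent-of-sample ladder for extracts; 24 hpf death drawn independently
per well; surviving wells drawing the endpoint incidence from a known
quantal curve. The default background response is 12%, matching the
typical per-day incidence rate of such screens, and the default truth is
quantal linear with slope 0.05/µM so the BMD10 (≈ 2.11 µM) sits inside the
tested range. Everything derives from a single seed; identical seeds give
byte-identical datasets.

What the simulator does *not* emulate: plate spatial gradients, dosing or
concentration measurement error, correlated endpoints within a well,
between-day batch effects, and behavioural trace processing. Passing
recovery tests therefore validates the estimation machinery under the
stated sampling model, not robustness to those real-data artefacts.

`recovery_experiment` runs the full per-series pipeline per replicate and
reports BMD bias/RMSE against the closed-form true BMD plus the fraction
of replicates with BMDL ≤ true BMD. Its `models` argument restricts the
fitted families: with the generating family alone it measures the
estimator's consistency and the profile bound's calibration (the
properties the acceptance suite asserts — coverage ≈ 95%, median BMD10
error ≈ 11% at 32 wells/group, < 1% at 10⁵); with all eight families it
additionally measures the cost of AIC model selection.

### Known limitation: selection-induced undercoverage

With all eight families in play at screening sample sizes, the selected
model's BMD inherits model-uncertainty that AIC cannot remove: families
without a background parameter (logistic, probit) win on sigmoidal noise
draws and push the BMD upward severalfold, and the selected-model BMDL
then covers the true BMD in roughly 75–85% of replicates rather than the
nominal 95% (the acceptance script computes this number honestly as
`bmdl_coverage_with_aic_selection_pct`). This is a documented property of
best-model selection in benchmark-dose practice, not an implementation
defect; the per-family profile bound is calibrated. Users comparing
potencies across substances should treat the QC badge and the selected
family as part of the record, and interpret BMDs far beyond the tested
range (possible because the root bracket extends to 10 × the top dose) as
qualitative "low potency" calls rather than estimates.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| control_fail_fraction | 0.5 | plate dropped when control response strictly exceeds it |
| min_dose_groups | 3 | minimum concentration groups to fit (control counts) |
| spearman_min | 0.2 | trend gate on group-level Spearman ρ |
| flat_p_cutoff | 0.32 | flatness-test p at or below ⇒ Good |
| bmr_levels | 0.10, 0.50 | extra-risk benchmark response levels |
| bmdl_confidence | 0.95 | one-sided level of the profile bound |
| curve_points | 100 | XY rows per fitted series |
| restrict_power | false | constrain Weibull/gamma α ≥ 1 |

Problem sizes used by the test suite and acceptance script — 200
replicates for recovery, 500 for coverage, 20 at 10⁵ wells/group for the
asymptotic check, and a 5-substance mixed screen for the QC tallies — were
chosen to estimate each quantity to comfortably better precision than the
bounds being checked.
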