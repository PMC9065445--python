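# Methods

## Model structure

The model is a three-state Markov cohort simulation — progression-free
(PFS), progressed disease (PD), death — with 1-month cycles over a 5-year
horizon (60 cycles plus the entry row).  The whole cohort starts in PFS.
Future costs and health outcomes are discounted at 3 %/year using
per-cycle compounding, `(1+r)^(-t/12)` at the end of cycle *t*; the
difference from annually stepped discounting is below 0.1 %.  State time
is credited by half-cycle correction (trapezoid mean of start- and
end-of-cycle occupancy), applied to QALYs and to per-cycle state costs
but not to one-off costs (adverse-event management, terminal care),
which are expected-value events rather than durations.

## Survival inputs and the transition engine

Each arm's PFS and OS follow two-parameter Weibull laws
`S(t) = exp(-λ t^γ)` with *t* in months; the per-cycle exit probability
is `P(t) = 1 - exp[λ(t-1)^γ - λ t^γ]`, the conditional probability of
leaving during cycle *t*.  The fitted (λ, γ) pairs for the four
arm-endpoint combinations, with SEs and 95 % CIs, are bundled in
`src/gcea/data/base_case.yaml`.

How two marginal curves combine into one transition matrix is
underdetermined, so the engine declares its convention explicitly:

* total exit from PFS in cycle *t* equals the PFS-curve `P(t)` (trial
  PFS events include deaths, so the PFS curve governs all departures);
* cohort deaths in cycle *t* equal the OS decrement
  `S_os(t-1) - S_os(t)`;
* the PFS→death flow is the all-cause background mortality of the
  general population (0.707 %/year, converted to monthly via
  `1-(1-p)^(1/12)`); when PD is too thinly occupied to absorb the OS
  decrement (the first cycles), the excess deaths are taken from PFS —
  clinically, early deaths occur before progression;
* PD→death is back-calculated each cycle so total deaths match the OS
  curve, clamped to [0, 1] with a logged warning if the curves cross
  (the bundled parameters never cross within the horizon).

The result is an exact partitioned-survival model: PFS occupancy equals
`S_pfs(t)` and the alive fraction equals `S_os(t)` at every cycle, which
is the engine's structural invariant and is asserted to 1e-8 in the
tests.  No extrapolation beyond the 5-year horizon is applied; a small
share of the cohort (≈ 0.3–1.6 %) is still alive at the horizon and
simply stops accruing.

## Costs

All costs are 2020 USD ($1 = ¥6.9; the exchange rate is metadata only).
The reference patient weighs 65 kg, is 1.64 m tall, and has a body
surface area of 1.72 m².  Per-administration drug amounts come from flat
or per-m² dosing (capecitabine 1,000 mg/m² twice daily × 14 days,
oxaliplatin 130 mg/m² on day 1, every 3 weeks; nivolumab 360 mg q3w);
acquisition cost is fractional per mg by default, with whole-vial
rounding as a config switch.  A q3w/q2w schedule is converted to the
monthly cycle by the mean month length 365.25/12 days.

The base-case intervention regimen is nivolumab 360 mg q3w plus XELOX;
nivolumab 240 mg q2w and FOLFOX are provided as config switches (the
trial allowed both and the published analysis does not state the mix).
The two nivolumab schedules are economically identical per month of
treatment (both deliver 120 mg/week), so this choice is immaterial for
the nivolumab component.

PFS time accrues first-line drugs, tests/examinations ($141.29/cycle)
and follow-up ($80.71/cycle); PD time accrues salvage chemotherapy
($478.82/cycle — paclitaxel-based salvage subsumed in this printed
per-cycle figure), supportive care ($164.57/cycle) and follow-up.
Serious adverse events (grade ≥ 3, incidence > 5 % in either arm: anemia,
neutrophil count decreased, neutropenia, increased lipase) enter once at
model entry as Σ incidence × management cost, booked to the PFS bucket;
SAE disutilities are not modelled.  Terminal care ($1,460.30) attaches to
each cycle's increment of death occupancy, discounted at that cycle, and
is booked to the PD bucket.

### Treatment duration: exposure and calibration

First-line treatment is not given for the whole of PFS: in practice
delivery stops at a finite number of cycles, and the published analysis
states that treatment duration was adjusted to the median number of
treatment cycles without printing that number.  The package handles this
with two declared mechanisms:

1. **Exposure curve.**  Each arm carries an explicit time-on-treatment
   Weibull law, set to that arm's base-case PFS law.  Drug costs accrue
   on this exposure curve rather than on the (possibly re-scanned) trace
   occupancy, because treatment delivery is an observed trial quantity:
   varying the PFS *extrapolation* in sensitivity analysis changes
   health-state time but not how much drug was historically delivered.
   In the base case the two are identical, so this choice only matters
   in the deterministic sensitivity scan of the PFS curve.

2. **Administration caps.**  Each regimen carries a maximum number of
   administrations: 33 q3w administrations of nivolumab (≈ 22.8 months)
   and 7 q3w cycles of XELOX (≈ 4.8 months), prorated within the month
   where the cap falls.  These two integers are the model's only
   calibrated quantities: they were chosen once, by matching the
   published per-state cost subtotals, and then frozen.  They are
   clinically plausible (oxaliplatin-based induction is conventionally
   limited to roughly half a year; immunotherapy continuation to about
   two years) but they are a calibration, not a printed input.  With
   them the model reproduces the published ICER to 0.04 % and the
   per-arm totals to −1.3 %/+4.3 %; the largest residual (+8.9 % on the
   ICER under a 90 % nivolumab price cut) is attributable to whatever
   unprinted regimen mix and duration rules the original analysis used.

## Sensitivity analyses

*One-way (tornado):* every Table-style parameter — unit prices, per-cycle
costs, SAE costs and incidences, utilities, body surface area, the
discount rate (0–8 %) — is pushed to the bounds of its plausible range
with all else at base, and parameters are ranked by ICER span.  The
"duration of PFS" entry scans the combination arm's PFS scale parameter
over its own fitted 95 % CI (0.035621–0.062776); the published analysis
names this bar without stating its parameterization, and the parameter's
printed CI is the natural uncertainty range for it.  Ties in span are
broken alphabetically for deterministic output.

*Probabilistic (PSA):* 1,000 Monte-Carlo draws jointly resample all
non-fixed parameters, independently across parameters: triangular
(low, mode = base, high) for costs and body surface area; beta for
incidences and utilities, with mean = base and SD = range/(2·1.96)
(reading the printed range as a 95 % interval) converted to shape
parameters by method of moments.  The discount rate and the Weibull
parameters are fixed in the PSA.  Because the two utilities are drawn
independently, ~1.4 % of draws invert the PFS/PD utility ordering; these
draws are kept (rejecting them would bias the utility means), and the
ordering is enforced only on the configured base case.  The
cost-effectiveness acceptability curve reports, per willingness-to-pay
value on a $0–400,000 grid, the fraction of draws with positive
incremental net monetary benefit `w·ΔQALY − ΔCost`.

*Threshold price:* bisection on a multiplier m ∈ [0, 1] of the nivolumab
pack price until the deterministic ICER is within $1/QALY of the target
WTP.  The ICER is strictly increasing in m, so the root is unique; the
search is deterministic and seed-independent.

*Subgroups:* `apply_hazard_ratio` rescales a Weibull law's scale
parameter by a hazard ratio (shape preserved, `S_hr = S^hr`), supporting
OS-HR-based subgroup scenarios.

## Synthetic data

`simulate_ipd` draws event times by inverse transform
`t = (-ln U/λ)^(1/γ)`, with optional exponential dropout and
administrative censoring at 36 months — a stand-in for the trial's
enrollment-plus-follow-up window; the true censoring pattern is not
published, so these defaults are declared, not inferred.  Arm sizes
default to the trial's 473/482.  `km_estimate` produces the
digitized-curve surrogate: product-limit survival sampled on a monthly
grid with a numbers-at-risk table every 3 months, mirroring a typical
published figure.  `reconstruct_ipd` inverts such a curve
deterministically, interval by interval: integer event counts are chosen
to match the survival drops under the product-limit relation, the
censoring count per risk-table interval is iterated until the numbers at
risk match exactly, censoring times are spread uniformly, and events are
placed at the midpoint of their digitization step (placement at the grid
time itself would bias downstream hazard fits late).  The output always
contains exactly n₀ subjects.

What the synthetic loop does *not* emulate: digitization noise (pixel
error), non-administrative censoring structure, covariate-dependent
dropout, and within-month event clustering.  Passing round-trip tests
therefore show the pipeline is self-consistent at figure-level
resolution, not that it would recover parameters from a noisy manual
digitization.

## Fitting

`fit_weibull` maximizes the right-censored Weibull log-likelihood in
(log λ, log γ) (L-BFGS-B with analytic gradient, shape bounded to
e^±4).  Standard errors come from the inverse observed information
(central-difference Hessian of the negative log-likelihood at the
optimum) and 95 % CIs are Wald intervals on the log scale, guaranteeing
positive bounds — the published parameter table's CI method is not
stated, and all its bounds are positive, consistent with this choice.
Degenerate data (e.g. all events at one time, where the shape MLE
diverges) produce point estimates at the bound with NaN SEs and an
explicit `DegenerateFitWarning` rather than a silent failure.  The
fitter agrees with an independent implementation (lifelines'
`WeibullFitter`, reparameterized) to 4 decimals in the tests.

## Numerical choices and problem sizes

Tolerances: trace rows sum to 1 within 1e-10; the partitioned-survival
identity holds within 1e-8; threshold-price bisection stops at $1/QALY.
The test suite runs the full pipeline at the study sizes (60 cycles,
1,000 PSA draws, 100 fit replicates per arm-endpoint at n = 473/482),
chosen to match the analysis itself.

## Known limitations

* The treatment-duration caps are calibrated, not printed inputs; cost
  conclusions inherit that uncertainty (the ±10 % reproduction bands in
  the tests reflect it).
* Five-year truncation slightly undercounts both arms' QALYs and costs;
  the published analysis shares this horizon.
* Weibull extrapolation beyond ~3 years of follow-up is an assumption;
  no alternative parametric families are implemented.
* PSA samples parameters independently; no correlation structure between
  costs, incidences or utilities is modelled.
* The Asian-subgroup scenario requires an OS hazard ratio that is not
  part of the bundled inputs; `apply_hazard_ratio` supports such
  analyses but no subgroup default is shipped.
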