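# Methods

## Decision problem and model structure

The package evaluates second-line pembrolizumab against single-agent
chemotherapy (paclitaxel, docetaxel or irinotecan at clinician's choice)
for advanced esophageal carcinoma from the US third-party payer
perspective, separately for the ITT, ESCC and PD-L1 CPS ≥ 10 populations.

The cohort model is a three-state *partitioned survival* model. Because
each arm's OS and PFS curves are fitted independently, they pin down the
state occupancies directly but not a unique transition matrix; reading
membership off the curves —

    pfs(t)  = min(S_PFS(t), S_OS(t)),
    pd(t)   = S_OS(t) − pfs(t),
    dead(t) = 1 − S_OS(t)

— is the standard realization consistent with exactly the quantities the
fitted curves identify. Where a fitted PFS curve crosses above its OS curve
(a real occurrence with independently fitted parametric families, e.g. the
heavy log-normal PFS tail against a gamma OS in the ITT chemotherapy arm),
PFS occupancy is clamped to OS and a warning is emitted; occupancies then
always lie in [0, 1], sum to one, and the dead fraction is non-decreasing.

## Survival machinery

Six families, time in months, in the parameterizations standard in
survival extrapolation (those of R's `flexsurv`):

| family       | parameters      | S(t) |
|--------------|-----------------|------|
| exponential  | rate            | exp(−rate·t) |
| Weibull      | shape, scale    | exp(−(t/scale)^shape) |
| gamma        | shape, rate     | 1 − P(shape, rate·t) (regularized lower incomplete gamma) |
| log-normal   | meanlog, sdlog  | 1 − Φ((ln t − meanlog)/sdlog) |
| log-logistic | shape, scale    | 1/(1 + (t/scale)^shape) |
| Gompertz     | shape, rate     | exp(−(rate/shape)(e^{shape·t} − 1)) |

The month scale and these conventions are confirmed by the packaged
parameters themselves: the log-logistic scale equals the median
(2.742 months for ITT pembrolizumab PFS) and the log-normal median
exp(meanlog) reproduces the trial's reported median OS values to within
digitization error. The gamma and Gompertz conventions are the standard
shape–rate forms; no other convention reproduces month-scale medians from
the packaged values. A Gompertz with negative shape is defective (survival
plateaus at exp(rate/shape)); quantiles beyond the eventual-event fraction
return infinity, and this case is exercised in the tests. Near-zero
Gompertz shape (|shape| < 1e−12) switches to the exponential limit to
avoid 0/0. Five families are evaluated through scipy's frozen
distributions behind this fixed parameterization surface; the Gompertz is
implemented directly since scipy's version excludes the defective case.
Sampling is inverse-transform through the closed-form quantile.

## Model settings

| setting | default | note |
|---|---|---|
| cycle length | 21 days (3-week dosing cycle) | `cycle_months = 21/30.4375` |
| horizon | 10 years → `floor(3652.5/21)` = 173 cycles | effectively exhausts all OS curves |
| discount | 3%/year on costs and effects | factor `(1.03)^(−c·21/365.25)`, continuous-in-cycles exponent |
| WTP | $150,000/QALY | |
| half-cycle correction | off | toggle averages start/end-of-cycle occupancy |
| days per month | 30.4375 | calendar mean, used only for the cycle↔month conversion |

Cycle accrual uses start-of-cycle occupancy by default (cycle 0 is the
whole cohort progression-free, matching treatment initiation); the
half-cycle flag exists because neither convention is canonical across
decision-modelling tools, and it shifts totals by only ~3%.

## Costs, utilities, adverse events

Per-cycle dollar inputs: pembrolizumab $10,323.20; chemotherapy drug cost
is the unweighted mean of paclitaxel ($79.50), docetaxel ($87.00) and
irinotecan ($61.00) = $75.83, ignoring their differing native schedules
since all prices are already expressed per cycle; administration $69.81;
laboratory $87.60; follow-up $51.50; best supportive care $117.10. The
progression-free state accrues drug + administration + laboratory +
follow-up; the progressed state accrues best supportive care + third-line
single-agent chemotherapy (same $75.83 average, in both arms — the
third-line assumption is arm-agnostic) + administration. Grade 3–4
adverse-event management costs enter once at model entry as
Σ incidence × cost per arm (no duration is defined for them); AE
disutilities are not modelled. Utilities: PFS 0.741, PD 0.581, dead 0.
Currency is a single-year USD snapshot; no inflation adjustment.

## Synthetic IPD and fitting

The published analysis fitted its curves to pseudo-individual-patient data
digitized from trial Kaplan-Meier figures; those figures are not an input
here. Instead `simulate_ipd` draws event times from any of the six
families and censors them by the earlier of an administrative cut
(default 30 months, roughly the trial follow-up) and exponential dropout
(default 0.005/month). The generator reproduces the *statistical
structure* the fitting stage assumes — independent right-censoring, no
covariates, no interval censoring — and none of the operational features
of real trial data (staggered accrual, digitization error, informative
censoring). Passing recovery tests therefore validates the estimator, not
the provenance of any particular published parameter set.

Fitting maximizes the right-censored log-likelihood
Σ_events ln f + Σ_censored ln S by L-BFGS-B on log-transformed positive
parameters (meanlog and Gompertz shape unconstrained), multi-started from
method-of-moments and exponential-equivalent initial values; gradient
tolerance 1e−8; the exponential uses its closed-form MLE
(events / total follow-up). Standard errors come from the inverse
central-difference observed information. Model selection is minimum AIC,
with ties (|ΔAIC| < 1e−6) broken by BIC and then by a fixed family order.
Right-censoring (not interval censoring) is assumed throughout.

## Sensitivity analyses

*One-way*: every cost, utility and AE-risk input is varied to ±20% of its
base value (the packaged ranges) one at a time, the full deterministic
model is rerun at each bound, and parameters are ranked by the absolute
ICER-per-QALY spread.

*Probabilistic*: 10,000 seeded Monte-Carlo iterations redraw all those
inputs jointly — beta for quantities in [0, 1], gamma for dollar amounts,
method-of-moments hyperparameters with mean = base and
sd = (high − low)/(2·1.96), i.e. the ±20% range is treated as a 95%
interval (the prevailing convention; the z-value is configurable).
Survival-curve parameters stay at their point estimates, mirroring the
scope of the published input table; occupancies are therefore constant
across draws, and the implementation precomputes each arm's discounted
occupancy streams once and revalues costs and utilities per draw (exactly
equal to rerunning the full model, which the tests assert). The CEAC
reports, per WTP value, the fraction of iterations with positive
incremental net monetary benefit WTP·ΔQALY − ΔCost; CEAC monotonicity is
not asserted anywhere since acceptability curves need not be monotone.

## Numerical and design notes

* Discounted life-years are bounded above by the undiscounted restricted
  mean survival time, itself bounded by the unrestricted mean E[T] of the
  OS distribution — a useful sanity bound when comparing any cohort
  model's output against external figures.
* With the packaged inputs the base-case ICERs computed by
  `scripts/acceptance.py` are ≈ $494,000 (ITT), $594,000 (ESCC) and
  $377,000 (CPS ≥ 10) per QALY — above the $150,000/QALY threshold in all
  three populations, with a correspondingly ≈ 0% PSA probability of
  cost-effectiveness at that threshold. The dominant drivers (tornado) are
  the progressed-state utility and the pembrolizumab price.
* Degenerate inputs are rejected early with field-naming errors: negative
  times, utilities outside [0, 1], u_PD > u_PFS, incidences outside
  [0, 1], unknown config keys, beta PSA requests whose implied variance
  exceeds m(1 − m).
* Determinism: all randomness flows through `numpy.random.Generator`
  seeds; identical config + seed gives byte-identical output files (run
  logs record a config hash and versions, deliberately no timestamps).

## Limitations

* Treatment-duration caps (e.g. a 35-cycle pembrolizumab stopping rule)
  and time-varying pricing are not modelled.
* The AE profile is the ITT safety table in all three populations (no
  subgroup safety data exist in the source inputs).
* Parametric-fit uncertainty is excluded from the PSA by design; a
  bootstrap or multivariate-normal draw over survival parameters would be
  the natural extension.
* The KM estimator delegates to lifelines and is intended for round-trip
  validation of simulated data, not for reconstructing curves from
  published figures (no digitization step is included).
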