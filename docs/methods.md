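# Methods

This note documents the model, its assumptions, the numerical choices,
and what the synthetic data do and do not establish.

## Pseudo-IPD reconstruction

Published KM figures are summarised by the digitized step curve and the
numbers-at-risk row. Reconstruction proceeds interval by interval
between consecutive at-risk times, treating intervals as half-open
[t_k, t_{k+1}):

- events are placed at the digitized drop times, with counts from the
  product-limit relation d = r·(1 − S_j/S_{j−}) evaluated on the running
  risk set r;
- censorings within an interval are pooled at the interval midpoint
  (deterministic, no sampling), with the count chosen so the end-of-
  interval risk set matches the printed at-risk figure;
- because midpoint censorings thin the risk sets of later drops, event
  and censoring counts are solved jointly by fixed-point iteration
  (converges in a few passes);
- event counts are rounded to integers with a running remainder carried
  forward so that totals are conserved;
- a drop exactly at an at-risk time belongs to the interval starting
  there, since the printed count still includes subjects about to fail;
- subjects at risk past the last tabulated time are censored at the
  later of the last curve time and last at-risk time.

The midpoint convention makes per-interval implied event counts
approximate; small deficits against the at-risk decline are absorbed by
clamping censorings at zero, and only gross inconsistencies (implied
events exceeding the at-risk decline by more than max(5, 50%)) raise a
reconstruction-infeasible error naming the interval. On simulated
five-year trial bundles the KM curve re-estimated from the
reconstruction stays within 0.02 of the source curve (typically within
0.005), and reconstructed event totals land within a few percent of the
simulation truth.

## Parametric fitting and extrapolation

Five families are fitted by right-censored maximum likelihood:
exponential, Weibull, gamma, lognormal (AFT: μ, σ of log T) and
log-logistic (scale α, shape β). The exponential, Weibull, lognormal
and log-logistic fits delegate to lifelines' univariate fitters; the
plain two-parameter gamma has no lifelines fitter and is maximised
directly (Nelder–Mead on log-parameters with scipy.stats.gamma
log-density/log-survival; x-tolerance 1e-8). Selection is by AIC
(2k − 2·logL), ties broken by fewer parameters, then by a fixed family
order.

Extrapolation blends the fitted hazard into life-table background
mortality. With trial follow-up ending at `t_obs` (default 60 months)
and a convergence window ending at `t_conv` (default 108 months, i.e.
convergence between years 5 and 9; both configurable, and the
sensitivity scenarios stretch `t_conv`):

- t < t_obs: parametric hazard;
- t_obs ≤ t < t_conv: h(t) = (1−w)·h_param(t) + w·h_bg(t) with w linear
  from 0 to 1 — the blend is on hazards, not survival, which guarantees
  a monotone survival function and continuity at both boundaries;
- t ≥ t_conv: background hazard alone. For event endpoints (RFS, DMFS)
  this means no excess relapse events in the long run, only background
  mortality.

Annual death probabilities q are converted to monthly hazards
h = −ln(1−q)/12, piecewise-constant within each age year. The survival
function is the exponential of the integrated hazard: analytic below
`t_obs`, dense trapezoid integration (step 0.125 months) above it;
against a much finer quadrature oracle the error at 10 years is below
1e-6. A proportional-hazards wrapper (S ↦ S^HR) can be applied to any
fit before blending; the background-mortality portion is never scaled.

The progression curves feeding the Markov sub-model (first-line PFS and
second-line OS after distant relapse) are fitted the same way but kept
purely parametric: they describe within-state dynamics over a few
years, where a population-mortality floor has no empirical basis, and
the model horizon truncates their tails anyway.

## Cohort model

A cohort of starting age 50 is stepped in 6-month cycles to age 100
(both configurable; the cycle length must divide the horizon). At every
cycle boundary the outer partition is read directly off the curves —
RFS = S_RFS, dead = 1 − S_OS, progressed = S_OS − S_RFS — so outer
mortality is never distorted by sub-model assumptions. If fitted curves
cross (S_RFS > S_OS), RFS is clipped to OS and a warning is issued.

New progressions each cycle, RFS(k−1) − RFS(k), split 33% locoregional
/ 67% distant (configurable `lr_share`). Within the progressed mass:

- LR → DM1 uses the DMFS-curve hazard over the model-time interval,
  multiplied by `lr_to_dm_hr` = 1.5;
- DM1 → DM2 uses the first-line-PFS curve;
- DM1 and DM2 → death use the second-line-OS curve; LR → death uses the
  same curve under a hazard ratio `lr_mortality_hr` = 0.35 (locoregional
  disease is far less lethal than distant metastasis);
- DM2 is terminal progression: best supportive care, exits only to
  death.

All probabilities are p = 1 − (S(t+Δ)/S(t))^HR. If competing exits from
a state sum past 1 (possible with coarse cycles), they are renormalised
proportionally. After the provisional flows, the three sub-model
occupancies are rescaled by one common factor so that their sum equals
the outer progressed mass — the chosen reconciliation of the two
mortality accounts: simple, conserving, and order-independent. If the
provisional mass vanishes while the outer model still has progressed
patients, the mass is re-seeded proportionally to pre-death shares
(or, failing that, to the new-entry split).

Sub-model clocks: the progression curves are indexed by time-in-state
by default, approximated by a cohort-average state age (stayers age by
one cycle, entrants start at zero — a tunnel-free approximation that
avoids state explosion). A `submodel_clock="model"` flag switches to
time-since-baseline; for memoryless (exponential) curves the two agree
exactly, which the tests exploit.

Membership is counted at cycle start and no half-cycle correction is
applied by default (a config flag reserves the option); the 1-month-
cycle sensitivity scenario bounds the discretisation effect (the ICER
moves by well under 10% on the test fixture).

## Economics

Per-state utilities (QALY weight per year) for relapse-free,
locoregional and distant-metastasis states; per-cycle state costs
(reference 6-month cycle, rescaled proportionally for other cycle
lengths). Adjuvant drug cost accrues over the first 12 months weighted
by relapse-free occupancy — treatment stops at relapse, and on-treatment
persistence beyond that is not modelled. A one-off adverse-event cost
(700 € by default) is charged at treatment start to treated strategies.
Palliative care is one 6-month block attached to each cycle's death
inflow, discounted at that cycle's start. Everything is discounted at
3%/year, evaluated at cycle starts.

The optional ageing decrement subtracts 0.00029 QALY per discounted
person-year lived beyond age 65 (off by default, exposed as a
sensitivity scenario), and a lifetime adverse-event utility decrement
per treated patient is available as a config field.

Costs are decomposed into treatment / relapse-free / locoregional /
distant-metastasis categories, with palliative care pooled into the
distant-metastasis category; whether relapse-phase drug costs belong in
the treatment row is a reporting choice on which published tables are
ambiguous — here treatment means adjuvant phase plus adverse events.

ICER = Δcost/ΔQALY with dominance flags; ΔQALY = 0 yields an undefined
ICER signal, never a number.

## Indirect comparison and projection

Bucher anchored comparisons combine log hazard ratios through a shared
comparator: ln HR_AB = ln HR_AC − ln HR_BC, variances additive, CIs
treated as log-symmetric Wald intervals with the 97.5% normal quantile
fixed at 1.959964. A second treatment is projected onto the reference
arm's fitted curves as S_proj = S_ref^(1/HR) per endpoint (OS, RFS,
DMFS), sharing the progression curves. The ±20% HR sensitivity scales
the point estimates and rounds to two decimals before use, matching how
rescaled hazard ratios are conventionally reported.

## Scenario runner

Scenarios are flat key→value overrides onto the model/economics
configuration, validated against the schema (unknown keys are an
error). Two special keys: `hr_shift` multiplies the trial-endpoint
hazards of both arms uniformly (survival-shift scenarios) and
`projection_hr_scale` rescales the projection HR set. The DSA table
carries full-precision values with display rounding (costs to 0.1 T€,
QALY to 0.01, ICER to 0.1 T€/QALY) applied last, and every row's ICER
is re-validated against its own cost/QALY columns. Runs are
deterministic: identical configurations give identical tables.

## Synthetic data

`simulate_trial` draws per-endpoint event times from named families
(treatment-arm effects as proportional hazards via inverse-CDF
sampling, U^(1/HR)), applies administrative censoring at 60 months plus
15% uniform dropout, and emits the artefacts a real analysis would
ingest: monthly-grid digitized curves, 6-monthly at-risk tables, and
per-subject truth for recovery tests. Default endpoint shapes are
five-year adjuvant-melanoma-like (≈45% relapse-free at 5 years under
observation, strong treatment effects with HRs near 0.5), but
endpoints are drawn independently per arm — real RFS/OS/DMFS are
correlated within patients, curves cannot cross by construction in real
data, and digitization noise is absent unless enabled. Passing tests
therefore establish the correctness of the machinery, not the clinical
accuracy of any particular published model.

The synthetic life table is Gompertz–Makeham,
q(age) = 1 − exp(−(a + b·e^{c·age})) with a = 5e-4, b = 3e-5, c = 0.1,
giving q(50) ≈ 0.005 and q(95) ≈ 0.33 — the magnitudes of a modern
national period life table. The economics fixture is an explicitly
synthetic placeholder (utilities 0.87/0.80/0.68, adjuvant cost
42,000 €/cycle for two cycles, first-line distant-metastasis cost
14,000 €/cycle, best-supportive-care 3,000 €/cycle, palliative block
4,000 €, adverse-event cost 700 €): unit-consistent and
order-of-magnitude plausible for a European payer, calibrated only for
tests and examples.

## Problem sizes and tolerances

Test and acceptance runs use: n = 300 per arm for reconstruction
round trips (tolerance 0.02 on survival), n = 2,000 for parameter
recovery (within 2 SE, 20 seeds) and AIC family selection (50
replicates, ≥80% correct for a log-logistic truth), n = 4,000 for the
end-to-end closed-form check (discounted life expectancy within 1%),
and machine-precision checks (1e-9 to 1e-12) for the sub-model matrix
oracle, Bucher identities, and occupancy conservation. These sizes make
sampling error small relative to each tolerance while keeping the whole
suite fast on a single CPU.

## Known limitations

- The Hoyle–Henley-style reconstruction cannot recover within-interval
  censoring patterns; midpoint pooling is an approximation that becomes
  visible when intervals are long or event counts small.
- The cohort-average time-in-state clock is exact only for memoryless
  curves; with strongly time-varying progression hazards it compresses
  the within-state age distribution.
- The proportional-hazards projection of a second treatment inherits
  every weakness of the anchored comparison it is based on: no
  population adjustment is attempted.
- State costs and utilities are constants per state; no time-on-
  treatment cost tapering, no cure-fraction models, no probabilistic
  sensitivity analysis.
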