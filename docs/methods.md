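# Methods

## The decision problem

The package models whether a nationwide advance-care-planning (ACP)
program, delivered in primary care to everyone turning 65, pays for itself
from the health system's perspective in a population at risk of dementia.
The comparator is the current situation, in which ACP uptake stays low.
An advance care directive (ACD) does not change anyone's health: its
effect is confined to the end of life, where a followed directive makes a
hospital death much less likely, and a non-hospital end-of-life year is
cheaper than a hospital one.  The question is whether those end-of-life
savings outweigh the cost of delivering the consultations.

## Model structure

A deterministic Markov cohort model with one-year cycles and six states:

```
WELL → MILD → MODERATE → SEVERE        (dementia, forward-only)
  any alive state → EOL → DEAD         (end-of-life tunnel, one cycle)
```

* Everyone enters WELL at the starting age (65 by default).
* Each cycle, an alive person may fall terminally ill and enter the
  end-of-life state with an age- and state-dependent probability
  p_EOL(a, s); this competing risk is resolved first, and the surviving
  mass then develops dementia (WELL → MILD, probability p_onset(a)) or
  progresses one stage (constant probabilities p_12, p_23).  The model
  gives no intra-cycle ordering a priori; end-of-life-first is the
  documented convention and the microsimulation oracle uses the same rule.
* EOL is a tunnel: occupied exactly one cycle, then DEAD.  Every death
  therefore passes through exactly one end-of-life year, which carries the
  end-of-life event cost and its own utility weight.
* The cohort is stratified at cycle 0 into directive holders (the
  scenario's uptake fraction) and non-holders.  Completion happens in the
  first year, while everyone is still dementia-free — ACP is only feasible
  before decision-making capacity is lost.  Health transitions are
  identical across strata and scenarios, so holder and non-holder
  occupancies stay exactly proportional; the engine exploits this by
  propagating a single unit trajectory (`markov.propagate_unit`) and
  weighting it per scenario.
* Horizon: age 110 with an alive-mass tolerance of 1e-10, plus one flush
  cycle so the final end-of-life year resolves.  The synthetic tables route
  all survivors at the oldest tabulated age into end-of-life care, which
  closes the model; records without that closure trigger a
  `HorizonWarning` and truncate, rather than fail.

## Accrual rules

Per cycle t (discount weight (1+r)^-t, r = 5%/year in the base case, 2%
and 7% as alternatives):

* **State costs / utilities** — occupancy × the age-indexed annual cost
  and utility of each alive state; the end-of-life year accrues its own
  utility u_EOL.
* **End-of-life event cost** — entrants × [h·C(a) + (1-h)·ρ·C(a)], where
  C(a) is the age-increasing hospital end-of-life cost, ρ = 0.60 the
  non-hospital/hospital cost ratio ("roughly 40% less"), and h the
  stratum's hospital-death probability: h = p_usual (0.55) for
  non-holders, h = c·p_ACP + (1-c)·p_usual for holders (compliance
  c = 0.86, p_ACP = 0.15).
* **ACP tolls (holders only)** — the initial consultation block
  (4 visits × $121.43 = 850/7, charged undiscounted at cycle 0 in both
  scenarios: the current situation's 15% completers use the same
  services), one directive review at first dementia diagnosis, and one at
  end-of-life entry.
* **Unmet-preference disutility** — subtracted from u_EOL for everyone
  whose wishes are not guiding care at the end of life: non-holders
  (preferences unknown) and holders whose directive is not followed.  The
  conservative base case sets it to zero, which makes the two scenarios'
  QALYs *bitwise* equal — the comparison is then presented as incremental
  cost, and the ICER is flagged undefined.  Any positive disutility makes
  the program strictly more effective as well as (in the base case)
  cheaper, i.e. dominant.
* Half-cycle correction is available as a toggle (trapezoid weights on the
  continuous accruals, events untouched) but off by default, matching
  yearly in-state accrual.

## Parameters that matter

| parameter | base | unit | role |
|---|---|---|---|
| uptake (current / program) | 0.15 / 0.50 | fraction | scenario difference |
| compliance c | 0.86 | probability | mixes holder hospital risk |
| p_hosp with / without followed ACD | 0.15 / 0.55 | probability | place-of-death shift |
| non-hospital cost ratio ρ | 0.60 | — | size of per-death saving |
| visits × cost | 4 × 121.43 | AUD | program delivery cost |
| review cost | 470.12 | AUD | diagnosis + end-of-life reviews |
| discount rate | 0.05 | /year | 0.02 / 0.07 alternates |
| WTP | 50 000 | AUD/QALY | NMB and CEAC reference |

With equal QALYs the incremental cost reduces (analytically) to
(uptake_p − uptake_c) × [visit block + reviews − c·(p_usual − p_ACP)·(1 − ρ)·E],
where E is the discounted expected hospital end-of-life cost per person.
Every monotonicity the tests assert (non-decreasing in ρ, visit cost,
p_ACP; non-increasing in compliance) is visible in that expression.

## Synthetic inputs and the frozen base case

The age-indexed evidence tables behind the published analysis are not
distributed in a form this package can consume, so `acpcea.synthetic`
generates them parametrically: onset risk doubling every 6 years from 0.5%/year at
65, Gompertz end-of-life entry (doubling every 8 years from 1.1%/year,
severity multipliers 1/1.3/2/3.5), hospital end-of-life cost rising 1.2%
per year of age, modest dementia-stage care costs, and utilities declining
with age and severity.  Anchors are jittered log-normally for randomised
records; utilities share one jitter factor so the severity ordering holds
for every seed.

`data/fixture_base_case.yaml` is the frozen record the analyses run on.
Two knobs — the end-of-life cost anchor (13 839.34) and the review cost
(470.12) — were solved once, linearly, so the run reproduces the published
discounted totals (6 749 / 6 682, incremental −67).  The published totals
and the published breakeven points cannot all hold at once under the
stated behavioural parameters (a 75% compliance breakeven needs a
discounted end-of-life cost burden larger than the printed totals allow),
so the fixture anchors the totals exactly and lets the breakevens fall
where they may: compliance ≈ 0.687, consultation package ≈ $677/person,
coverage exactly at the current 15% (savings scale with the coverage
difference, so the breakeven coincides with current uptake in this
structure).  All of these sit inside the brackets the published
sensitivity rows themselves imply.

Because the generator's curves are smooth parametric stand-ins, passing
tests demonstrate that the machinery — propagation, accrual, thresholds,
PSA — is correct under realistic shapes, not that the Australian evidence
base is reproduced.

## Verification

A vectorised microsimulation (`synthetic.microsim_oracle`) pushes
individuals through matrices built by the engine's own
`build_transition_matrices` (one transition definition, so disagreement
isolates accrual bugs) and accrues the same payoffs stochastically.  The
cohort recursion is required to match the 200 000-individual oracle on
cost, QALY and place-of-death fraction within 4 Monte-Carlo standard
errors on three random parameter sets.  Closed forms check the rest:
geometric-series discounting to 1e-10, the compliance-mixture hospital
probability, and the end-of-life cost arithmetic.

## Sensitivity machinery

* **One-way sweeps** substitute a single dotted parameter path and rerun
  the full two-scenario model per grid value; invalid substitutions flag
  the row rather than abort the table.
* **Threshold search** is plain bisection on incremental cost (the
  equal-QALY framing makes cost the conclusion), parameter-scale tolerance
  1e-4, deterministic, with endpoint signs reported when no bracket
  exists.  Use the `nmb` objective when QALYs differ.
* **PSA** draws each uncertain parameter independently — beta for
  probabilities/utilities, gamma for costs, moment-matched to (mean, SE);
  zero SE collapses to the mean.  Behavioural parameters with one
  underlying truth (compliance, place-of-death preferences) are sampled
  once and applied to both scenario blocks via the `acp.` path prefix.  No
  correlation structure is modelled.  The default spreads encode the wide
  behavioural uncertainty the evidence carries (SE 0.07–0.12 on the beta
  parameters, 0.20 on the end-of-life cost scale).  5000 draws run in
  ~20 s because each draw reuses one unit-trajectory propagation for both
  scenarios.  A draw counts as cost-effective when NMB ≥ 0 (ties
  included); the CEAC re-evaluates the stored draws on a WTP grid, never
  re-samples — and is exactly flat when the QALY difference is zero.

## Numerical choices and degenerate inputs

* Age lookups are exact-match with last-value-carried-forward; asking for
  an age before a table's first row is an error.
* Probability conservation is enforced to 1e-12 per cycle in tests; the
  recursion is linear algebra on a 6-vector, so drift stays at machine
  epsilon.
* ICER is declared undefined below |ΔQALY| = 1e-12; dominance
  classification uses a $1e-9 cost tie band.
* Zero-death traces make the place-of-death distribution an explicit
  error, not a NaN surprise (accrual stores NaN and carries on).
* PSA draws that fail validation are resampled up to 20 times, then raise.

## Limitations

* Health-system perspective only: no carer or productivity costs, which
  would favour the program further.
* Directive completion is a point event at cohort entry; gradual uptake
  over several years is not modelled.
* End-of-life care is a single mixed hospital/non-hospital year; no
  within-year intensity gradation.
* The synthetic evidence curves are calibrated stand-ins, and the
  published breakeven points are only bracketed, not reproduced exactly —
  see the fixture discussion above.
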