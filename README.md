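# acpcea — cost-effectiveness of a nationwide advance-care-planning program

`acpcea` is a health-economic decision model asking whether a nationwide
advance-care-planning (ACP) program — a short series of primary-care
consultations in which people aged 65+ record an advance care directive
before dementia can erode their capacity to do so — saves the health
system money compared with today's low-uptake status quo.  It is written
for health economists and health-services researchers who want a fully
inspectable, scriptable replacement for a spreadsheet or TreeAge-style
model: every input is an explicit row in a YAML record, every result is
reproducible from a seed, and the cohort engine is verified against an
independent microsimulation.

## The model in brief

A life-time Markov cohort model with one-year cycles over six states —
well, mild/moderate/severe dementia (forward-only), a one-year end-of-life
tunnel, and death.  Dementia onset and end-of-life entry risks rise with
age; progression is constant.  Both scenarios share identical
epidemiology: a directive only changes what happens in the final year of
life.  For a directive holder the probability of dying in hospital is

```
h = c · p_ACP + (1 − c) · p_usual        (base: 0.86·0.15 + 0.14·0.55 = 0.206)
```

against `p_usual = 0.55` without one, and a non-hospital end-of-life year
costs 60% of a hospital one.  Discounted lifetime cost per person is the
sum of state care costs, the mixed end-of-life event cost, and the
program's consultation costs; QALYs weight occupancy by age/state
utilities.  With the conservative zero-disutility assumption both
scenarios accrue identical QALYs, so the headline quantity is the
incremental cost, supplemented by breakeven (bisection) analyses and a
5000-draw probabilistic sensitivity analysis with a cost-effectiveness
acceptability curve at AUD 50,000/QALY.

## Worked example

```python
from acpcea import evaluate_comparison, find_threshold, calibrated_fixture

p = calibrated_fixture()                    # frozen base-case record
current, program, ce = evaluate_comparison(p)
print(round(current.discounted_cost, 2))    # 6749.0   $/person, current situation
print(round(program.discounted_cost, 2))    # 6682.0   $/person, ACP program
print(round(ce.delta_cost, 2))              # -67.0    incremental cost
print(ce.delta_qaly, ce.icer)               # 0.0 None (equal QALYs -> no ICER)
print(ce.dominance)                         # cost-saving-equal-QALY

th = find_threshold(p, "acp.compliance", (0.5, 0.86))
print(round(th.threshold, 3))               # 0.687  compliance breakeven
```

Read: at 50% program uptake the program costs $67 less per person over a
lifetime than the current situation while delivering the same QALYs — the
end-of-life savings of the extra directive holders more than cover the
consultations — and this stops being true if fewer than ~69% of
directives are actually followed.

The same numbers from the shell:

```bash
acpcea synth params.yaml            # write the base-case record
acpcea run params.yaml              # two-scenario comparison report
acpcea sweep params.yaml --parameter costs.r_nonhosp --values 0.5,0.6,0.7
acpcea threshold params.yaml --parameter acp.compliance --lo 0.5 --hi 0.86
acpcea psa params.yaml --n-draws 5000 --seed 13 --plot
```

## Repository layout

- `src/acpcea/` — the library: `parameters` (validated YAML record),
  `markov` (cohort engine), `economics` (accrual and comparison),
  `sensitivity` (sweeps, thresholds, PSA), `synthetic` (input generator,
  frozen fixture, microsimulation oracle), `cli`, `reporting`.
- `analysis/01_inputs.py … 04_psa.py` — numbered drivers that materialise
  the inputs, the base-case and sensitivity tables, the breakevens and
  the PSA, writing their tables and figures under `results/`.
- `docs/methods.md` — model assumptions, accrual rules, calibration and
  limitations.

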