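"""Discounted cost and QALY accrual over a cohort trace, and scenario comparison.

Costs fall into three groups:

* annual care costs of the alive health states (well + dementia stages);
* the end-of-life event: one hospital or non-hospital end-of-life year,
  mixed by the stratum's hospital-death probability, charged in the cycle
  the person enters end-of-life care;
* advance-care-planning tolls for directive holders — the initial block of
  consultations at cycle 0, a directive review at first dementia diagnosis
  and another at end-of-life entry.

QALYs weight occupancy by age/state utilities; the end-of-life year uses
its own utility, reduced by the unmet-preference disutility for everyone
whose wishes are not guiding care (non-holders, and holders whose
directive is not followed).  In the conservative base case that disutility
is zero, so both scenarios accrue identical QALYs and the comparison is
presented as incremental cost rather than an ICER.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .markov import CohortTrace, _table_on_ages, build_trace
from .parameters import ACPParams, ModelParameters
from .states import ALIVE_STATES, HealthState

_QALY_EPS = 1e-12


class ConsistencyError(ValueError):
    """A trace was paired with parameters or a scenario it was not built from."""


def discount_factor(cycle: int | np.ndarray, rate: float) -> float | np.ndarray:
    """Per-cycle discount weight ``(1 + rate) ** -cycle`` (cycle 0 undiscounted)."""
    if rate <= -1.0:
        raise ValueError(f"discount rate {rate} must be > -1")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


def eol_hospital_probability(stratum: str, acp: ACPParams) -> float:
    """Probability that a death in ``stratum`` happens in hospital.

    A non-holder dies in hospital with the usual-care probability.  A
    holder's directive is followed with probability ``compliance``, in which
    case the (low) directive hospital probability applies; otherwise care
    falls back to the usual-care probability.
    """
    if stratum == "non_holder":
        return acp.p_hosp_usual
    if stratum == "holder":
        return acp.compliance * acp.p_hosp_acp + (1.0 - acp.compliance) * acp.p_hosp_usual
    raise ValueError(f"unknown stratum {stratum!r}")


def expected_eol_cost(
    stratum: str, age: int, p: ModelParameters, scenario: str = "program"
) -> float:
    """Expected cost of the end-of-life year entered at ``age``.

    ``h * C(age) + (1 - h) * r_nonhosp * C(age)`` with ``h`` the stratum's
    hospital probability and ``C`` the hospital end-of-life cost table;
    holders additionally receive a final directive review at entry.
    """
    acp = p.acp(scenario)
    h = eol_hospital_probability(stratum, acp)
    c_hosp = p.costs.c_eol_hospital_by_age(age)
    cost = h * c_hosp + (1.0 - h) * p.costs.r_nonhosp * c_hosp
    if stratum == "holder":
        cost += p.costs.c_review_visit
    return cost


@dataclass
class ScenarioResult:
    """Lifetime per-person outcomes of one scenario."""

    scenario: str
    discounted_cost: float
    discounted_qaly: float
    p_hospital_death: float
    undiscounted_cost: float
    undiscounted_qaly: float
    trace: CohortTrace
    cost_by_cycle: np.ndarray
    qaly_by_cycle: np.ndarray

    def cycle_table(self):
        """Per-cycle accrual table (pandas DataFrame) for CSV export."""
        import pandas as pd

        tr = self.trace
        df = pd.DataFrame(
            {
                "cycle": np.arange(tr.n_cycles),
                "age": tr.ages,
                "cost": self.cost_by_cycle,
                "qaly": self.qaly_by_cycle,
            }
        )
        for s in HealthState:
            df[s.name.lower()] = tr.occupancy[:, :, s].sum(axis=1)
        return df


def accumulate(trace: CohortTrace, p: ModelParameters, scenario: str) -> ScenarioResult:
    """Accrue discounted lifetime cost and QALYs per person over ``trace``."""
    acp = p.acp(scenario)
    if trace.scenario != scenario or abs(trace.uptake - acp.uptake) > 1e-15:
        raise ConsistencyError(
            f"trace built for scenario {trace.scenario!r} (uptake {trace.uptake}) "
            f"does not match scenario {scenario!r} (uptake {acp.uptake})"
        )

    ages = trace.ages
    unit = trace.unit
    w_holder, w_non = acp.uptake, 1.0 - acp.uptake
    n = trace.n_cycles
    cycles = np.arange(n)
    disc = discount_factor(cycles, p.econ.discount_rate)

    # continuous accruals: annual state costs and utilities (incl. the EOL year)
    c_state = np.zeros(n)
    u_state = np.zeros(n)
    for s in ALIVE_STATES:
        c_state += unit[:, s] * _table_on_ages(p.costs.c_state_by_age[s], ages)
        u_state += unit[:, s] * _table_on_ages(p.utils.u_state_by_age[s], ages)
    eol_occ = unit[:, HealthState.EOL]
    unmet = w_non + w_holder * (1.0 - acp.compliance)  # share with no followed directive
    u_cont = u_state + eol_occ * (p.utils.u_eol - p.utils.d_noncompliance * unmet)

    hcc = np.ones(n)
    if p.econ.half_cycle_correction and n > 1:
        hcc[0] = hcc[-1] = 0.5

    # event tolls: end-of-life year cost (+ final review for holders), the
    # diagnosis review, and the initial consultation block at cycle 0
    c_hosp = _table_on_ages(p.costs.c_eol_hospital_by_age, ages)
    mix = np.array(
        [eol_hospital_probability(k, acp) for k in ("holder", "non_holder")]
    )
    mix_cost = mix + (1.0 - mix) * p.costs.r_nonhosp  # per-stratum multiplier on C(age)
    eol_cost = eol_occ * c_hosp * (w_holder * mix_cost[0] + w_non * mix_cost[1])
    eol_cost += eol_occ * w_holder * p.costs.c_review_visit
    review_dx = trace.new_dementia_unit * w_holder * p.costs.c_review_visit
    events = eol_cost + review_dx
    events[0] += w_holder * p.costs.n_initial_visits * p.costs.c_acp_visit

    cost_by_cycle = c_state * hcc + events
    qaly_by_cycle = u_cont * hcc

    pod = place_of_death_safe(trace, p, scenario)
    return ScenarioResult(
        scenario=scenario,
        discounted_cost=float(cost_by_cycle @ disc),
        discounted_qaly=float(qaly_by_cycle @ disc),
        p_hospital_death=pod,
        undiscounted_cost=float(cost_by_cycle.sum()),
        undiscounted_qaly=float(qaly_by_cycle.sum()),
        trace=trace,
        cost_by_cycle=cost_by_cycle * disc,
        qaly_by_cycle=qaly_by_cycle * disc,
    )


def place_of_death_safe(trace: CohortTrace, p: ModelParameters, scenario: str) -> float:
    from .markov import place_of_death_distribution

    try:
        return place_of_death_distribution(trace, p, scenario)["hospital"]
    except ValueError:  # degenerate horizon with zero deaths
        return float("nan")


@dataclass
class CEResult:
    """Incremental comparison of an alternative against a reference scenario."""

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    nmb: float
    dominance: str
    wtp: float

    @property
    def cost_effective(self) -> bool:
        """Cost-effective at the stated willingness-to-pay (NMB >= 0)."""
        return self.nmb >= 0.0


def compare(ref: ScenarioResult, alt: ScenarioResult, wtp: float) -> CEResult:
    """Incremental cost/QALY of ``alt`` vs ``ref`` with dominance classification.

    The ICER is flagged undefined (None) when the QALY difference is below
    1e-12 — the equal-QALY case in which incremental cost is the headline
    quantity — and the net monetary benefit ``wtp * dQALY - dCost`` is
    always computed for PSA machinery.
    """
    dc = alt.discounted_cost - ref.discounted_cost
    dq = alt.discounted_qaly - ref.discounted_qaly
    icer = None if abs(dq) < _QALY_EPS else dc / dq
    nmb = wtp * dq - dc

    cost_eps = 1e-9
    if abs(dq) < _QALY_EPS:
        if dc < -cost_eps:
            dominance = "cost-saving-equal-QALY"
        elif dc > cost_eps:
            dominance = "dominated"
        else:
            dominance = "equivalent"
    elif dq > 0:
        dominance = "dominant" if dc <= cost_eps else "tradeoff"
    else:
        dominance = "dominated" if dc >= -cost_eps else "tradeoff"
    return CEResult(delta_cost=dc, delta_qaly=dq, icer=icer, nmb=nmb, dominance=dominance, wtp=wtp)


def run_scenario(p: ModelParameters, scenario: str) -> ScenarioResult:
    """Build the trace and accrue outcomes for one scenario."""
    return accumulate(build_trace(p, scenario), p, scenario)


def evaluate_comparison(
    p: ModelParameters, wtp: Optional[float] = None
) -> tuple[ScenarioResult, ScenarioResult, CEResult]:
    """Full two-scenario run: (current, program, incremental comparison).

    The two scenarios share one propagation of the health trajectory
    (epidemiology is identical by construction), so this is cheaper than —
    but numerically identical to — two independent :func:`run_scenario`
    calls.
    """
    from .markov import propagate_unit, trace_from_unit

    ut = propagate_unit(p)
    cur = accumulate(trace_from_unit(ut, "current", p.acp_current.uptake), p, "current")
    prog = accumulate(trace_from_unit(ut, "program", p.acp_program.uptake), p, "program")
    return cur, prog, compare(cur, prog, p.econ.wtp if wtp is None else wtp)
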