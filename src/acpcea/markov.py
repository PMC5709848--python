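"""Cohort state-transition engine.

A deterministic Markov cohort recursion with one-year cycles.  Everyone
enters well at the starting age; each cycle a person may fall terminally
ill and enter the one-year end-of-life (EOL) tunnel state (resolved first,
as the competing risk), and the survivors may develop or progress dementia
(forward-only: mild → moderate → severe).  EOL empties into the absorbing
DEAD state the next cycle, so every death passes through exactly one
end-of-life year.

The cohort is stratified by advance-care-directive possession.  Directive
completion happens in the first cycle, while the whole cohort is still
dementia-free, so the stratum split is fixed at the scenario's uptake at
cycle 0.  Health transitions are identical across strata and scenarios —
the directive changes end-of-life care decisions, never disease or death
risk — so holder/non-holder occupancies stay exactly proportional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .parameters import AgeTable, ModelParameters
from .states import ALIVE_STATES, N_STATES, HealthState

ALIVE_TOL = 1e-10
STRATA = ("holder", "non_holder")

W, M, MO, SV, EO, D = (
    HealthState.WELL,
    HealthState.MILD,
    HealthState.MODERATE,
    HealthState.SEVERE,
    HealthState.EOL,
    HealthState.DEAD,
)


class HorizonWarning(UserWarning):
    """Alive mass remained above tolerance when the age horizon was reached."""


def _table_on_ages(table: AgeTable, ages: np.ndarray) -> np.ndarray:
    """Vectorised last-value-carried-forward lookup on integer ages."""
    tab_ages = np.asarray(table.ages)
    if ages.min() < tab_ages[0]:
        raise KeyError(
            f"age {int(ages.min())} precedes first tabulated age {int(tab_ages[0])}"
        )
    idx = np.searchsorted(tab_ages, ages, side="right") - 1
    return np.asarray(table.values)[idx]


def transition_row(state: HealthState, age: int, p: ModelParameters) -> np.ndarray:
    """One-cycle transition probabilities out of ``state`` at ``age``.

    This is the model's single transition definition: the cohort engine and
    the microsimulation oracle both consume matrices built from it.
    Competing risks within a cycle are resolved with end-of-life entry
    first; the remaining mass splits between staying and progressing.
    """
    row = np.zeros(N_STATES)
    if state == D:
        row[D] = 1.0
        return row
    if state == EO:  # one-cycle tunnel: end-of-life year always ends in death
        row[D] = 1.0
        return row

    p_eol = p.epi.p_eol_by_age_state[state](age)
    stay = 1.0 - p_eol
    row[EO] = p_eol
    if state == W:
        p_onset = p.epi.p_onset_by_age(age)
        row[M] = stay * p_onset
        row[W] = stay * (1.0 - p_onset)
    elif state == M:
        row[MO] = stay * p.epi.p_mild_to_mod
        row[M] = stay * (1.0 - p.epi.p_mild_to_mod)
    elif state == MO:
        row[SV] = stay * p.epi.p_mod_to_sev
        row[MO] = stay * (1.0 - p.epi.p_mod_to_sev)
    else:  # SEVERE: no further progression
        row[SV] = stay
    return row


def build_transition_matrices(p: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrices for every model age.

    Returns ``(ages, P)`` where ``ages`` runs from ``start_age`` to
    ``max_age`` and ``P[i]`` is the 6x6 matrix at ``ages[i]``, built
    vectorised but cell-for-cell identical to :func:`transition_row`.
    """
    econ = p.econ
    ages = np.arange(econ.start_age, econ.max_age + 1)
    n = ages.size
    P = np.zeros((n, N_STATES, N_STATES))

    p_eol = {s: _table_on_ages(p.epi.p_eol_by_age_state[s], ages) for s in ALIVE_STATES}
    onset = _table_on_ages(p.epi.p_onset_by_age, ages)
    p12, p23 = p.epi.p_mild_to_mod, p.epi.p_mod_to_sev

    P[:, W, EO] = p_eol[W]
    P[:, W, M] = (1 - p_eol[W]) * onset
    P[:, W, W] = (1 - p_eol[W]) * (1 - onset)
    P[:, M, EO] = p_eol[M]
    P[:, M, MO] = (1 - p_eol[M]) * p12
    P[:, M, M] = (1 - p_eol[M]) * (1 - p12)
    P[:, MO, EO] = p_eol[MO]
    P[:, MO, SV] = (1 - p_eol[MO]) * p23
    P[:, MO, MO] = (1 - p_eol[MO]) * (1 - p23)
    P[:, SV, EO] = p_eol[SV]
    P[:, SV, SV] = 1 - p_eol[SV]
    P[:, EO, D] = 1.0
    P[:, D, D] = 1.0
    return ages, P


@dataclass
class CohortTrace:
    """State occupancy fractions by cycle, stratified by directive possession.

    ``occupancy[t, k, s]`` is the fraction of the initial cohort that is in
    health state ``s`` of stratum ``k`` (0 = holder, 1 = non-holder) at the
    start of cycle ``t``; each cycle's total is 1.  ``ages[t]`` is the
    cohort age during cycle ``t`` (capped at ``max_age`` for lookups).
    Because strata evolve proportionally, ``unit[t, s]`` holds the shared
    per-person health trajectory and ``occupancy = weights x unit``.
    """

    scenario: str
    uptake: float
    ages: np.ndarray
    occupancy: np.ndarray
    unit: np.ndarray
    new_dementia_unit: np.ndarray
    converged: bool
    residual_alive: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def eol_entrants(self) -> np.ndarray:
        """Per-cycle fraction entering the end-of-life year, by stratum."""
        return self.occupancy[:, :, EO]

    @property
    def stratum_weights(self) -> np.ndarray:
        return np.array([self.uptake, 1.0 - self.uptake])


@dataclass
class UnitTrace:
    """Stratum-independent per-person health trajectory.

    Health transitions do not depend on directive possession or scenario,
    so one propagation serves both strata of both scenarios.
    """

    ages: np.ndarray
    unit: np.ndarray
    new_dementia_unit: np.ndarray
    converged: bool
    residual_alive: float


def propagate_unit(p: ModelParameters) -> UnitTrace:
    """Propagate one person-mass from ``start_age`` until death or the horizon.

    The run stops once alive mass (anything not DEAD) falls below 1e-10,
    else at ``max_age`` plus one flush cycle that lets the final
    end-of-life year resolve; remaining alive mass at that point is
    reported via :class:`HorizonWarning`, not an error.
    """
    ages_grid, P = build_transition_matrices(p)
    max_cycles = ages_grid.size + 1  # + flush cycle at the horizon

    unit = np.zeros((max_cycles + 1, N_STATES))
    new_dem = np.zeros(max_cycles + 1)
    unit[0, W] = 1.0
    n_used = max_cycles + 1
    for t in range(max_cycles):
        i = min(t, ages_grid.size - 1)  # carry the last age's matrix forward
        unit[t + 1] = unit[t] @ P[i]
        new_dem[t + 1] = unit[t, W] * P[i, W, M]
        if 1.0 - unit[t + 1, D] < ALIVE_TOL:
            n_used = t + 2
            break

    unit = unit[:n_used]
    new_dem = new_dem[:n_used]
    ages = np.minimum(p.econ.start_age + np.arange(n_used), p.econ.max_age)
    residual = float(1.0 - unit[-1, D])
    converged = residual < ALIVE_TOL
    if not converged:
        warnings.warn(
            f"alive mass {residual:.3e} remains at age horizon {p.econ.max_age}",
            HorizonWarning,
            stacklevel=2,
        )

    return UnitTrace(
        ages=ages,
        unit=unit,
        new_dementia_unit=new_dem,
        converged=converged,
        residual_alive=residual,
    )


def trace_from_unit(ut: UnitTrace, scenario: str, uptake: float) -> CohortTrace:
    """Split a unit trajectory into directive strata at the given uptake."""
    weights = np.array([uptake, 1.0 - uptake])
    occupancy = weights[None, :, None] * ut.unit[:, None, :]
    return CohortTrace(
        scenario=scenario,
        uptake=uptake,
        ages=ut.ages,
        occupancy=occupancy,
        unit=ut.unit,
        new_dementia_unit=ut.new_dementia_unit,
        converged=ut.converged,
        residual_alive=ut.residual_alive,
    )


def build_trace(p: ModelParameters, scenario: str) -> CohortTrace:
    """Propagate the cohort for one scenario.

    Cycle 0 places the whole cohort in WELL at ``start_age``, split into
    directive strata by the scenario's uptake; see :func:`propagate_unit`
    for the horizon rules.
    """
    return trace_from_unit(propagate_unit(p), scenario, p.acp(scenario).uptake)


def place_of_death_distribution(
    trace: CohortTrace, p: ModelParameters, scenario: str
) -> dict[str, float]:
    """Fractions of all deaths occurring in vs. outside hospital.

    End-of-life entrants in each stratum are weighted by the
    compliance-mixed hospital probability: non-holders die in hospital with
    the usual-care probability; holders with a followed directive die in
    hospital with the (much lower) directive probability.
    """
    from .economics import eol_hospital_probability

    acp = p.acp(scenario)
    entrants = trace.eol_entrants.sum(axis=0)  # per stratum
    total = float(entrants.sum())
    if total <= 0.0:
        raise ValueError("no deaths in trace: place-of-death distribution undefined")
    h = np.array(
        [eol_hospital_probability("holder", acp), eol_hospital_probability("non_holder", acp)]
    )
    hospital = float((entrants * h).sum() / total)
    return {"hospital": hospital, "non_hospital": 1.0 - hospital}
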