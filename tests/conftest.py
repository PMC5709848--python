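"""Shared fixtures: generated records, the frozen base case, and a
hand-constructible flat record whose expectations can be worked out on paper."""

from __future__ import annotations

import pytest

from acpcea import (
    ACPParams,
    AgeTable,
    CostParams,
    EconSettings,
    EpidemiologyParams,
    ModelParameters,
    UtilityParams,
    calibrated_fixture,
    generate_parameters,
)
from acpcea.parameters import validate_parameters
from acpcea.states import ALIVE_STATES


def flat_params(
    p_eol: float = 0.2,
    onset: float = 0.1,
    p12: float = 0.25,
    p23: float = 0.25,
    c_state: tuple = (0.0, 500.0, 1000.0, 1500.0),
    c_eol: float = 50_000.0,
    r_nonhosp: float = 0.6,
    utilities: tuple = (0.84, 0.69, 0.53, 0.35),
    u_eol: float = 0.35,
    d_noncompliance: float = 0.0,
    uptake_current: float = 0.15,
    uptake_program: float = 0.50,
    compliance: float = 0.86,
    p_hosp_acp: float = 0.15,
    p_hosp_usual: float = 0.55,
    n_initial_visits: int = 4,
    c_acp_visit: float = 850.0 / 7.0,
    c_review: float = 470.0,
    discount: float = 0.05,
    start_age: int = 65,
    max_age: int = 95,
    closure: bool = True,
    half_cycle_correction: bool = False,
) -> ModelParameters:
    """Age-constant record (closure optionally routes the last age to EOL)."""

    def table(v: float, close: bool = False) -> AgeTable:
        if close:
            return AgeTable((start_age, max_age), (v, 1.0))
        return AgeTable((start_age,), (v,))

    return ModelParameters(
        epi=EpidemiologyParams(
            p_onset_by_age=table(onset),
            p_mild_to_mod=p12,
            p_mod_to_sev=p23,
            p_eol_by_age_state={s: table(p_eol, close=closure) for s in ALIVE_STATES},
        ),
        costs=CostParams(
            c_state_by_age={s: table(c) for s, c in zip(ALIVE_STATES, c_state)},
            c_eol_hospital_by_age=table(c_eol),
            r_nonhosp=r_nonhosp,
            c_acp_visit=c_acp_visit,
            n_initial_visits=n_initial_visits,
            c_review_visit=c_review,
        ),
        utils=UtilityParams(
            u_state_by_age={s: table(u) for s, u in zip(ALIVE_STATES, utilities)},
            u_eol=u_eol,
            d_noncompliance=d_noncompliance,
        ),
        acp_current=ACPParams(uptake_current, compliance, p_hosp_acp, p_hosp_usual),
        acp_program=ACPParams(uptake_program, compliance, p_hosp_acp, p_hosp_usual),
        econ=EconSettings(
            discount_rate=discount,
            start_age=start_age,
            max_age=max_age,
            half_cycle_correction=half_cycle_correction,
        ),
    )


@pytest.fixture(scope="session")
def base_params():
    p = generate_parameters(seed=1)
    assert validate_parameters(p) == []
    return p


@pytest.fixture(scope="session")
def fixture_params():
    return calibrated_fixture()
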