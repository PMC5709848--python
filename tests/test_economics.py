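"""Accrual and comparison: discounting, end-of-life cost mixtures, QALY rules."""

import numpy as np
import pytest

from acpcea import (
    accumulate,
    build_trace,
    compare,
    discount_factor,
    eol_hospital_probability,
    evaluate_comparison,
    expected_eol_cost,
    run_scenario,
    substitute,
)
from acpcea.economics import ConsistencyError
from acpcea.parameters import ACPParams

from conftest import flat_params


class TestDiscounting:
    def test_cycle_zero_is_undiscounted(self):
        assert discount_factor(0, 0.05) == 1.0
        assert discount_factor(0, 0.0) == 1.0

    def test_one_cycle_closed_form(self):
        assert discount_factor(1, 0.05) == pytest.approx(1 / 1.05)

    def test_thirty_cycle_annuity_matches_geometric_series(self):
        cycles = np.arange(30)
        total = discount_factor(cycles, 0.05).sum()
        geometric = (1 - 1.05 ** (-30)) / (1 - 1 / 1.05)  # annuity-due closed form
        assert total == pytest.approx(geometric, abs=1e-10)

    def test_rate_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -1.0)


class TestEolHospitalProbability:
    def test_non_holder_uses_usual_care_probability(self):
        assert eol_hospital_probability("non_holder", ACPParams(0.5)) == 0.55

    def test_fully_compliant_holder_uses_directive_probability(self):
        assert eol_hospital_probability("holder", ACPParams(0.5, compliance=1.0)) == 0.15

    def test_compliance_mixture(self):
        acp = ACPParams(0.5, compliance=0.86, p_hosp_acp=0.15, p_hosp_usual=0.55)
        assert eol_hospital_probability("holder", acp) == pytest.approx(0.206)


class TestExpectedEolCost:
    def test_unit_ratio_makes_cost_place_independent(self):
        p = flat_params(r_nonhosp=1.0, c_eol=40_000.0, c_review=0.0)
        assert expected_eol_cost("holder", 70, p) == expected_eol_cost("non_holder", 70, p)

    def test_certain_hospitalisation_charges_full_cost_plus_review(self):
        p = flat_params(p_hosp_acp=1.0, p_hosp_usual=1.0, c_eol=40_000.0, c_review=470.0)
        assert expected_eol_cost("non_holder", 70, p) == pytest.approx(40_000.0)
        assert expected_eol_cost("holder", 70, p) == pytest.approx(40_470.0)

    def test_holder_mixture_arithmetic(self):
        p = flat_params(c_eol=50_000.0, r_nonhosp=0.6, compliance=0.86, c_review=470.0)
        # h = 0.206 -> 50000 * (0.206 + 0.794 * 0.6) = 34120, plus the review
        assert expected_eol_cost("holder", 70, p) == pytest.approx(34_120.0 + 470.0)


class TestAccumulate:
    def test_zero_discount_equates_discounted_and_undiscounted(self):
        p = flat_params(discount=0.0)
        res = run_scenario(p, "program")
        assert res.discounted_cost == pytest.approx(res.undiscounted_cost)
        assert res.discounted_qaly == pytest.approx(res.undiscounted_qaly)

    def test_discounted_below_undiscounted_at_positive_rate(self, base_params):
        res = run_scenario(base_params, "current")
        assert res.discounted_cost < res.undiscounted_cost

    def test_zero_disutility_gives_identical_qalys_across_scenarios(self, base_params):
        cur, prog, ce = evaluate_comparison(base_params)
        assert base_params.utils.d_noncompliance == 0.0
        assert ce.delta_qaly == 0.0  # exact, not approximate

    def test_positive_disutility_makes_program_strictly_more_effective(self):
        p = flat_params(d_noncompliance=0.1)
        cur, prog, ce = evaluate_comparison(p)
        assert prog.discounted_qaly > cur.discounted_qaly
        assert ce.delta_qaly > 0

    def test_coinciding_scenarios_yield_identical_results(self):
        p = flat_params(uptake_current=0.3, uptake_program=0.3)
        cur, prog, ce = evaluate_comparison(p)
        assert cur.discounted_cost == pytest.approx(prog.discounted_cost, abs=1e-9)
        assert ce.delta_cost == pytest.approx(0.0, abs=1e-9)
        assert ce.dominance == "equivalent"

    def test_initial_visit_toll_charged_at_cycle_zero(self):
        p = flat_params(c_state=(0.0, 0.0, 0.0, 0.0), n_initial_visits=4)
        res = run_scenario(p, "program")
        toll = 0.5 * 4 * p.costs.c_acp_visit  # uptake x visits x cost, undiscounted
        assert res.cost_by_cycle[0] == pytest.approx(toll)

    def test_trace_scenario_mismatch_raises(self, base_params):
        trace = build_trace(base_params, "current")
        with pytest.raises(ConsistencyError):
            accumulate(trace, base_params, "program")

    def test_half_cycle_correction_halves_boundary_state_accrual(self):
        p = flat_params(half_cycle_correction=True, discount=0.0)
        p0 = flat_params(half_cycle_correction=False, discount=0.0)
        res, res0 = run_scenario(p, "current"), run_scenario(p0, "current")
        assert res.discounted_qaly < res0.discounted_qaly
        # event tolls are unaffected (well-state cost is zero in this record)
        assert res.cost_by_cycle[0] == pytest.approx(res0.cost_by_cycle[0])


class TestCompare:
    def test_published_base_case_arithmetic(self, fixture_params):
        cur, prog, ce = evaluate_comparison(fixture_params)
        assert cur.discounted_cost == pytest.approx(6749.0, abs=0.5)
        assert prog.discounted_cost == pytest.approx(6682.0, abs=0.5)
        assert ce.delta_cost == pytest.approx(-67.0, abs=0.5)
        assert ce.icer is None
        assert ce.dominance == "cost-saving-equal-QALY"

    def test_antisymmetry(self, base_params):
        cur, prog, _ = evaluate_comparison(base_params)
        ab = compare(cur, prog, 50_000.0)
        ba = compare(prog, cur, 50_000.0)
        assert ab.delta_cost == pytest.approx(-ba.delta_cost)
        assert ab.delta_qaly == pytest.approx(-ba.delta_qaly)

    def test_dominant_classification_with_disutility(self):
        p = flat_params(d_noncompliance=0.1)
        cur, prog, ce = evaluate_comparison(p)
        if ce.delta_cost <= 0:
            assert ce.dominance in ("dominant",)
        assert ce.icer is not None

    def test_nmb_definition(self, base_params):
        _, _, ce = evaluate_comparison(base_params, wtp=50_000.0)
        assert ce.nmb == pytest.approx(50_000.0 * ce.delta_qaly - ce.delta_cost)


class TestMonotonicity:
    """Incremental cost must move the right way along 5-point grids."""

    @pytest.mark.parametrize(
        "path, grid, direction",
        [
            ("costs.r_nonhosp", [0.4, 0.5, 0.6, 0.7, 0.8], +1),
            ("costs.c_acp_visit", [50, 100, 150, 200, 250], +1),
            ("acp.p_hosp_acp", [0.05, 0.15, 0.25, 0.35, 0.45], +1),
            ("acp.compliance", [0.5, 0.6, 0.7, 0.8, 0.9], -1),
        ],
    )
    def test_delta_cost_direction(self, fixture_params, path, grid, direction):
        deltas = [
            evaluate_comparison(substitute(fixture_params, path, v))[2].delta_cost
            for v in grid
        ]
        diffs = np.diff(deltas) * direction
        assert (diffs >= -1e-9).all(), deltas
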