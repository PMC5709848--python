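"""Sweeps, bisection thresholds, and the probabilistic sensitivity analysis."""

import numpy as np
import pytest

from acpcea import (
    PSASpec,
    evaluate_comparison,
    find_threshold,
    one_way,
    run_psa,
    sample_parameters,
    substitute,
)
from acpcea.sensitivity import BracketError, _draw_value, default_psa_spec

from conftest import flat_params


class TestOneWay:
    def test_grid_containing_base_value_reproduces_base_row(self, fixture_params):
        base = evaluate_comparison(fixture_params)[2]
        table = one_way(fixture_params, "costs.r_nonhosp", [0.5, 0.6, 0.7])
        row = table[table["value"] == 0.6].iloc[0]
        assert row["delta_cost"] == pytest.approx(base.delta_cost, abs=1e-9)
        assert row["conclusion"] == "Cost effective"

    def test_conclusion_flips_along_compliance_grid(self, fixture_params):
        table = one_way(fixture_params, "acp.compliance", [0.60, 0.86])
        assert list(table["conclusion"]) == ["Not cost effective", "Cost effective"]

    def test_invalid_grid_value_is_flagged_not_fatal(self, fixture_params):
        table = one_way(fixture_params, "acp.compliance", [0.86, 1.5])
        assert table.iloc[0]["conclusion"] == "Cost effective"
        assert table.iloc[1]["conclusion"].startswith("invalid:")
        assert np.isnan(table.iloc[1]["delta_cost"])

    def test_delta_cost_monotone_along_sorted_ratio_grid(self, fixture_params):
        table = one_way(fixture_params, "costs.r_nonhosp", [0.4, 0.5, 0.6, 0.7, 0.8])
        assert (np.diff(table["delta_cost"]) >= -1e-9).all()


class TestFindThreshold:
    def test_recovers_root_of_linear_incremental_cost(self):
        # incremental cost is exactly linear in the per-visit cost, so two
        # model runs give an independent closed-form root
        p = flat_params()
        f = lambda v: evaluate_comparison(substitute(p, "costs.c_acp_visit", v))[2].delta_cost
        v0, v1 = 0.0, 3000.0
        a = (f(v1) - f(v0)) / (v1 - v0)
        root = v0 - f(v0) / a
        res = find_threshold(p, "costs.c_acp_visit", (v0, v1), tolerance=1e-4)
        assert res.threshold == pytest.approx(root, abs=1e-4)

    def test_result_invariant_to_bracket_widening(self, fixture_params):
        tol = 1e-4
        a = find_threshold(fixture_params, "acp.compliance", (0.55, 0.86), tolerance=tol)
        b = find_threshold(fixture_params, "acp.compliance", (0.40, 0.86), tolerance=tol)
        assert abs(a.threshold - b.threshold) <= tol
        assert a.delta_cost_at_lo > 0 > a.delta_cost_at_hi

    def test_no_sign_change_reports_endpoint_values(self, fixture_params):
        with pytest.raises(BracketError, match="f\\(0.8"):
            find_threshold(fixture_params, "acp.compliance", (0.80, 0.86))

    def test_converged_threshold_sits_at_the_sign_flip(self, fixture_params):
        res = find_threshold(fixture_params, "acp.compliance", (0.5, 0.86), tolerance=1e-3)
        f = lambda c: evaluate_comparison(substitute(fixture_params, "acp.compliance", c))[2].delta_cost
        assert f(res.threshold - 2e-3) > 0 > f(res.threshold + 2e-3)


class TestSampling:
    def test_degenerate_distributions_return_base_record(self, base_params):
        spec = PSASpec(
            distributions={
                "acp.compliance": {"family": "beta", "mean": 0.86, "se": 0.0},
                "costs.r_nonhosp": {"family": "beta", "mean": 0.60, "se": 0.0},
            },
            n_draws=3,
            seed=0,
        )
        rng = np.random.default_rng(0)
        q, sampled = sample_parameters(base_params, spec, rng)
        assert sampled == {"acp.compliance": 0.86, "costs.r_nonhosp": 0.60}
        assert q == base_params

    def test_same_seed_gives_identical_draw_sequences(self, base_params):
        spec = default_psa_spec(n_draws=5, seed=42)
        draws_a = run_psa(base_params, spec).draws
        draws_b = run_psa(base_params, spec).draws
        assert draws_a.equals(draws_b)

    def test_beta_empirical_mean_matches_specification(self):
        rng = np.random.default_rng(7)
        mean, se, n = 0.86, 0.07, 5000
        draws = np.array([_draw_value("beta", mean, se, rng) for _ in range(n)])
        assert abs(draws.mean() - mean) < 3 * se / np.sqrt(n)
        assert ((draws >= 0) & (draws <= 1)).all()

    def test_gamma_support_and_mean(self):
        rng = np.random.default_rng(8)
        draws = np.array([_draw_value("gamma", 1.0, 0.2, rng) for _ in range(5000)])
        assert (draws > 0).all()
        assert abs(draws.mean() - 1.0) < 3 * 0.2 / np.sqrt(5000)

    def test_overlarge_beta_se_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="too large"):
            _draw_value("beta", 0.5, 0.6, rng)


class TestRunPsa:
    def test_degenerate_spec_reproduces_deterministic_comparison(self, fixture_params):
        spec = PSASpec(
            distributions={"acp.compliance": {"family": "beta", "mean": 0.86, "se": 0.0}},
            n_draws=20,
            seed=1,
        )
        det = evaluate_comparison(fixture_params, wtp=spec.wtp)[2]
        res = run_psa(fixture_params, spec)
        assert (res.draws["delta_cost"] == det.delta_cost).all()
        assert res.p_ce_at_wtp in (0.0, 1.0)

    def test_ceac_at_wtp_zero_equals_cost_saving_fraction(self, fixture_params):
        res = run_psa(fixture_params, default_psa_spec(n_draws=100, seed=5))
        frac_saving = float((res.draws["delta_cost"] <= 0.0).mean())
        assert res.ceac.iloc[0]["wtp"] == 0.0
        assert res.ceac.iloc[0]["p_cost_effective"] == frac_saving

    def test_ceac_monotone_when_all_draws_gain_qalys(self):
        p = flat_params(d_noncompliance=0.1)
        res = run_psa(p, default_psa_spec(n_draws=150, seed=9))
        assert (res.draws["delta_qaly"] > 0).all()
        assert (np.diff(res.ceac["p_cost_effective"]) >= 0).all()

    def test_symmetric_draws_around_breakeven_give_even_odds(self):
        # place the compliance breakeven at 0.5 by charging visits at the
        # breakeven per-visit cost, then sample compliance ~ Beta(mean .5):
        # incremental cost is linear in compliance and the distribution is
        # symmetric, so P(cost-effective) -> 0.5
        p = flat_params()
        at_half = substitute(p, "acp.compliance", 0.5)
        root = find_threshold(at_half, "costs.c_acp_visit", (0.0, 2000.0)).threshold
        q = substitute(p, "costs.c_acp_visit", root)
        spec = PSASpec(
            distributions={"acp.compliance": {"family": "beta", "mean": 0.5, "se": 0.08}},
            n_draws=5000,
            seed=11,
        )
        res = run_psa(q, spec)
        ci_half_width = 3 * np.sqrt(0.25 / 5000)
        assert abs(res.p_ce_at_wtp - 0.5) < ci_half_width + 0.01

    def test_ceac_at_arbitrary_wtp_consistent_with_grid(self, fixture_params):
        res = run_psa(fixture_params, default_psa_spec(n_draws=50, seed=2))
        assert res.ceac_at(50_000.0) == res.p_ce_at_wtp
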