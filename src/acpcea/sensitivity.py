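"""One-way sweeps, breakeven (threshold) analysis, and second-order PSA.

One-way sweeps substitute a single parameter and rerun the full
two-scenario comparison per grid value.  Threshold analysis bisects on the
incremental cost (the study's cost-saving framing: with zero end-of-life
disutility both scenarios accrue identical QALYs, so the conclusion flips
exactly where incremental cost crosses zero).  The probabilistic
sensitivity analysis draws parameter values from per-parameter
distributions — beta for probabilities and utilities, gamma for costs, the
standard convention for second-order PSA, parameterised by mean and
standard error — reruns the model per draw, and summarises the draws as a
probability of cost-effectiveness and a cost-effectiveness acceptability
curve (CEAC).  Draws are independent across parameters (no correlation
structure is modelled) and the CEAC re-uses the stored draws at every
willingness-to-pay point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .economics import evaluate_comparison
from .parameters import ModelParameters, substitute, validate_parameters


@dataclass
class ThresholdResult:
    """Breakeven value of one parameter (incremental cost crosses zero)."""

    parameter_path: str
    threshold: float
    bracket: tuple[float, float]
    tolerance: float
    crossings_checked: int
    delta_cost_at_lo: float
    delta_cost_at_hi: float


class BracketError(ValueError):
    """The objective does not change sign over the supplied bracket."""


def _delta_cost(p: ModelParameters, path: str, value: float, objective: str) -> float:
    q = substitute(p, path, value)
    violations = validate_parameters(q)
    if violations:
        raise ValueError(
            f"substituting {path}={value} produced an invalid record:\n" + "\n".join(violations)
        )
    _, _, ce = evaluate_comparison(q)
    return ce.delta_cost if objective == "delta_cost" else -ce.nmb


def one_way(
    p: ModelParameters, parameter_path: str, grid: Iterable[float]
) -> pd.DataFrame:
    """One full two-scenario run per grid value of one parameter.

    Returns a table of (value, cost_current, cost_program, delta_cost,
    delta_qaly, conclusion); the conclusion is "Cost effective" iff the net
    monetary benefit at the record's willingness-to-pay is non-negative
    (which reduces to delta_cost <= 0 when the QALYs are equal).  Grid
    values whose substitution fails validation are flagged, not fatal.
    """
    rows = []
    for value in grid:
        q = substitute(p, parameter_path, value)
        violations = validate_parameters(q)
        if violations:
            rows.append(
                {
                    "value": value,
                    "cost_current": float("nan"),
                    "cost_program": float("nan"),
                    "delta_cost": float("nan"),
                    "delta_qaly": float("nan"),
                    "conclusion": f"invalid: {violations[0]}",
                }
            )
            continue
        cur, prog, ce = evaluate_comparison(q)
        rows.append(
            {
                "value": value,
                "cost_current": cur.discounted_cost,
                "cost_program": prog.discounted_cost,
                "delta_cost": ce.delta_cost,
                "delta_qaly": ce.delta_qaly,
                "conclusion": "Cost effective" if ce.cost_effective else "Not cost effective",
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "parameter", parameter_path)
    return out


def find_threshold(
    p: ModelParameters,
    parameter_path: str,
    bracket: tuple[float, float],
    tolerance: float = 1e-4,
    objective: str = "delta_cost",
) -> ThresholdResult:
    """Deterministic bisection for the parameter value where the conclusion flips.

    ``objective`` is the incremental cost by default (use ``"nmb"`` to
    bisect on the negated net monetary benefit when QALYs differ).  The
    endpoints must produce opposite signs; the returned bracket width is at
    most ``tolerance``.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError(f"bracket {bracket} must satisfy lo < hi")
    f_lo = _delta_cost(p, parameter_path, lo, objective)
    f_hi = _delta_cost(p, parameter_path, hi, objective)
    if f_lo == 0.0:
        return ThresholdResult(parameter_path, lo, (lo, hi), tolerance, 2, f_lo, f_hi)
    if f_hi == 0.0:
        return ThresholdResult(parameter_path, hi, (lo, hi), tolerance, 2, f_lo, f_hi)
    if math.copysign(1.0, f_lo) == math.copysign(1.0, f_hi):
        raise BracketError(
            f"no sign change for {parameter_path} over {bracket}: "
            f"f({lo})={f_lo:.6g}, f({hi})={f_hi:.6g}"
        )
    a, b, f_a = lo, hi, f_lo
    checked = 2
    while b - a > tolerance:
        mid = 0.5 * (a + b)
        f_mid = _delta_cost(p, parameter_path, mid, objective)
        checked += 1
        if f_mid == 0.0:
            a = b = mid
            break
        if math.copysign(1.0, f_mid) == math.copysign(1.0, f_a):
            a, f_a = mid, f_mid
        else:
            b = mid
    return ThresholdResult(
        parameter_path=parameter_path,
        threshold=0.5 * (a + b),
        bracket=(lo, hi),
        tolerance=tolerance,
        crossings_checked=checked,
        delta_cost_at_lo=f_lo,
        delta_cost_at_hi=f_hi,
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSASpec:
    """Distributional assumptions for the second-order PSA.

    ``distributions`` maps a parameter path (see
    :func:`acpcea.parameters.substitute` for the path syntax, including the
    ``acp.`` shared prefix and ``:scale`` table multipliers) to
    ``{"family": "beta"|"gamma", "mean": m, "se": s}``.  Probability-type
    parameters must use beta (support [0, 1]); cost-type parameters gamma
    (support [0, inf)).  ``se = 0`` collapses to the mean.
    """

    distributions: dict[str, dict]
    n_draws: int = 5000
    seed: int = 0
    wtp: float = 50_000.0
    wtp_grid: tuple[float, ...] = tuple(float(w) for w in range(0, 102_500, 2_500))
    resample_cap: int = 20


@dataclass
class PSAResult:
    """Paired incremental outcomes across Monte-Carlo parameter draws."""

    draws: pd.DataFrame  # columns: delta_cost, delta_qaly, nmb + sampled values
    p_ce_at_wtp: float
    wtp: float
    ceac: pd.DataFrame  # columns: wtp, p_cost_effective
    seed: int

    def ceac_at(self, wtp: float) -> float:
        """Fraction of stored draws cost-effective at an arbitrary WTP."""
        nmb = wtp * self.draws["delta_qaly"].to_numpy() - self.draws["delta_cost"].to_numpy()
        return float((nmb >= 0.0).mean())


def _draw_value(family: str, mean: float, se: float, rng: np.random.Generator) -> float:
    if se < 0:
        raise ValueError("standard error must be >= 0")
    if se == 0.0:
        return float(mean)
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"beta mean {mean} must lie in (0, 1)")
        v = se * se
        if v >= mean * (1.0 - mean):
            raise ValueError(f"beta se {se} too large for mean {mean}")
        nu = mean * (1.0 - mean) / v - 1.0
        return float(rng.beta(mean * nu, (1.0 - mean) * nu))
    if family == "gamma":
        if mean <= 0.0:
            raise ValueError(f"gamma mean {mean} must be > 0")
        shape = (mean / se) ** 2
        return float(rng.gamma(shape, scale=se * se / mean))
    raise ValueError(f"unknown distribution family {family!r}")


def sample_parameters(
    p: ModelParameters, spec: PSASpec, rng: np.random.Generator
) -> tuple[ModelParameters, dict[str, float]]:
    """One coherent parameter record per draw; unlisted parameters stay at base.

    A draw that fails validation is resampled up to ``spec.resample_cap``
    times, then raises.  Returns the record and the sampled values by path.
    """
    for _ in range(spec.resample_cap):
        q = p
        sampled: dict[str, float] = {}
        for path, dist in spec.distributions.items():
            value = _draw_value(dist["family"], float(dist["mean"]), float(dist["se"]), rng)
            sampled[path] = value
            q = substitute(q, path, value)
        if not validate_parameters(q):
            return q, sampled
    raise ValueError(
        f"PSA draw failed validation {spec.resample_cap} times; "
        "check the distribution specification"
    )


def run_psa(p: ModelParameters, spec: PSASpec) -> PSAResult:
    """Second-order PSA: rerun the full two-scenario model per parameter draw.

    The same seed always reproduces the same draw sequence.  The CEAC and
    the probability of cost-effectiveness are computed from the stored
    draws (no re-sampling per willingness-to-pay point); a draw counts as
    cost-effective when its net monetary benefit is >= 0.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for _ in range(int(spec.n_draws)):
        q, sampled = sample_parameters(p, spec, rng)
        _, _, ce = evaluate_comparison(q, wtp=spec.wtp)
        row = {"delta_cost": ce.delta_cost, "delta_qaly": ce.delta_qaly, "nmb": ce.nmb}
        row.update(sampled)
        records.append(row)
    draws = pd.DataFrame(records)
    dq = draws["delta_qaly"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    ceac = pd.DataFrame(
        {
            "wtp": spec.wtp_grid,
            "p_cost_effective": [float((w * dq - dc >= 0.0).mean()) for w in spec.wtp_grid],
        }
    )
    return PSAResult(
        draws=draws,
        p_ce_at_wtp=float((draws["nmb"].to_numpy() >= 0.0).mean()),
        wtp=spec.wtp,
        ceac=ceac,
        seed=spec.seed,
    )


def default_psa_spec(n_draws: int = 5000, seed: int = 0, wtp: float = 50_000.0) -> PSASpec:
    """Distributions over the study's influential parameters.

    Beta on the behavioural probabilities (shared across scenarios where
    they describe one underlying behaviour), gamma scale on the hospital
    end-of-life cost table.  Means sit at the base case; standard errors
    reflect the wide uncertainty the evidence base carries.
    """
    return PSASpec(
        distributions={
            "acp.compliance": {"family": "beta", "mean": 0.86, "se": 0.10},
            "acp_program.uptake": {"family": "beta", "mean": 0.50, "se": 0.12},
            "acp.p_hosp_acp": {"family": "beta", "mean": 0.15, "se": 0.07},
            "acp.p_hosp_usual": {"family": "beta", "mean": 0.55, "se": 0.07},
            "costs.r_nonhosp": {"family": "beta", "mean": 0.60, "se": 0.08},
            "costs.c_eol_hospital_by_age:scale": {"family": "gamma", "mean": 1.0, "se": 0.20},
        },
        n_draws=n_draws,
        seed=seed,
        wtp=wtp,
    )
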