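"""Parameter record for one model run: epidemiology, costs, utilities,
scenario-specific advance-care-planning (ACP) behaviour and economic settings.

The record is a single structured YAML document (schema ``acpcea/1``) in
which every age-indexed input appears as explicit ``[age, value]`` rows, so
each number the model consumes can be audited.  Ages are integer years;
lookups are exact-match with the last tabulated value carried forward past
the end of the table (one-year cycles make interpolation unnecessary).

Both scenarios (current situation vs. nationwide ACP program) share one
epidemiology/cost/utility block by construction — only the ACP behaviour
blocks differ — which encodes the modelling assumption that the program
changes end-of-life decisions, not disease or death risk.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .states import ALIVE_STATES, HealthState

SCHEMA_TAG = "acpcea/1"


class SchemaError(ValueError):
    """A parameter file is structurally invalid (missing/unknown field)."""


class ValidationError(ValueError):
    """A parameter record violates one or more documented invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid parameters:\n" + "\n".join(self.violations))


class AgeLookupError(KeyError):
    """Requested age precedes the first tabulated age."""


@dataclass(frozen=True)
class AgeTable:
    """Age-indexed annual quantity with last-value-carried-forward lookup."""

    ages: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.values) or not self.ages:
            raise SchemaError("age table needs equal-length, non-empty age/value rows")
        if list(self.ages) != sorted(set(self.ages)):
            raise SchemaError("age table ages must be strictly increasing integers")

    @classmethod
    def from_rows(cls, rows: Iterable[Iterable[float]]) -> "AgeTable":
        pairs = [(int(a), float(v)) for a, v in rows]
        return cls(tuple(a for a, _ in pairs), tuple(v for _, v in pairs))

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "AgeTable":
        return cls.from_rows(sorted(mapping.items()))

    def __call__(self, age: int) -> float:
        if age < self.ages[0]:
            raise AgeLookupError(f"age {age} precedes first tabulated age {self.ages[0]}")
        # exact match or carry the last earlier value forward
        idx = 0
        for i, a in enumerate(self.ages):
            if a > age:
                break
            idx = i
        return self.values[idx]

    def to_rows(self) -> list[list[float]]:
        return [[a, v] for a, v in zip(self.ages, self.values)]

    def scaled(self, factor: float) -> "AgeTable":
        return AgeTable(self.ages, tuple(v * factor for v in self.values))

    @property
    def min_age(self) -> int:
        return self.ages[0]

    def is_nondecreasing(self) -> bool:
        return all(b >= a for a, b in zip(self.values, self.values[1:]))


@dataclass
class EpidemiologyParams:
    """Disease onset, progression and mortality routing.

    Death is routed through the one-year end-of-life (EOL) state: the
    age/state-dependent ``p_eol_by_age_state`` is the annual probability of
    falling terminally ill, and everyone in EOL dies the following cycle.
    Dementia onset risk rises with age; stage progression probabilities are
    constant over time.
    """

    p_onset_by_age: AgeTable
    p_mild_to_mod: float
    p_mod_to_sev: float
    p_eol_by_age_state: dict[HealthState, AgeTable]


@dataclass
class CostParams:
    """Annual state care costs and event costs, in the record's currency.

    ``c_eol_hospital_by_age`` is the cost of a hospital-based end-of-life
    year; a non-hospital end-of-life year costs ``r_nonhosp`` times that.
    ``c_acp_visit`` is one face-to-face ACP consultation (charged
    ``n_initial_visits`` times at entry for everyone completing a directive);
    ``c_review_visit`` is one facilitated review of the directive (charged at
    first dementia diagnosis and at end-of-life entry for directive holders).
    """

    c_state_by_age: dict[HealthState, AgeTable]
    c_eol_hospital_by_age: AgeTable
    r_nonhosp: float = 0.60
    c_acp_visit: float = 850.0 / 7.0
    n_initial_visits: int = 4
    c_review_visit: float = 850.0 / 7.0


@dataclass
class UtilityParams:
    """Quality-of-life weights per state and the end-of-life disutility.

    ``d_noncompliance`` is subtracted from ``u_eol`` in the end-of-life year
    of anyone whose wishes are not guiding care: directive holders whose
    directive is not followed, and non-holders (preferences unknown).  The
    conservative base case sets it to zero.
    """

    u_state_by_age: dict[HealthState, AgeTable]
    u_eol: float
    d_noncompliance: float = 0.0


@dataclass
class ACPParams:
    """Scenario-specific advance-care-planning behaviour."""

    uptake: float
    compliance: float = 0.86
    p_hosp_acp: float = 0.15
    p_hosp_usual: float = 0.55


@dataclass
class EconSettings:
    discount_rate: float = 0.05
    cycle_length: float = 1.0
    start_age: int = 65
    max_age: int = 110
    wtp: float = 50_000.0
    half_cycle_correction: bool = False


@dataclass
class ModelParameters:
    """Complete input record for one two-scenario model run.

    ``epi``, ``costs`` and ``utils`` are shared between the scenarios by
    construction; the only scenario difference is the ACP behaviour block.
    """

    epi: EpidemiologyParams
    costs: CostParams
    utils: UtilityParams
    acp_current: ACPParams
    acp_program: ACPParams
    econ: EconSettings = field(default_factory=EconSettings)
    currency: str = "2015 Australian dollars"

    def acp(self, scenario: str) -> ACPParams:
        if scenario == "current":
            return self.acp_current
        if scenario == "program":
            return self.acp_program
        raise ValueError(f"unknown scenario {scenario!r}; expected 'current' or 'program'")


SCENARIOS = ("current", "program")

_PROB_01 = "must lie in [0, 1]"


def _check_table_prob(name: str, table: AgeTable, out: list[str], monotone: bool) -> None:
    for a, v in zip(table.ages, table.values):
        if not (0.0 <= v <= 1.0) or not math.isfinite(v):
            out.append(f"{name}[{a}] = {v} {_PROB_01}")
    if monotone and not table.is_nondecreasing():
        out.append(f"{name} must be non-decreasing in age")


def validate_parameters(p: ModelParameters) -> list[str]:
    """Return every invariant violation (empty list iff the record is valid).

    Violations are data, not exceptions; each names the offending field and
    the bound it breaks.
    """
    v: list[str] = []
    epi, costs, utils, econ = p.epi, p.costs, p.utils, p.econ

    _check_table_prob("epi.p_onset_by_age", epi.p_onset_by_age, v, monotone=True)
    for scalar_name in ("p_mild_to_mod", "p_mod_to_sev"):
        val = getattr(epi, scalar_name)
        if not (0.0 <= val <= 1.0):
            v.append(f"epi.{scalar_name} = {val} {_PROB_01}")
    for state in ALIVE_STATES:
        if state not in epi.p_eol_by_age_state:
            v.append(f"epi.p_eol_by_age_state missing state {state.name}")
            continue
        _check_table_prob(
            f"epi.p_eol_by_age_state[{state.name}]",
            epi.p_eol_by_age_state[state],
            v,
            monotone=True,
        )

    for state in ALIVE_STATES:
        if state not in costs.c_state_by_age:
            v.append(f"costs.c_state_by_age missing state {state.name}")
            continue
        tab = costs.c_state_by_age[state]
        for a, c in zip(tab.ages, tab.values):
            if c < 0 or not math.isfinite(c):
                v.append(f"costs.c_state_by_age[{state.name}][{a}] = {c} must be finite and >= 0")
    for a, c in zip(costs.c_eol_hospital_by_age.ages, costs.c_eol_hospital_by_age.values):
        if c < 0 or not math.isfinite(c):
            v.append(f"costs.c_eol_hospital_by_age[{a}] = {c} must be finite and >= 0")
    if not costs.c_eol_hospital_by_age.is_nondecreasing():
        v.append("costs.c_eol_hospital_by_age must be non-decreasing in age")
    if not (0.0 < costs.r_nonhosp <= 1.0):
        v.append(f"costs.r_nonhosp = {costs.r_nonhosp} must lie in (0, 1]")
    for scalar_name in ("c_acp_visit", "c_review_visit"):
        val = getattr(costs, scalar_name)
        if val < 0 or not math.isfinite(val):
            v.append(f"costs.{scalar_name} = {val} must be finite and >= 0")
    if costs.n_initial_visits < 1:
        v.append(f"costs.n_initial_visits = {costs.n_initial_visits} must be >= 1")

    for state in ALIVE_STATES:
        if state not in utils.u_state_by_age:
            v.append(f"utils.u_state_by_age missing state {state.name}")
    common = [s for s in ALIVE_STATES if s in utils.u_state_by_age]
    for state in common:
        tab = utils.u_state_by_age[state]
        for a, u in zip(tab.ages, tab.values):
            if not (0.0 <= u <= 1.0):
                v.append(f"utils.u_state_by_age[{state.name}][{a}] = {u} {_PROB_01}")
    # utility non-increasing across severity at every age either table indexes
    if len(common) == len(ALIVE_STATES):
        ages = sorted({a for s in common for a in utils.u_state_by_age[s].ages})
        for a in ages:
            if a < max(utils.u_state_by_age[s].min_age for s in common):
                continue
            seq = [utils.u_state_by_age[s](a) for s in common]
            if any(b > a_ + 1e-12 for a_, b in zip(seq, seq[1:])):
                v.append(f"utils.u_state_by_age at age {a} must be non-increasing across severity")
                break
    if not (0.0 <= utils.u_eol <= 1.0):
        v.append(f"utils.u_eol = {utils.u_eol} {_PROB_01}")
    if not (0.0 <= utils.d_noncompliance <= utils.u_eol):
        v.append(
            f"utils.d_noncompliance = {utils.d_noncompliance} must lie in [0, u_eol={utils.u_eol}]"
        )

    for scen in SCENARIOS:
        acp = p.acp(scen)
        for f_ in fields(acp):
            val = getattr(acp, f_.name)
            if not (0.0 <= val <= 1.0):
                v.append(f"acp_{scen}.{f_.name} = {val} {_PROB_01}")

    if not (0.0 <= econ.discount_rate < 1.0):
        v.append(f"econ.discount_rate = {econ.discount_rate} must lie in [0, 1)")
    if econ.cycle_length != 1.0:
        v.append(f"econ.cycle_length = {econ.cycle_length} must be 1 (one-year cycles)")
    if not econ.start_age < econ.max_age:
        v.append(f"econ.start_age = {econ.start_age} must be < max_age = {econ.max_age}")
    if not econ.wtp > 0:
        v.append(f"econ.wtp = {econ.wtp} must be > 0")

    # age coverage: every table must reach back to start_age
    def _covers(name: str, tab: AgeTable) -> None:
        if tab.min_age > econ.start_age:
            v.append(f"{name} starts at age {tab.min_age}, after econ.start_age = {econ.start_age}")

    _covers("epi.p_onset_by_age", epi.p_onset_by_age)
    for state, tab in epi.p_eol_by_age_state.items():
        _covers(f"epi.p_eol_by_age_state[{state.name}]", tab)
    for state, tab in costs.c_state_by_age.items():
        _covers(f"costs.c_state_by_age[{state.name}]", tab)
    _covers("costs.c_eol_hospital_by_age", costs.c_eol_hospital_by_age)
    for state, tab in utils.u_state_by_age.items():
        _covers(f"utils.u_state_by_age[{state.name}]", tab)

    return v


# ---------------------------------------------------------------------------
# serialization


def _state_tables_to_yaml(tables: Mapping[HealthState, AgeTable]) -> dict:
    return {s.name: tables[s].to_rows() for s in ALIVE_STATES if s in tables}


def _require(mapping: Mapping, key: str, context: str):
    if not isinstance(mapping, Mapping) or key not in mapping:
        raise SchemaError(f"missing field: {context}{key}")
    return mapping[key]


def _state_tables_from_yaml(node: Mapping, context: str) -> dict[HealthState, AgeTable]:
    return {
        s: AgeTable.from_rows(_require(node, s.name, context)) for s in ALIVE_STATES
    }


def parameters_to_dict(p: ModelParameters) -> dict:
    """Plain-python representation used by the YAML reader/writer."""
    return {
        "schema": SCHEMA_TAG,
        "currency": p.currency,
        "econ": {
            "discount_rate": p.econ.discount_rate,
            "cycle_length": p.econ.cycle_length,
            "start_age": p.econ.start_age,
            "max_age": p.econ.max_age,
            "wtp": p.econ.wtp,
            "half_cycle_correction": p.econ.half_cycle_correction,
        },
        "epidemiology": {
            "p_onset_by_age": p.epi.p_onset_by_age.to_rows(),
            "p_mild_to_mod": p.epi.p_mild_to_mod,
            "p_mod_to_sev": p.epi.p_mod_to_sev,
            "p_eol_by_age_state": _state_tables_to_yaml(p.epi.p_eol_by_age_state),
        },
        "costs": {
            "c_state_by_age": _state_tables_to_yaml(p.costs.c_state_by_age),
            "c_eol_hospital_by_age": p.costs.c_eol_hospital_by_age.to_rows(),
            "r_nonhosp": p.costs.r_nonhosp,
            "c_acp_visit": p.costs.c_acp_visit,
            "n_initial_visits": p.costs.n_initial_visits,
            "c_review_visit": p.costs.c_review_visit,
        },
        "utilities": {
            "u_state_by_age": _state_tables_to_yaml(p.utils.u_state_by_age),
            "u_eol": p.utils.u_eol,
            "d_noncompliance": p.utils.d_noncompliance,
        },
        "acp_current": vars(p.acp_current).copy(),
        "acp_program": vars(p.acp_program).copy(),
    }


def parameters_from_dict(doc: Mapping) -> ModelParameters:
    tag = _require(doc, "schema", "")
    if tag != SCHEMA_TAG:
        raise SchemaError(f"unsupported schema {tag!r}; expected {SCHEMA_TAG!r}")
    econ_node = _require(doc, "econ", "")
    econ = EconSettings(
        discount_rate=float(_require(econ_node, "discount_rate", "econ.")),
        cycle_length=float(_require(econ_node, "cycle_length", "econ.")),
        start_age=int(_require(econ_node, "start_age", "econ.")),
        max_age=int(_require(econ_node, "max_age", "econ.")),
        wtp=float(_require(econ_node, "wtp", "econ.")),
        half_cycle_correction=bool(_require(econ_node, "half_cycle_correction", "econ.")),
    )
    epi_node = _require(doc, "epidemiology", "")
    epi = EpidemiologyParams(
        p_onset_by_age=AgeTable.from_rows(_require(epi_node, "p_onset_by_age", "epidemiology.")),
        p_mild_to_mod=float(_require(epi_node, "p_mild_to_mod", "epidemiology.")),
        p_mod_to_sev=float(_require(epi_node, "p_mod_to_sev", "epidemiology.")),
        p_eol_by_age_state=_state_tables_from_yaml(
            _require(epi_node, "p_eol_by_age_state", "epidemiology."),
            "epidemiology.p_eol_by_age_state.",
        ),
    )
    cost_node = _require(doc, "costs", "")
    costs = CostParams(
        c_state_by_age=_state_tables_from_yaml(
            _require(cost_node, "c_state_by_age", "costs."), "costs.c_state_by_age."
        ),
        c_eol_hospital_by_age=AgeTable.from_rows(
            _require(cost_node, "c_eol_hospital_by_age", "costs.")
        ),
        r_nonhosp=float(_require(cost_node, "r_nonhosp", "costs.")),
        c_acp_visit=float(_require(cost_node, "c_acp_visit", "costs.")),
        n_initial_visits=int(_require(cost_node, "n_initial_visits", "costs.")),
        c_review_visit=float(_require(cost_node, "c_review_visit", "costs.")),
    )
    util_node = _require(doc, "utilities", "")
    utils = UtilityParams(
        u_state_by_age=_state_tables_from_yaml(
            _require(util_node, "u_state_by_age", "utilities."), "utilities.u_state_by_age."
        ),
        u_eol=float(_require(util_node, "u_eol", "utilities.")),
        d_noncompliance=float(_require(util_node, "d_noncompliance", "utilities.")),
    )

    def _acp(name: str) -> ACPParams:
        node = _require(doc, name, "")
        return ACPParams(
            uptake=float(_require(node, "uptake", f"{name}.")),
            compliance=float(_require(node, "compliance", f"{name}.")),
            p_hosp_acp=float(_require(node, "p_hosp_acp", f"{name}.")),
            p_hosp_usual=float(_require(node, "p_hosp_usual", f"{name}.")),
        )

    return ModelParameters(
        epi=epi,
        costs=costs,
        utils=utils,
        acp_current=_acp("acp_current"),
        acp_program=_acp("acp_program"),
        econ=econ,
        currency=str(_require(doc, "currency", "")),
    )


def load_parameters(path: str | Path) -> ModelParameters:
    """Read and validate a parameter file; raise on schema or invariant errors."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: top level must be a mapping")
    p = parameters_from_dict(doc)
    violations = validate_parameters(p)
    if violations:
        raise ValidationError(violations)
    return p


def write_parameters(p: ModelParameters, path: str | Path) -> None:
    """Validate and write a record so that ``load_parameters`` round-trips it."""
    violations = validate_parameters(p)
    if violations:
        raise ValidationError(violations)
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(p), fh, sort_keys=False)


def export_age_tables_csv(p: ModelParameters, path: str | Path) -> None:
    """Write every age-indexed input as one long CSV for inspection."""
    import csv

    rows = [("table", "state", "age", "value")]
    rows += [("p_onset_by_age", "", a, v) for a, v in zip(
        p.epi.p_onset_by_age.ages, p.epi.p_onset_by_age.values)]
    for group, tables in (
        ("p_eol_by_age_state", p.epi.p_eol_by_age_state),
        ("c_state_by_age", p.costs.c_state_by_age),
        ("u_state_by_age", p.utils.u_state_by_age),
    ):
        for state, tab in tables.items():
            rows += [(group, state.name, a, v) for a, v in zip(tab.ages, tab.values)]
    rows += [("c_eol_hospital_by_age", "", a, v) for a, v in zip(
        p.costs.c_eol_hospital_by_age.ages, p.costs.c_eol_hospital_by_age.values)]
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)


# ---------------------------------------------------------------------------
# parameter substitution (used by sensitivity sweeps / threshold search / PSA)


def substitute(p: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a deep copy of ``p`` with the parameter at ``path`` replaced.

    ``path`` is a dotted attribute path (``"costs.r_nonhosp"``,
    ``"acp_program.compliance"``, ``"econ.start_age"``).  Two extensions:

    - a leading ``"acp."`` applies the value to both scenario blocks (a
      behavioural parameter with a single underlying truth, e.g. compliance);
    - a trailing ``":scale"`` multiplies an :class:`AgeTable` (or a dict of
      them) by ``value`` instead of assigning, e.g.
      ``"costs.c_eol_hospital_by_age:scale"``.
    """
    if path.startswith("acp."):
        leaf = path.split(".", 1)[1]
        q = substitute(p, f"acp_current.{leaf}", value)
        return substitute(q, f"acp_program.{leaf}", value)

    scale = path.endswith(":scale")
    attr_path = path[: -len(":scale")] if scale else path
    parts = attr_path.split(".")
    q = copy.deepcopy(p)
    obj = q
    for name in parts[:-1]:
        obj = getattr(obj, name)
    leaf = parts[-1]
    if not hasattr(obj, leaf):
        raise AttributeError(f"no parameter at path {path!r}")
    if scale:
        target = getattr(obj, leaf)
        if isinstance(target, AgeTable):
            setattr(obj, leaf, target.scaled(value))
        elif isinstance(target, dict):
            setattr(obj, leaf, {k: t.scaled(value) for k, t in target.items()})
        else:
            raise AttributeError(f"path {path!r} does not point at an age table")
    else:
        current = getattr(obj, leaf)
        setattr(obj, leaf, type(current)(value) if isinstance(current, int) else float(value))
    return q


def get_by_path(p: ModelParameters, path: str):
    obj = p
    for name in path.split("."):
        obj = getattr(obj, name)
    return obj
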