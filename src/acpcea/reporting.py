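"""Human-readable run reports with reproducibility provenance."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .economics import CEResult, ScenarioResult


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a reader needs to reproduce the printed numbers."""

    scenarios: dict[str, ScenarioResult]
    comparison: Optional[CEResult] = None
    sensitivity: Optional[pd.DataFrame] = None
    psa_summary: Optional[dict] = None
    provenance: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = []
        lines.append("advance-care-planning cost-effectiveness model")
        lines.append(f"acpcea {__version__}")
        for key, val in self.provenance.items():
            lines.append(f"  {key}: {val}")
        lines.append("")
        rows = []
        for name, res in self.scenarios.items():
            rows.append(
                {
                    "scenario": name,
                    "discounted cost ($)": round(res.discounted_cost, 2),
                    "discounted QALY": round(res.discounted_qaly, 4),
                    "undiscounted cost ($)": round(res.undiscounted_cost, 2),
                    "P(hospital death)": round(res.p_hospital_death, 4),
                }
            )
        lines.append(pd.DataFrame(rows).to_string(index=False))
        if self.comparison is not None:
            ce = self.comparison
            lines.append("")
            lines.append("incremental (program vs current situation):")
            lines.append(f"  incremental cost ($):  {ce.delta_cost:12.2f}")
            lines.append(f"  incremental QALY:      {ce.delta_qaly:12.6f}")
            icer = "undefined (equal QALYs; incremental cost presented instead)" \
                if ce.icer is None else f"{ce.icer:.2f}"
            lines.append(f"  ICER ($/QALY):         {icer}")
            lines.append(f"  NMB at WTP {ce.wtp:,.0f}:    {ce.nmb:12.2f}")
            lines.append(f"  conclusion:            {ce.dominance}"
                         f" ({'cost effective' if ce.cost_effective else 'not cost effective'})")
        if self.sensitivity is not None and len(self.sensitivity):
            lines.append("")
            lines.append("sensitivity analyses:")
            lines.append(self.sensitivity.to_string(index=False))
        if self.psa_summary:
            lines.append("")
            lines.append("probabilistic sensitivity analysis:")
            for key, val in self.psa_summary.items():
                lines.append(f"  {key}: {val}")
        return "\n".join(lines) + "\n"
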