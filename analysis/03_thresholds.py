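#!/usr/bin/env python
"""Breakeven analysis: where does the cost-saving conclusion flip?

Bisects the incremental cost to zero along the three determinants of the
program's economics — compliance with the directive, the per-person cost
of delivering the consultations, and program coverage — and writes
``results/thresholds.csv``.

Finding on the base-case record: the program stops being cost-saving when
compliance falls below ~69%, when the per-person consultation package
exceeds ~$677, or (trivially, since savings scale with the extra coverage)
when program coverage falls to the current 15%.
"""

from pathlib import Path

import pandas as pd

from acpcea import find_threshold
from acpcea.synthetic import calibrated_fixture

OUT = Path(__file__).resolve().parent.parent / "results"

SEARCHES = [
    ("acp.compliance", (0.50, 0.86), "probability"),
    ("costs.c_acp_visit", (850 / 7, 6 * 850 / 7), "$/visit"),
    ("acp_program.uptake", (0.02, 0.50), "probability"),
    ("costs.r_nonhosp", (0.50, 0.90), "ratio"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    p = calibrated_fixture()
    rows = []
    for path, bracket, unit in SEARCHES:
        res = find_threshold(p, path, bracket)
        rows.append(
            {"parameter": path, "threshold": round(res.threshold, 5), "unit": unit,
             "bracket_lo": bracket[0], "bracket_hi": bracket[1],
             "evaluations": res.crossings_checked}
        )
        print(f"{path:28s} breakeven at {res.threshold:.4f} {unit}")
    per_person = p.costs.n_initial_visits * rows[1]["threshold"]
    print(f"per-person consultation package breakeven: ${per_person:.2f} "
          f"({p.costs.n_initial_visits} visits)")
    pd.DataFrame(rows).to_csv(OUT / "thresholds.csv", index=False)


if __name__ == "__main__":
    main()
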