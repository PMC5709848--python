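"""Health states of the dementia / end-of-life cohort model.

The cohort moves between four alive health states (well, and three
Clinical-Dementia-Rating-style dementia stages), a one-year end-of-life
tunnel state, and an absorbing dead state.  Dementia is irreversible, so
stage transitions are forward-only.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    """Model states, ordered; dementia severity is MILD < MODERATE < SEVERE."""

    WELL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    EOL = 4
    DEAD = 5


#: States in which the cohort is alive and accrues annual state costs/utilities.
ALIVE_STATES = (
    HealthState.WELL,
    HealthState.MILD,
    HealthState.MODERATE,
    HealthState.SEVERE,
)

#: Dementia stages in progression order.
DEMENTIA_STATES = (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE)

N_STATES = len(HealthState)
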