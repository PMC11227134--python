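"""Health states and transitions of the three-state disease model.

Patients occupy one of three mutually exclusive states — out of hospital,
in hospital (for a major cardiovascular event), or dead — and move between
them under cause-specific hazards. Time within each transient state is
measured from state entry (clock-reset / semi-Markov convention).
"""

from __future__ import annotations

OUT = "OUT"
HOSP = "HOSP"
DEAD = "DEAD"

STATES = (OUT, HOSP, DEAD)
TRANSIENT_STATES = (OUT, HOSP)

#: the four permitted transitions, as (from, to) pairs
TRANSITIONS = ((OUT, HOSP), (OUT, DEAD), (HOSP, OUT), (HOSP, DEAD))

#: canonical string labels, e.g. "OUT->HOSP"
TRANSITION_LABELS = tuple(f"{r}->{s}" for r, s in TRANSITIONS)

SPC = "SPC"
TWO_PILL = "TWO_PILL"
STRATEGIES = (SPC, TWO_PILL)

DAYS_PER_YEAR = 365.25

#: administrative follow-up cap: 52 months expressed in days
MAX_FOLLOWUP_DAYS = 1583  # ceil(52 * 30.4375)


def transition_label(r: str, s: str) -> str:
    if (r, s) not in TRANSITIONS:
        raise ValueError(f"no such transition: {r}->{s}")
    return f"{r}->{s}"


def split_label(label: str) -> tuple[str, str]:
    r, _, s = label.partition("->")
    if (r, s) not in TRANSITIONS:
        raise ValueError(f"unknown transition label: {label!r}")
    return r, s


def outgoing(state: str) -> tuple[str, ...]:
    """Competing destination states reachable from ``state``."""
    if state == DEAD:
        return ()
    return tuple(s for r, s in TRANSITIONS if r == state)
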