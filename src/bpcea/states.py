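"""Health-state space of the cardiovascular Markov cohort model.

The model tracks a cohort of initially disease-free prehypertensive adults
through first and recurrent cardiovascular disease (CVD) events.  Each
nonfatal event type is split into a one-cycle *acute* (hospitalization)
tunnel state and a *chronic* (post-hospitalization) state; fatal CVD and
non-CVD death are absorbing.  The state order below is fixed so that
transition matrices and occupancy vectors are position-stable everywhere in
the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Nonfatal CVD event types, in canonical order.  Acute myocardial
#: infarction (AMI) is kept separate from other ischemic heart disease
#: because its hospitalization cost differs substantially.
EVENTS: tuple[str, ...] = (
    "ami",
    "other_ihd",
    "ischemic_stroke",
    "hemorrhagic_stroke",
)

DISEASE_FREE = "disease_free"
FATAL_CVD = "fatal_cvd"
NON_CVD_DEATH = "non_cvd_death"

#: Outcomes a hazard multiplier may act on: the four nonfatal event types
#: plus fatal CVD.  Non-CVD death is never an outcome.
OUTCOMES: tuple[str, ...] = EVENTS + (FATAL_CVD,)


def acute_state(event: str) -> str:
    return f"acute_{event}"


def chronic_state(event: str) -> str:
    return f"chronic_{event}"


def _build_states() -> tuple[str, ...]:
    states = [DISEASE_FREE]
    for ev in EVENTS:
        states.append(acute_state(ev))
        states.append(chronic_state(ev))
    states.append(FATAL_CVD)
    states.append(NON_CVD_DEATH)
    return tuple(states)


@dataclass(frozen=True)
class HealthStateSpace:
    """Ordered, fixed set of model states.

    Invariants: exactly two absorbing states (``fatal_cvd``,
    ``non_cvd_death``); every acute state is a one-cycle tunnel routing only
    to its chronic twin or a death state.
    """

    states: tuple[str, ...] = field(default_factory=_build_states)

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None

    @property
    def absorbing(self) -> tuple[str, ...]:
        return (FATAL_CVD, NON_CVD_DEATH)

    @property
    def absorbing_indices(self) -> tuple[int, int]:
        return (self.index(FATAL_CVD), self.index(NON_CVD_DEATH))

    @property
    def transient_indices(self) -> tuple[int, ...]:
        absorbing = set(self.absorbing_indices)
        return tuple(i for i in range(self.n) if i not in absorbing)


#: The canonical state space instance used throughout the package.
STATE_SPACE = HealthStateSpace()
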