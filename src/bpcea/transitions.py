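"""Age-banded baseline transition probabilities and matrix construction.

Baseline inputs are 10-year cumulative probabilities by age band
(35-44, 45-54, 55-64, 65-75 by default): first-event probabilities from the
disease-free state per CVD outcome, fatal-CVD and non-CVD death
probabilities, and between-event probabilities from each chronic event
state.  Between-event probabilities are estimated on wider age groups
(35-75, 45-75, ...) keyed by the cohort's starting age, because recurrent
events are too sparse to band finely.

``build_transition_matrix`` converts the 10-year probabilities to annual
ones, applies per-outcome hazard multipliers (with optional adherence
mixtures) in the rate domain, and assembles a row-stochastic matrix over
the fixed state space.  Hazard multipliers act only on CVD-event and
fatal-CVD transitions, never on non-CVD death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .effects import apply_components_to_probability, ten_year_to_annual
from .states import (
    DISEASE_FREE,
    EVENTS,
    FATAL_CVD,
    NON_CVD_DEATH,
    STATE_SPACE,
    acute_state,
    chronic_state,
)

#: Default age bands for first-event probabilities (inclusive bounds, years).
DEFAULT_BANDS: tuple[tuple[int, int], ...] = ((35, 44), (45, 54), (55, 64), (65, 75))

#: Destinations reachable from a chronic event state.
BETWEEN_DESTINATIONS: tuple[str, ...] = EVENTS + (FATAL_CVD, NON_CVD_DEATH)

EffectMap = Mapping[str, Sequence[tuple[float, float]]]
"""outcome -> sequence of (hazard multiplier, adherent fraction) components."""


@dataclass(frozen=True)
class AgeBandedTransitionModel:
    """Baseline 10-year transition probabilities indexed by age band.

    ``first_event[outcome][band]`` is the 10-year probability of a first
    event of that type from disease-free; ``fatal_cvd`` and ``non_cvd_death``
    are per-band 10-year probabilities from disease-free; ``between[from_event]
    [destination][band]`` covers transitions out of chronic event states
    (recurrence, cross-event shifts, and death).  All probabilities are
    cumulative over ``horizon_years``.
    """

    first_event: Mapping[str, tuple[float, ...]]
    fatal_cvd: tuple[float, ...]
    non_cvd_death: tuple[float, ...]
    between: Mapping[str, Mapping[str, tuple[float, ...]]]
    bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS
    horizon_years: float = 10.0

    def __post_init__(self) -> None:
        nb = len(self.bands)
        for outcome in EVENTS:
            values = self.first_event.get(outcome)
            if values is None or len(values) != nb:
                raise ValueError(
                    f"first_event[{outcome!r}] must have one value per band"
                )
            self._check_probs(values, f"first_event/{outcome}")
        self._check_probs(self.fatal_cvd, "fatal_cvd")
        self._check_probs(self.non_cvd_death, "non_cvd_death")
        for ev in EVENTS:
            dests = self.between.get(ev)
            if dests is None:
                raise ValueError(f"between[{ev!r}] missing")
            for dest in BETWEEN_DESTINATIONS:
                values = dests.get(dest, (0.0,) * nb)
                self._check_probs(values, f"between/{ev}/{dest}")
        for outcome in EVENTS:
            values = self.first_event[outcome]
            if any(b < a for a, b in zip(values, values[1:])):
                warnings.warn(
                    f"first_event probabilities for {outcome!r} are not "
                    "non-decreasing across age bands",
                    stacklevel=2,
                )

    @staticmethod
    def _check_probs(values: Sequence[float], label: str) -> None:
        for i, p in enumerate(values):
            if not 0.0 <= p < 1.0:
                raise ValueError(
                    f"transitions/{label}/{i}: probability {p} outside [0, 1)"
                )

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_index(self, age: float) -> int:
        """Band containing ``age``; ages above the last band reuse it."""
        if age < self.bands[0][0]:
            raise ValueError(
                f"age {age} is below the first age band "
                f"({self.bands[0][0]}-{self.bands[0][1]})"
            )
        for i, (lo, hi) in enumerate(self.bands):
            if age <= hi:
                return i
        return self.n_bands - 1

    def between_probability(self, from_event: str, dest: str, band: int) -> float:
        values = self.between[from_event].get(dest)
        return 0.0 if values is None else values[band]


def _apply(p10: float, horizon: float, effects: Sequence[tuple[float, float]]) -> float:
    annual = ten_year_to_annual(p10, horizon)
    return apply_components_to_probability(annual, effects)


def build_transition_matrix(
    model: AgeBandedTransitionModel,
    age: float,
    effects: EffectMap | None = None,
    between_band: int | None = None,
    apply_to_recurrence: bool = True,
) -> np.ndarray:
    """Annual row-stochastic transition matrix at a given cohort age.

    ``effects`` maps outcomes (event types and ``fatal_cvd``) to hazard
    multiplier components; missing outcomes are untreated.  ``between_band``
    selects the wider age group for transitions out of chronic states
    (defaults to the band containing ``age``).  ``apply_to_recurrence``
    controls whether effects also act on transitions out of chronic and
    acute states, not just on first events.

    Rows sum to 1 exactly (residual mass stays in place); acute rows route
    only to the chronic twin or death; death rows are identity.
    """
    effects = effects or {}
    band = model.band_index(age)
    bb = band if between_band is None else between_band
    h = model.horizon_years
    ss = STATE_SPACE
    M = np.zeros((ss.n, ss.n))

    def eff(outcome: str, first: bool) -> Sequence[tuple[float, float]]:
        if not first and not apply_to_recurrence:
            return ()
        return effects.get(outcome, ())

    def fill_row(row_state: str, entries: dict[str, float]) -> None:
        i = ss.index(row_state)
        exit_mass = sum(entries.values())
        if exit_mass >= 1.0:
            raise ValueError(
                f"row {row_state!r} at age {age}: exit probabilities sum to "
                f"{exit_mass:.6f} >= 1 after effect application"
            )
        for dest, p in entries.items():
            M[i, ss.index(dest)] = p
        M[i, i] += 1.0 - exit_mass

    # Disease-free: first events, fatal CVD, non-CVD death.
    df_entries: dict[str, float] = {}
    for ev in EVENTS:
        df_entries[acute_state(ev)] = _apply(
            model.first_event[ev][band], h, eff(ev, first=True)
        )
    df_entries[FATAL_CVD] = _apply(model.fatal_cvd[band], h, eff(FATAL_CVD, first=True))
    df_entries[NON_CVD_DEATH] = ten_year_to_annual(model.non_cvd_death[band], h)
    fill_row(DISEASE_FREE, df_entries)

    # Event states.  Acute rows are tunnels: death entries as from the
    # chronic row, residual forced to the chronic twin.
    for ev in EVENTS:
        death_entries = {
            FATAL_CVD: _apply(
                model.between_probability(ev, FATAL_CVD, bb), h, eff(FATAL_CVD, False)
            ),
            NON_CVD_DEATH: ten_year_to_annual(
                model.between_probability(ev, NON_CVD_DEATH, bb), h
            ),
        }
        i = ss.index(acute_state(ev))
        exit_mass = sum(death_entries.values())
        if exit_mass >= 1.0:
            raise ValueError(
                f"row {acute_state(ev)!r} at age {age}: exit probabilities "
                f"sum to {exit_mass:.6f} >= 1 after effect application"
            )
        for dest, p in death_entries.items():
            M[i, ss.index(dest)] = p
        M[i, ss.index(chronic_state(ev))] = 1.0 - exit_mass

        chronic_entries = dict(death_entries)
        for dest_ev in EVENTS:
            p = _apply(
                model.between_probability(ev, dest_ev, bb), h, eff(dest_ev, False)
            )
            if p > 0.0:
                chronic_entries[acute_state(dest_ev)] = p
        fill_row(chronic_state(ev), chronic_entries)

    for dead in (FATAL_CVD, NON_CVD_DEATH):
        M[ss.index(dead), ss.index(dead)] = 1.0

    return M
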