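"""Cohort simulation: annual cycles, discounting, cost and QALY accrual.

The cohort starts fully disease-free at the chosen age and is pushed
through annual transition matrices until the lifetime horizon (``max_age``)
or until the unabsorbed mass is negligible.  Costs and utilities accrue on
the post-transition occupancy of each cycle (so a one-cycle acute state
carries exactly one acute cost), multiplied by the cycle's discount factor.
An optional half-cycle correction averages pre- and post-transition
occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd

from .states import (
    DISEASE_FREE,
    EVENTS,
    FATAL_CVD,
    NON_CVD_DEATH,
    STATE_SPACE,
    acute_state,
)

MatrixProvider = Callable[[float, int], np.ndarray]
"""(cohort age at cycle start, cycle index) -> annual transition matrix."""


@dataclass(frozen=True)
class DiscountSettings:
    """Annual discounting of costs and effectiveness (default 5%/year).

    ``end_of_cycle`` discounts cycle ``t`` by ``(1+rate)^-(t+1)`` —
    accrual is valued at the end of the year it occurs in; ``start_of_cycle``
    uses ``(1+rate)^-t``.
    """

    rate: float = 0.05
    convention: Literal["start_of_cycle", "end_of_cycle"] = "end_of_cycle"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"discount rate must be non-negative, got {self.rate}")
        if self.convention not in ("start_of_cycle", "end_of_cycle"):
            raise ValueError(f"unknown discount convention {self.convention!r}")


def discount_factor(cycle_index: int, discount: DiscountSettings) -> float:
    """Discount factor for one annual cycle."""
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be non-negative, got {cycle_index}")
    exponent = cycle_index + (1 if discount.convention == "end_of_cycle" else 0)
    return (1.0 + discount.rate) ** (-exponent)


@dataclass(frozen=True)
class StateEconomics:
    """Per-cycle cost and utility for each state, plus intervention cost.

    ``state_cost[state]`` is the cost (USD) of one cycle spent in the state:
    acute states carry the per-event hospitalization plus acute indirect
    cost, chronic states the annual chronic-management cost.  The
    intervention's annual cost accrues on the eligible alive occupancy
    (all alive states by default, or disease-free only).
    """

    state_cost: Mapping[str, float]
    utility: Mapping[str, float]
    intervention_annual_cost: float = 0.0
    intervention_cost_states: Literal["alive", "disease_free"] = "alive"

    def __post_init__(self) -> None:
        for st in STATE_SPACE.states:
            c = self.state_cost.get(st, 0.0)
            if c < 0:
                raise ValueError(f"cost for state {st!r} must be non-negative, got {c}")
            u = self.utility.get(st, 0.0)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for state {st!r} must be in [0, 1], got {u}")
        for dead in (FATAL_CVD, NON_CVD_DEATH):
            if self.utility.get(dead, 0.0) != 0.0:
                raise ValueError(f"utility of death state {dead!r} must be 0")
        if self.intervention_annual_cost < 0:
            raise ValueError("intervention_annual_cost must be non-negative")

    def cost_vector(self) -> np.ndarray:
        return np.array([self.state_cost.get(s, 0.0) for s in STATE_SPACE.states])

    def utility_vector(self) -> np.ndarray:
        return np.array([self.utility.get(s, 0.0) for s in STATE_SPACE.states])

    def intervention_mask(self) -> np.ndarray:
        if self.intervention_cost_states == "disease_free":
            eligible = {DISEASE_FREE}
        else:
            eligible = set(STATE_SPACE.states) - {FATAL_CVD, NON_CVD_DEATH}
        return np.array([1.0 if s in eligible else 0.0 for s in STATE_SPACE.states])


@dataclass(frozen=True)
class RunSettings:
    """Cohort run settings: start age, lifetime-horizon cutoff, currency."""

    start_age: float = 40.0
    max_age: float = 100.0
    cycle_length: float = 1.0
    currency_rate: float = 6.9  # RMB per USD

    def __post_init__(self) -> None:
        if self.start_age >= self.max_age:
            raise ValueError("start_age must be below max_age")
        if self.cycle_length != 1.0:
            raise ValueError("only annual cycles are supported")
        if self.currency_rate <= 0:
            raise ValueError("currency_rate must be positive")


@dataclass
class CohortTrace:
    """Per-cycle cohort occupancy with discounted cost and QALY streams.

    ``occupancy[t]`` is the state distribution after cycle ``t`` (cohort age
    ``start_age + t + 1``); ``cum_first_event_incidence[t]`` is the
    cumulative proportion of the original cohort that has left the
    disease-free state through a CVD event (including directly fatal CVD)
    by the end of cycle ``t``.
    """

    start_age: float
    occupancy: np.ndarray  # (cycles, n_states), post-transition
    discounted_cost: np.ndarray
    discounted_qaly: np.ndarray
    cum_first_event_incidence: np.ndarray
    acute_entries: np.ndarray  # per-cycle inflow into acute states (all events)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def total_cost(self) -> float:
        return float(self.discounted_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.discounted_qaly.sum())

    @property
    def lifetime_first_event_incidence(self) -> float:
        return float(self.cum_first_event_incidence[-1])

    @property
    def total_acute_entries(self) -> float:
        """Expected lifetime count of acute-state entries (incl. recurrences)."""
        return float(self.acute_entries.sum())

    def to_frame(self) -> pd.DataFrame:
        ages = self.start_age + np.arange(1, self.n_cycles + 1)
        df = pd.DataFrame(self.occupancy, columns=list(STATE_SPACE.states))
        df.insert(0, "age", ages)
        df["discounted_cost"] = self.discounted_cost
        df["discounted_qaly"] = self.discounted_qaly
        df["cum_cvd_incidence"] = self.cum_first_event_incidence
        return df


def run_cohort(
    matrix_provider: MatrixProvider,
    economics: StateEconomics,
    discount: DiscountSettings,
    run: RunSettings,
    half_cycle_correction: bool = False,
    mass_tol: float = 1e-9,
) -> CohortTrace:
    """Simulate the cohort and accumulate discounted costs and QALYs.

    Stops at ``max_age`` or once the unabsorbed mass drops below
    ``mass_tol``.  Raises if a provided matrix is not row-stochastic or has
    negative entries.
    """
    ss = STATE_SPACE
    df_idx = ss.index(DISEASE_FREE)
    fatal_idx = ss.index(FATAL_CVD)
    acute_idx = np.array([ss.index(acute_state(ev)) for ev in EVENTS])
    first_event_cols = np.append(acute_idx, fatal_idx)

    cost_vec = economics.cost_vector()
    util_vec = economics.utility_vector()
    iv_mask = economics.intervention_mask()
    transient = np.array(ss.transient_indices)

    occ = np.zeros(ss.n)
    occ[df_idx] = 1.0

    occupancies, costs, qalys, cum_inc, acute_in = [], [], [], [], []
    cum = 0.0
    n_cycles = int(round(run.max_age - run.start_age))
    for t in range(n_cycles):
        age = run.start_age + t
        M = np.asarray(matrix_provider(age, t), dtype=float)
        if M.shape != (ss.n, ss.n) or (M < 0).any():
            raise ValueError(f"invalid transition matrix at cycle {t}")
        rowsum = M.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(rowsum - 1.0)))
            raise ValueError(
                f"transition matrix at cycle {t} is not row-stochastic "
                f"(row {ss.states[bad]!r} sums to {rowsum[bad]:.12f})"
            )
        cum += occ[df_idx] * M[df_idx, first_event_cols].sum()
        entries = float(occ @ M[:, acute_idx].sum(axis=1))
        occ_new = occ @ M
        accrual = 0.5 * (occ + occ_new) if half_cycle_correction else occ_new
        dfac = discount_factor(t, discount)
        cost = accrual @ cost_vec + economics.intervention_annual_cost * (
            accrual @ iv_mask
        )
        occupancies.append(occ_new)
        costs.append(dfac * cost)
        qalys.append(dfac * (accrual @ util_vec))
        cum_inc.append(cum)
        acute_in.append(entries)
        occ = occ_new
        if occ[transient].sum() < mass_tol:
            break

    return CohortTrace(
        start_age=run.start_age,
        occupancy=np.array(occupancies),
        discounted_cost=np.array(costs),
        discounted_qaly=np.array(qalys),
        cum_first_event_incidence=np.array(cum_inc),
        acute_entries=np.array(acute_in),
    )


class UndefinedEventReduction(ZeroDivisionError):
    """Raised when the comparator trace has zero CVD incidence."""


def event_reduction(trace_a: CohortTrace, trace_b: CohortTrace) -> float:
    """Relative reduction in lifetime first-CVD-event incidence of a vs b.

    Returns ``(inc_b - inc_a) / inc_b`` where ``inc`` is the cumulative
    first-event incidence; positive when strategy a prevents events relative
    to comparator b.
    """
    if trace_a.start_age != trace_b.start_age:
        raise ValueError("traces must share the same start age")
    inc_a = trace_a.lifetime_first_event_incidence
    inc_b = trace_b.lifetime_first_event_incidence
    if inc_b == 0.0:
        raise UndefinedEventReduction(
            "comparator trace has zero CVD incidence; reduction undefined"
        )
    return (inc_b - inc_a) / inc_b
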