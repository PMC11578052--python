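"""Comparative cost-effectiveness: ICERs, dominance, frontier, decisions.

Strategies are compared by discounted lifetime cost and QALYs.  The
efficient frontier is found by sorting on effectiveness, removing strictly
dominated strategies (more costly, no more effective), then iteratively
removing extended-dominated ones until incremental cost-effectiveness
ratios (ICERs) strictly increase along the frontier.  A strategy is adopted
at a willingness-to-pay (WTP) threshold via the frontier rule — the most
effective frontier member whose incremental ICER does not exceed WTP —
which is equivalent to maximizing net monetary benefit ``WTP*QALY - cost``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

#: 2019 Chinese GDP per capita in USD, the conventional WTP threshold.
GDP_PER_CAPITA_2019_USD = 10264.8

ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


@dataclass(frozen=True)
class StrategyResult:
    """Discounted lifetime totals for one strategy."""

    name: str
    total_cost: float
    total_qaly: float
    cvd_incidence: float | None = None

    def __post_init__(self) -> None:
        if self.total_qaly < 0:
            raise ValueError(f"total_qaly must be non-negative, got {self.total_qaly}")


@dataclass(frozen=True)
class DecisionSettings:
    wtp: float = GDP_PER_CAPITA_2019_USD

    def __post_init__(self) -> None:
        if self.wtp <= 0:
            raise ValueError(f"wtp must be positive, got {self.wtp}")


class UndefinedICER(ValueError):
    """Raised when two strategies have identical QALYs (no ratio exists)."""


def icer(reference: StrategyResult, comparator: StrategyResult) -> float:
    """Incremental cost per QALY gained of ``comparator`` over ``reference``.

    A zero QALY difference has no meaningful ratio and raises
    :class:`UndefinedICER`; use :func:`classify_pair` for a label instead.
    A negative value means the more effective strategy is cost-saving
    (dominant) — by convention it is reported as a dominance label, not a
    ratio.
    """
    dq = comparator.total_qaly - reference.total_qaly
    dc = comparator.total_cost - reference.total_cost
    if dq == 0.0:
        raise UndefinedICER(
            f"{comparator.name!r} vs {reference.name!r}: equal QALYs; "
            "this is a dominance/equivalence case, not a ratio"
        )
    return dc / dq


def classify_pair(reference: StrategyResult, comparator: StrategyResult) -> tuple[str, float | None]:
    """(label, icer) for comparator vs reference.

    Labels: ``icer`` (positive ratio), ``dominant (cost-saving)`` (more
    QALYs for less or equal cost), ``dominated`` (fewer QALYs for equal or
    higher cost), ``equivalent`` (identical cost and QALYs).
    """
    dq = comparator.total_qaly - reference.total_qaly
    dc = comparator.total_cost - reference.total_cost
    if dq == 0.0 and dc == 0.0:
        return "equivalent", None
    if dq >= 0.0 and dc <= 0.0:
        return "dominant (cost-saving)", None
    if dq <= 0.0 and dc >= 0.0:
        return "dominated", None
    return "icer", dc / dq


@dataclass
class FrontierMember:
    strategy: StrategyResult
    #: ICER vs the previous frontier member; None for the cheapest member.
    icer_vs_previous: float | None


@dataclass
class FrontierResult:
    """Efficient frontier with per-strategy dominance classification."""

    members: list[FrontierMember]
    classification: dict[str, str]

    @property
    def frontier_names(self) -> list[str]:
        return [m.strategy.name for m in self.members]

    def to_records(self) -> list[dict]:
        by_name = {m.strategy.name: m for m in self.members}
        records = []
        for name, label in self.classification.items():
            member = by_name.get(name)
            records.append(
                {
                    "strategy": name,
                    "classification": label,
                    "icer_vs_previous": None
                    if member is None or member.icer_vs_previous is None
                    else round(member.icer_vs_previous, 2),
                }
            )
        return records


def efficiency_frontier(strategies: Sequence[StrategyResult]) -> FrontierResult:
    """Classify strategies and compute the efficient frontier.

    Strict dominance: another strategy attains at least the QALYs at no
    more cost, strictly better in one dimension.  Extended dominance: the
    ICER vs the previous frontier member exceeds the ICER of the next
    member vs that same previous member, i.e. a mixture of neighbours is
    better.  Frontier ICERs are strictly increasing by construction.
    """
    if len(strategies) < 2:
        raise ValueError("need at least 2 strategies")
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ValueError("strategy names must be unique")

    seen: dict[tuple[float, float], str] = {}
    for s in sorted(strategies, key=lambda s: s.name):
        key = (s.total_cost, s.total_qaly)
        if key in seen:
            warnings.warn(
                f"strategies {seen[key]!r} and {s.name!r} have identical "
                "(cost, QALY); tie broken by name order",
                stacklevel=2,
            )
        else:
            seen[key] = s.name

    classification: dict[str, str] = {}
    # Sort by effectiveness; ties by cost then name so the keeper comes first.
    ordered = sorted(strategies, key=lambda s: (s.total_qaly, s.total_cost, s.name))

    def dominates(a: StrategyResult, b: StrategyResult) -> bool:
        if (a.total_qaly, a.total_cost) == (b.total_qaly, b.total_cost):
            return a.name < b.name  # duplicate tie-break
        return a.total_qaly >= b.total_qaly and a.total_cost <= b.total_cost

    candidates = []
    for s in ordered:
        if any(dominates(o, s) for o in ordered if o.name != s.name):
            classification[s.name] = DOMINATED
        else:
            candidates.append(s)

    # Iterative extended-dominance removal until ICERs strictly increase.
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for k in range(1, len(candidates) - 1):
            prev, cur, nxt = candidates[k - 1], candidates[k], candidates[k + 1]
            if icer(prev, cur) >= icer(prev, nxt):
                classification[cur.name] = EXTENDED_DOMINATED
                del candidates[k]
                changed = True
                break

    members = []
    for k, s in enumerate(candidates):
        classification[s.name] = ON_FRONTIER
        members.append(
            FrontierMember(
                strategy=s,
                icer_vs_previous=None if k == 0 else icer(candidates[k - 1], s),
            )
        )
    # Preserve input order in the classification mapping.
    classification = {name: classification[name] for name in names}
    return FrontierResult(members=members, classification=classification)


def net_monetary_benefit(strategy: StrategyResult, wtp: float) -> float:
    return wtp * strategy.total_qaly - strategy.total_cost


def decide(frontier: FrontierResult, settings: DecisionSettings) -> StrategyResult:
    """Adopt the most effective frontier strategy affordable at the WTP.

    Walks the frontier in increasing effectiveness and keeps stepping up
    while the incremental ICER is at most ``settings.wtp``; equivalent to
    the net-monetary-benefit argmax.
    """
    if not frontier.members:
        raise ValueError("empty frontier")
    chosen = frontier.members[0].strategy
    for member in frontier.members[1:]:
        assert member.icer_vs_previous is not None
        if member.icer_vs_previous <= settings.wtp:
            chosen = member.strategy
        else:
            break
    return chosen


def threshold_search(
    runner: Callable[[float], float],
    target_wtp: float,
    bracket: tuple[float, float],
    rel_tol: float = 1e-3,
    param_tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Find the parameter value at which the ICER equals the WTP threshold.

    ``runner(value)`` evaluates the model at the candidate parameter value
    and returns the ICER of interest.  Bisection over ``bracket`` requires
    the ICER-minus-WTP difference to change sign across the endpoints
    (monotonicity over the bracket is the caller's responsibility) and stops
    once ``|ICER - wtp| <= rel_tol * wtp`` or the bracket is narrower than
    ``param_tol``.
    """
    lo, hi = bracket
    if lo >= hi:
        raise ValueError("bracket must satisfy lo < hi")
    f_lo = runner(lo) - target_wtp
    f_hi = runner(hi) - target_wtp
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if math.copysign(1.0, f_lo) == math.copysign(1.0, f_hi):
        raise ValueError(
            f"ICER - wtp does not change sign over bracket ({f_lo + target_wtp:.4f}, "
            f"{f_hi + target_wtp:.4f} vs wtp {target_wtp})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = runner(mid) - target_wtp
        if abs(f_mid) <= rel_tol * target_wtp or (hi - lo) < param_tol:
            return mid
        if math.copysign(1.0, f_mid) == math.copysign(1.0, f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
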