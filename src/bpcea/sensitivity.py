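"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-evaluates the ICER of a strategy pair with each
parameter set to the low and high end of its plausibility range, producing
a tornado table sorted by influence.  Probabilistic sensitivity analysis
(PSA) assigns each parameter a distribution consistent with its domain —
beta for probabilities and utilities, gamma for costs, lognormal for
hazard ratios, uniform as fallback — samples them jointly and
independently, re-runs the model per draw, and summarizes decision
uncertainty as cost-effectiveness acceptability curves (CEACs): the
probability each strategy maximizes net monetary benefit across draws, as
a function of willingness-to-pay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cea import StrategyResult

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ParameterRange:
    """Plausibility range of one parameter (dotted config path)."""

    path: str
    low: float
    base: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.path}: range must satisfy low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )


Family = Literal["beta", "gamma", "lognormal", "uniform", "point"]


@dataclass(frozen=True)
class ParameterDistribution:
    """A sampling distribution bound to one parameter path."""

    path: str
    family: Family
    #: scipy frozen distribution; None for a point mass at ``value``.
    dist: object | None = None
    value: float | None = None

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "point":
            return (
                self.value if size is None else np.full(size, self.value, dtype=float)
            )
        return self.dist.rvs(size=size, random_state=rng)

    def mean(self) -> float:
        if self.family == "point":
            return float(self.value)
        return float(self.dist.mean())


# ----------------------------------------------------------------- one-way


@dataclass
class TornadoRow:
    parameter: str
    icer_low: float | None
    icer_high: float | None
    spread: float | None
    error: str | None = None


ICERRunner = Callable[[Mapping[str, float]], float]
"""overrides (dotted path -> value) -> ICER of the comparison pair."""


def one_way(
    runner: ICERRunner,
    ranges: Sequence[ParameterRange],
    top_k: int | None = None,
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    Each parameter is set to its low and high bound with everything else at
    base; the table is sorted by |ICER_high - ICER_low| descending.  A
    bound that makes the model invalid is recorded as a failed cell with
    the reason, not raised.
    """
    base_icer = runner({})
    rows: list[TornadoRow] = []
    for r in ranges:
        values: dict[str, float | None] = {}
        errors = []
        for label, bound in (("low", r.low), ("high", r.high)):
            try:
                values[label] = runner({r.path: bound})
            except Exception as exc:  # invalid model at the bound
                values[label] = None
                errors.append(f"{label}: {exc}")
        lo, hi = values["low"], values["high"]
        spread = abs(hi - lo) if lo is not None and hi is not None else None
        rows.append(
            TornadoRow(
                parameter=r.path,
                icer_low=lo,
                icer_high=hi,
                spread=spread,
                error="; ".join(errors) or None,
            )
        )
    rows.sort(key=lambda t: (t.spread is None, -(t.spread or 0.0)))
    df = pd.DataFrame(
        {
            "parameter": [t.parameter for t in rows],
            "icer_low": [t.icer_low for t in rows],
            "icer_high": [t.icer_high for t in rows],
            "spread": [t.spread for t in rows],
            "error": [t.error for t in rows],
        }
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["base_icer"] = base_icer
    return df.head(top_k) if top_k is not None else df


# --------------------------------------------------------- distributions


def _fit_beta(r: ParameterRange) -> ParameterDistribution | None:
    m = r.base
    if not 0.0 < m < 1.0 or r.low < 0.0 or r.high > 1.0:
        return None

    def loss(log_conc: float) -> float:
        conc = np.exp(log_conc)
        a, b = m * conc, (1.0 - m) * conc
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        return (lo - r.low) ** 2 + (hi - r.high) ** 2

    res = optimize.minimize_scalar(loss, bounds=(np.log(2.0), np.log(1e7)), method="bounded")
    conc = float(np.exp(res.x))
    dist = stats.beta(m * conc, (1.0 - m) * conc)
    return ParameterDistribution(r.path, "beta", dist=dist)


def _fit_gamma(r: ParameterRange) -> ParameterDistribution | None:
    m = r.base
    if m <= 0.0 or r.low < 0.0:
        return None

    def loss(log_shape: float) -> float:
        k = np.exp(log_shape)
        scale = m / k
        lo, hi = stats.gamma.ppf([0.025, 0.975], k, scale=scale)
        return ((lo - r.low) / m) ** 2 + ((hi - r.high) / m) ** 2

    res = optimize.minimize_scalar(loss, bounds=(np.log(1e-2), np.log(1e7)), method="bounded")
    k = float(np.exp(res.x))
    dist = stats.gamma(k, scale=m / k)
    return ParameterDistribution(r.path, "gamma", dist=dist)


def _fit_lognormal(r: ParameterRange) -> ParameterDistribution | None:
    if r.low <= 0.0 or r.base <= 0.0 or r.high <= r.low:
        return None
    # Median at base; CI width sets sigma (geometric-mean convention).
    sigma = (np.log(r.high) - np.log(r.low)) / (2.0 * Z975)
    dist = stats.lognorm(s=sigma, scale=r.base)
    return ParameterDistribution(r.path, "lognormal", dist=dist)


def derive_distribution(r: ParameterRange, family: str) -> ParameterDistribution:
    """Fit a sampling distribution to a base value and plausibility range.

    The mean (median for lognormal) is anchored at the base value and the
    low/high bounds are mapped to the 2.5/97.5 percentiles where feasible.
    A degenerate range collapses to a point mass; an infeasible fit falls
    back to uniform(low, high) with a warning.
    """
    if r.low == r.high:
        return ParameterDistribution(r.path, "point", value=r.base)
    fit = None
    if family == "beta":
        fit = _fit_beta(r)
    elif family == "gamma":
        fit = _fit_gamma(r)
    elif family == "lognormal":
        fit = _fit_lognormal(r)
    elif family != "uniform":
        raise ValueError(f"unknown distribution family {family!r}")
    if fit is None:
        if family != "uniform":
            warnings.warn(
                f"{r.path}: could not fit {family} distribution; "
                "falling back to uniform(low, high)",
                stacklevel=2,
            )
        fit = ParameterDistribution(
            r.path, "uniform", dist=stats.uniform(r.low, r.high - r.low)
        )
    return fit


def family_for_path(path: str) -> str:
    """Default distribution family by parameter domain, inferred from path."""
    if "utilities" in path or "transitions" in path:
        return "beta"
    if "cost" in path:
        return "gamma"
    if "hr" in path or "evidence" in path:
        return "lognormal"
    return "uniform"


# ------------------------------------------------------------------- PSA


PSARunner = Callable[[Mapping[str, float]], Mapping[str, StrategyResult]]
"""overrides -> per-strategy results."""


@dataclass
class PSAResult:
    """Per-iteration strategy results from Monte Carlo parameter draws."""

    iterations: pd.DataFrame  # columns: iteration, strategy, cost, qaly
    draws: pd.DataFrame  # columns: iteration + one column per parameter
    seed: int
    n_iterations: int
    n_resampled: int = 0

    def strategies(self) -> list[str]:
        return list(self.iterations["strategy"].unique())


def psa(
    runner: PSARunner,
    distributions: Sequence[ParameterDistribution],
    n_iterations: int,
    seed: int,
    max_resample_fraction: float = 0.01,
) -> PSAResult:
    """Probabilistic sensitivity analysis via Monte Carlo simulation.

    Parameters are drawn jointly and independently each iteration (draw
    order fixed by sorted parameter path so results are reproducible per
    seed), the model is evaluated per draw for every strategy, and draws
    that make the model invalid are resampled (warned about above a 1%
    resample rate).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    dists = sorted(distributions, key=lambda d: d.path)
    rng = np.random.default_rng(seed)
    records = []
    draw_records = []
    n_resampled = 0
    for it in range(n_iterations):
        for _attempt in range(100):
            overrides = {d.path: float(d.sample(rng)) for d in dists}
            try:
                results = runner(overrides)
            except Exception:
                n_resampled += 1
                continue
            break
        else:
            raise RuntimeError(
                f"iteration {it}: could not draw a valid parameter set in 100 tries"
            )
        draw_records.append({"iteration": it, **overrides})
        for name, res in results.items():
            records.append(
                {
                    "iteration": it,
                    "strategy": name,
                    "cost": res.total_cost,
                    "qaly": res.total_qaly,
                }
            )
    if n_resampled > max_resample_fraction * n_iterations:
        warnings.warn(
            f"{n_resampled} invalid draws resampled over {n_iterations} "
            "iterations (> 1%)",
            stacklevel=2,
        )
    return PSAResult(
        iterations=pd.DataFrame(records),
        draws=pd.DataFrame(draw_records),
        seed=seed,
        n_iterations=n_iterations,
        n_resampled=n_resampled,
    )


@dataclass
class CEACCurve:
    """Probability each strategy is cost-effective across a WTP grid."""

    table: pd.DataFrame  # index: wtp, one column per strategy

    def probability_at(self, strategy: str, wtp: float) -> float:
        idx = np.argmin(np.abs(self.table.index.to_numpy() - wtp))
        return float(self.table.iloc[idx][strategy])


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curves from PSA iterations.

    At each willingness-to-pay value, a strategy's probability is the
    fraction of iterations in which it attains the maximum net monetary
    benefit; exact ties split the count equally, so probabilities sum to 1
    at every grid point.
    """
    wtp_grid = list(wtp_grid)
    if len(wtp_grid) == 0:
        raise ValueError("wtp_grid must be non-empty")
    wide_cost = result.iterations.pivot(
        index="iteration", columns="strategy", values="cost"
    )
    wide_qaly = result.iterations.pivot(
        index="iteration", columns="strategy", values="qaly"
    )
    strategies = list(wide_cost.columns)
    if len(strategies) < 2:
        raise ValueError("CEAC needs at least 2 strategies")
    costs = wide_cost.to_numpy()
    qalys = wide_qaly.to_numpy()
    rows = []
    for wtp in wtp_grid:
        nmb = wtp * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        weights = winners / winners.sum(axis=1, keepdims=True)
        rows.append(weights.mean(axis=0))
    table = pd.DataFrame(rows, index=pd.Index(wtp_grid, name="wtp"), columns=strategies)
    return CEACCurve(table=table)
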