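"""High-level model: configuration in, strategy results out.

``Model`` wires a validated configuration into the cohort engine: it builds
the age-banded transition model, per-strategy economics and effect
pipelines, runs each strategy's cohort, and returns
:class:`~bpcea.cea.StrategyResult` objects ready for frontier analysis.
Transition matrices are cached per (age band, adherence pattern) since they
only change at band boundaries and adherence steps.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .cea import DecisionSettings, FrontierResult, StrategyResult, efficiency_frontier
from .config import ModelConfig, apply_overrides
from .effects import (
    AdherenceSchedule,
    EffectComponent,
    HazardRatioSet,
    InterventionSpec,
)
from .engine import (
    CohortTrace,
    DiscountSettings,
    RunSettings,
    StateEconomics,
    run_cohort,
)
from .states import EVENTS, OUTCOMES, acute_state, chronic_state
from .transitions import AgeBandedTransitionModel, build_transition_matrix


def _transition_model(cfg: ModelConfig) -> AgeBandedTransitionModel:
    tr = cfg.transitions
    return AgeBandedTransitionModel(
        first_event={ev: tuple(tr.first_event[ev]) for ev in EVENTS},
        fatal_cvd=tuple(tr.fatal_cvd),
        non_cvd_death=tuple(tr.non_cvd_death),
        between={
            ev: {dest: tuple(vals) for dest, vals in tr.between_events[ev].items()}
            for ev in EVENTS
        },
        bands=tuple(tuple(b) for b in tr.bands),
        horizon_years=tr.horizon_years,
    )


def _intervention_spec(cfg: ModelConfig, name: str) -> InterventionSpec:
    rate = cfg.run.currency_rate_rmb_per_usd
    for iv in cfg.interventions:
        if iv.name == name:
            components = []
            for comp in iv.components:
                block = cfg.evidence[comp.evidence]
                evidence = HazardRatioSet(
                    reference_delta=block.reference_delta_mmhg,
                    hr={o: tuple(v) for o, v in block.hr.items()},
                )
                adherence = AdherenceSchedule()
                if comp.adherence is not None:
                    adherence = AdherenceSchedule(
                        steps=tuple(tuple(s) for s in comp.adherence.steps),
                        final_fraction=comp.adherence.final_fraction,
                    )
                components.append(
                    EffectComponent(
                        evidence=evidence,
                        delta_sbp=comp.delta_sbp_mmhg,
                        adherence=adherence,
                    )
                )
            return InterventionSpec(
                name=name,
                annual_cost=iv.annual_cost.to_usd(rate),
                components=tuple(components),
            )
    raise KeyError(f"unknown strategy {name!r}")


class Model:
    """A runnable cost-effectiveness model bound to one configuration."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.transition_model = _transition_model(cfg)
        self.run_settings = RunSettings(
            start_age=cfg.run.start_age,
            max_age=cfg.run.max_age,
            currency_rate=cfg.run.currency_rate_rmb_per_usd,
        )
        self.discount = DiscountSettings(
            rate=cfg.run.discount_rate, convention=cfg.run.discount_convention
        )
        # Between-event probabilities are estimated on wide age groups keyed
        # by starting age: pick the band containing the start age, once.
        self.between_band = self.transition_model.band_index(cfg.run.start_age)

    def economics_for(self, name: str) -> StateEconomics:
        cfg = self.cfg
        rate = cfg.run.currency_rate_rmb_per_usd
        spec = _intervention_spec(cfg, name)
        state_cost: dict[str, float] = {}
        for ev in EVENTS:
            state_cost[acute_state(ev)] = cfg.economics.acute_cost[ev].to_usd(rate)
            state_cost[chronic_state(ev)] = cfg.economics.chronic_annual_cost[
                ev
            ].to_usd(rate)
        return StateEconomics(
            state_cost=state_cost,
            utility=dict(cfg.economics.utilities),
            intervention_annual_cost=spec.annual_cost,
            intervention_cost_states=cfg.run.intervention_cost_states,
        )

    def run_strategy(self, name: str) -> CohortTrace:
        spec = _intervention_spec(self.cfg, name)
        tm = self.transition_model
        recurrence = self.cfg.run.effects_apply_to_recurrence
        cache: dict[tuple, np.ndarray] = {}

        cap = self.cfg.run.effect_duration_years

        def provider(age: float, cycle: int) -> np.ndarray:
            band = tm.band_index(age)
            years = float(cycle)  # years since strategy start at cycle start
            if cap is not None and years >= cap:
                effects = {outcome: () for outcome in OUTCOMES}
            else:
                effects = {
                    outcome: spec.outcome_effects(outcome, band, years)
                    for outcome in OUTCOMES
                }
            key = (band, tuple(sorted((o, e) for o, e in effects.items())))
            if key not in cache:
                cache[key] = build_transition_matrix(
                    tm,
                    age,
                    effects=effects,
                    between_band=self.between_band,
                    apply_to_recurrence=recurrence,
                )
            return cache[key]

        return run_cohort(
            provider,
            self.economics_for(name),
            self.discount,
            self.run_settings,
            half_cycle_correction=self.cfg.run.half_cycle_correction,
        )

    def run_all(self) -> dict[str, CohortTrace]:
        return {name: self.run_strategy(name) for name in self.cfg.strategy_names()}

    def strategy_results(
        self, traces: Mapping[str, CohortTrace] | None = None
    ) -> list[StrategyResult]:
        traces = traces if traces is not None else self.run_all()
        return [
            StrategyResult(
                name=name,
                total_cost=trace.total_cost,
                total_qaly=trace.total_qaly,
                cvd_incidence=trace.lifetime_first_event_incidence,
            )
            for name, trace in traces.items()
        ]

    def frontier(self) -> FrontierResult:
        return efficiency_frontier(self.strategy_results())

    def decision_settings(self) -> DecisionSettings:
        return DecisionSettings(wtp=self.cfg.run.wtp_usd)


def run_with_overrides(
    cfg: ModelConfig, overrides: Mapping[str, float]
) -> dict[str, StrategyResult]:
    """Re-validate with overrides, run all strategies, return results by name."""
    model = Model(apply_overrides(cfg, overrides) if overrides else cfg)
    return {r.name: r for r in model.strategy_results()}


def icer_runner(cfg: ModelConfig, reference: str, comparator: str):
    """A callable mapping parameter overrides to the ICER of one pair.

    This is the runner shape the one-way sensitivity analysis and the
    threshold search consume.
    """
    from .cea import icer

    def run(overrides: Mapping[str, float]) -> float:
        res = run_with_overrides(cfg, overrides)
        return icer(res[reference], res[comparator])

    return run


def psa_runner(cfg: ModelConfig):
    """A callable mapping parameter overrides to per-strategy results."""

    def run(overrides: Mapping[str, float]) -> dict[str, StrategyResult]:
        return run_with_overrides(cfg, overrides)

    return run


def default_parameter_ranges(cfg: ModelConfig):
    """Plausibility ranges over the headline scalar parameters.

    Costs get ±30% (intervention annual costs ±50%, since they drive the
    headline tornado); chronic-state utilities get −0.10/+0.05 clipped to
    [0, 1]; hazard ratios at the youngest band get a ±0.08 band clipped to
    stay below 1.  Returns :class:`~bpcea.sensitivity.ParameterRange`
    objects keyed by dotted config paths.
    """
    from .sensitivity import ParameterRange

    ranges: list[ParameterRange] = []
    for iv in cfg.interventions:
        base = iv.annual_cost.value
        if base > 0:
            ranges.append(
                ParameterRange(
                    f"interventions.{iv.name}.annual_cost.value",
                    0.5 * base,
                    base,
                    1.5 * base,
                )
            )
    for section in ("acute_cost", "chronic_annual_cost"):
        for ev in EVENTS:
            base = getattr(cfg.economics, section)[ev].value
            ranges.append(
                ParameterRange(
                    f"economics.{section}.{ev}.value", 0.7 * base, base, 1.3 * base
                )
            )
    for ev in EVENTS:
        st = f"chronic_{ev}"
        base = cfg.economics.utilities[st]
        ranges.append(
            ParameterRange(
                f"economics.utilities.{st}",
                max(0.0, base - 0.10),
                base,
                min(1.0, base + 0.05),
            )
        )
    for key, block in cfg.evidence.items():
        for outcome in OUTCOMES:
            base = block.hr[outcome][0]
            ranges.append(
                ParameterRange(
                    f"evidence.{key}.hr.{outcome}.0",
                    max(0.05, base - 0.08),
                    base,
                    min(0.999, base + 0.08),
                )
            )
    return ranges
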