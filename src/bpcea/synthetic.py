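"""Synthetic parameter sets with the statistical structure of the study inputs.

Real transition probabilities and hazard ratios for this model are derived
from a restricted prospective cohort and are not redistributable.  This
module generates complete, schema-valid parameter files that reproduce the
*structure* of those inputs so every pipeline stage is testable:

* first-event probabilities that strictly increase across the four age
  bands (35-44 ... 65-75);
* per-10 mm Hg hazard ratios that attenuate with age and are strongest
  (smallest) for hemorrhagic stroke;
* an acute (hospitalization) vs chronic (annual management) cost split;
* utilities in [0, 1] with disease-free at 1;
* four strategies — no intervention, salt substitution (2 mm Hg SBP
  reduction), antihypertensive drugs (5.6 mm Hg), and their combination —
  wired through the evidence blocks;
* an optional high-CVD-risk variant scaling all baseline CVD hazards.

Magnitudes are calibrated so lifetime discounted QALYs from age 40 land
near 16-17 and headline ICERs near 10^3-10^4 USD/QALY; they are synthetic
calibration constants, not cohort estimates.  Generation is deterministic
per seed: every scalar receives a small lognormal jitter, with monotonicity
and ordering invariants enforced by construction.

Analytically solvable toy fixtures (geometric/annuity closed forms) are
also provided for engine verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import ModelConfig, validate_config
from .states import EVENTS, FATAL_CVD, NON_CVD_DEATH, OUTCOMES

# --- calibration constants (synthetic; order-of-magnitude realism only) ---

#: Baseline 10-year first-event probabilities at age band 35-44.
BASE_FIRST_EVENT: Mapping[str, float] = {
    "ami": 0.0024,
    "other_ihd": 0.018,
    "ischemic_stroke": 0.015,
    "hemorrhagic_stroke": 0.0036,
}
BASE_FATAL_CVD = 0.003
#: 10-year non-CVD death probabilities per band (not age-gradient scaled).
NON_CVD_DEATH_BY_BAND = (0.020, 0.050, 0.120, 0.300)

#: Per-10 mm Hg hazard ratios at age band 35-44.  The excess (1 - HR)
#: shrinks geometrically with each older band — blood-pressure associations
#: attenuate with age — and hemorrhagic stroke is the strongest
#: (smallest HR) outcome.
BASE_HR: Mapping[str, float] = {
    "hemorrhagic_stroke": 0.50,
    "ischemic_stroke": 0.70,
    "ami": 0.75,
    "other_ihd": 0.78,
    "fatal_cvd": 0.72,
}
HR_ATTENUATION = 0.55  # (1 - hr) multiplier per older band

#: 10-year probabilities out of chronic states (wide age groups).
BETWEEN_RECURRENCE = 0.15  # same-event recurrence
BETWEEN_CROSS = 0.04  # shift to a different event type
BETWEEN_FATAL_CVD = 0.18
BETWEEN_GRADIENT = 1.2  # increase per wider (older) start-age group

ACUTE_COST_USD: Mapping[str, float] = {
    "ami": 5000.0,
    "other_ihd": 2500.0,
    "ischemic_stroke": 3500.0,
    "hemorrhagic_stroke": 5500.0,
}
CHRONIC_ANNUAL_COST_USD: Mapping[str, float] = {
    "ami": 800.0,
    "other_ihd": 600.0,
    "ischemic_stroke": 900.0,
    "hemorrhagic_stroke": 1100.0,
}
ACUTE_UTILITY: Mapping[str, float] = {
    "ami": 0.65,
    "other_ihd": 0.75,
    "ischemic_stroke": 0.60,
    "hemorrhagic_stroke": 0.55,
}
CHRONIC_UTILITY_GAP = 0.20  # chronic utility = acute + gap, capped below 1

SALT_ANNUAL_COST_USD = 8.0
DRUG_ANNUAL_COST_USD = 80.0
SALT_DELTA_SBP = 2.0
DRUG_DELTA_SBP = 5.6


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic generator; defaults are the study conditions."""

    seed: int = 0
    n_age_bands: int = 4
    start_age: float = 40.0
    age_gradient: float = 1.5  # multiplicative increase of 10-yr p per band
    jitter_sd: float = 0.05  # lognormal sd applied to scalars
    high_risk: bool = False
    #: Hazard multiplier applied to all baseline CVD transitions for the
    #: high-CVD-risk subgroup variant.
    high_risk_multiplier: float = 2.0
    discount_rate: float = 0.05
    wtp_usd: float = 10264.8
    max_age: float = 100.0
    drug_adherence: bool = False

    def __post_init__(self) -> None:
        if self.n_age_bands < 1:
            raise ValueError("n_age_bands must be >= 1")
        if self.age_gradient <= 1.0:
            raise ValueError("age_gradient must exceed 1 (probabilities rise with age)")
        if self.high_risk_multiplier <= 0:
            raise ValueError("high_risk_multiplier must be positive")


def _bands(n: int) -> list[list[int]]:
    bands = [[35, 44], [45, 54], [55, 64], [65, 75]]
    if n <= 4:
        return bands[:n]
    lo = 75
    while len(bands) < n:
        bands.append([lo + 1, lo + 10])
        lo += 10
    return bands


def _risk_scale(p: float, multiplier: float) -> float:
    """Scale a probability in the rate domain so it stays in [0, 1)."""
    if p <= 0.0 or multiplier == 1.0:
        return p
    return -math.expm1(multiplier * math.log1p(-p))


def _cell_error(name: str, value: float) -> None:
    raise ValueError(f"synthetic generation produced invalid probability at {name}: {value}")


def generate_parameter_set(spec: SyntheticSpec) -> dict:
    """Generate a complete, schema-valid configuration dict.

    Deterministic per seed; raises naming the offending cell if any
    generated probability leaves [0, 1).
    """
    rng = np.random.default_rng(spec.seed)
    nb = spec.n_age_bands

    def jitter() -> float:
        return float(np.exp(rng.normal(0.0, spec.jitter_sd)))

    risk = spec.high_risk_multiplier if spec.high_risk else 1.0

    # First-event probabilities: jitter base and gradient once per outcome
    # so the increase across bands is strict by construction.
    first_event: dict[str, list[float]] = {}
    for ev in EVENTS:
        base = BASE_FIRST_EVENT[ev] * jitter()
        gradient = max(1.01, spec.age_gradient * jitter())
        probs = []
        for b in range(nb):
            p = _risk_scale(base * gradient**b, risk)
            if not 0.0 <= p < 1.0:
                _cell_error(f"transitions/first_event/{ev}/{b}", p)
            probs.append(round(p, 8))
        first_event[ev] = probs

    base_fatal = BASE_FATAL_CVD * jitter()
    grad_fatal = max(1.01, spec.age_gradient * jitter())
    fatal_cvd = []
    for b in range(nb):
        p = _risk_scale(base_fatal * grad_fatal**b, risk)
        if not 0.0 <= p < 1.0:
            _cell_error(f"transitions/fatal_cvd/{b}", p)
        fatal_cvd.append(round(p, 8))

    non_cvd = []
    for b in range(nb):
        ref = NON_CVD_DEATH_BY_BAND[min(b, len(NON_CVD_DEATH_BY_BAND) - 1)]
        p = min(0.95, ref * jitter())
        non_cvd.append(round(p, 8))

    # Between-event probabilities on wide start-age groups; the wider the
    # (older) group, the higher the probabilities.
    between: dict[str, dict[str, list[float]]] = {}
    for ev in EVENTS:
        dests: dict[str, list[float]] = {}
        for dest in EVENTS:
            base = (BETWEEN_RECURRENCE if dest == ev else BETWEEN_CROSS) * jitter()
            vals = []
            for b in range(nb):
                p = _risk_scale(min(0.9, base * BETWEEN_GRADIENT**b), risk)
                if not 0.0 <= p < 1.0:
                    _cell_error(f"transitions/between_events/{ev}/{dest}/{b}", p)
                vals.append(round(p, 8))
            dests[dest] = vals
        base = BETWEEN_FATAL_CVD * jitter()
        dests[FATAL_CVD] = [
            round(_risk_scale(min(0.9, base * BETWEEN_GRADIENT**b), risk), 8)
            for b in range(nb)
        ]
        dests[NON_CVD_DEATH] = [
            round(
                min(
                    0.95,
                    NON_CVD_DEATH_BY_BAND[min(b, len(NON_CVD_DEATH_BY_BAND) - 1)]
                    * 1.2
                    * jitter(),
                ),
                8,
            )
            for b in range(nb)
        ]
        between[ev] = dests

    # Hazard ratios: the excess (1 - HR) shrinks geometrically with age;
    # hemorrhagic stroke is enforced strongest (smallest HR) in every band.
    hr: dict[str, list[float]] = {}
    for outcome in OUTCOMES:
        base = min(0.99, BASE_HR[outcome] * jitter())
        vals = []
        for b in range(nb):
            v = 1.0 - (1.0 - base) * HR_ATTENUATION**b
            vals.append(round(min(0.995, v), 6))
        hr[outcome] = vals
    for b in range(nb):
        floor = min(hr[o][b] for o in OUTCOMES if o != "hemorrhagic_stroke")
        hr["hemorrhagic_stroke"][b] = min(hr["hemorrhagic_stroke"][b], round(floor, 6))

    utilities = {"disease_free": 1.0}
    for ev in EVENTS:
        acute_u = float(np.clip(ACUTE_UTILITY[ev] * jitter(), 0.05, 0.95))
        utilities[f"acute_{ev}"] = round(acute_u, 4)
        utilities[f"chronic_{ev}"] = round(min(0.99, acute_u + CHRONIC_UTILITY_GAP), 4)

    acute_cost = {
        ev: {"value": round(ACUTE_COST_USD[ev] * jitter(), 2), "currency": "USD"}
        for ev in EVENTS
    }
    chronic_cost = {
        ev: {
            "value": round(CHRONIC_ANNUAL_COST_USD[ev] * jitter(), 2),
            "currency": "USD",
        }
        for ev in EVENTS
    }

    salt_cost = round(SALT_ANNUAL_COST_USD * jitter(), 2)
    drug_cost = round(DRUG_ANNUAL_COST_USD * jitter(), 2)
    adherence = (
        {"steps": [[5.0, 0.75]], "final_fraction": 0.50} if spec.drug_adherence else None
    )
    salt_component = {"evidence": "bp_per_10mmhg", "delta_sbp_mmhg": SALT_DELTA_SBP}
    drug_component = {"evidence": "bp_per_10mmhg", "delta_sbp_mmhg": DRUG_DELTA_SBP}
    if adherence is not None:
        drug_component = {**drug_component, "adherence": adherence}

    config = {
        "run": {
            "start_age": spec.start_age,
            "max_age": spec.max_age,
            "discount_rate": spec.discount_rate,
            "wtp_usd": spec.wtp_usd,
        },
        "transitions": {
            "horizon_years": 10,
            "bands": _bands(nb),
            "first_event": first_event,
            "fatal_cvd": fatal_cvd,
            "non_cvd_death": non_cvd,
            "between_events": between,
        },
        "economics": {
            "acute_cost": acute_cost,
            "chronic_annual_cost": chronic_cost,
            "utilities": utilities,
        },
        "evidence": {
            "bp_per_10mmhg": {"reference_delta_mmhg": 10.0, "hr": hr},
        },
        "interventions": [
            {"name": "none", "annual_cost": {"value": 0.0, "currency": "USD"}},
            {
                "name": "salt_substitution",
                "annual_cost": {"value": salt_cost, "currency": "USD"},
                "components": [salt_component],
            },
            {
                "name": "drug_treatment",
                "annual_cost": {"value": drug_cost, "currency": "USD"},
                "components": [drug_component],
            },
            {
                "name": "combination",
                "annual_cost": {
                    "value": round(salt_cost + drug_cost, 2),
                    "currency": "USD",
                },
                "components": [salt_component, drug_component],
            },
        ],
    }
    validate_config(config)  # every generated set must pass the loader
    return config


@dataclass(frozen=True)
class ToyFixture:
    """A configuration whose totals have closed forms, plus those values."""

    config: dict
    expected: Mapping[str, float]
    params: Mapping[str, float] = field(default_factory=dict)

    def model_config(self) -> ModelConfig:
        return validate_config(self.config)


def _geometric_discounted_sum(per_cycle_survival: float, v: float, horizon: int) -> float:
    """sum_{t=0}^{H-1} s^(t+1) v^(t+1) — end-of-cycle accrual on survivors."""
    a = per_cycle_survival * v
    if a == 1.0:
        return float(horizon)
    return a * (1.0 - a**horizon) / (1.0 - a)


def _toy_config(
    annual_death: float,
    event_prob: float,
    horizon: int,
    discount_rate: float,
    intervention_cost: float,
) -> dict:
    nb = 4
    zero = [0.0] * nb
    p10_death = -math.expm1(10.0 * math.log1p(-annual_death)) if annual_death else 0.0
    p10_event = -math.expm1(10.0 * math.log1p(-event_prob)) if event_prob else 0.0
    first_event = {ev: list(zero) for ev in EVENTS}
    first_event["other_ihd"] = [p10_event] * nb
    between = {
        ev: {
            "other_ihd": [p10_event] * nb if ev == "other_ihd" else list(zero),
            "fatal_cvd": list(zero),
            "non_cvd_death": [p10_death] * nb,
        }
        for ev in EVENTS
    }
    utilities = {"disease_free": 1.0}
    for ev in EVENTS:
        utilities[f"acute_{ev}"] = 1.0
        utilities[f"chronic_{ev}"] = 1.0
    return {
        "run": {
            "start_age": 40.0,
            "max_age": 40.0 + horizon,
            "discount_rate": discount_rate,
        },
        "transitions": {
            "horizon_years": 10,
            "bands": _bands(nb),
            "first_event": first_event,
            "fatal_cvd": list(zero),
            "non_cvd_death": [p10_death] * nb,
            "between_events": between,
        },
        "economics": {
            "acute_cost": {ev: {"value": 0.0, "currency": "USD"} for ev in EVENTS},
            "chronic_annual_cost": {
                ev: {"value": 0.0, "currency": "USD"} for ev in EVENTS
            },
            "utilities": utilities,
        },
        "evidence": {},
        "interventions": [
            {
                "name": "toy",
                "annual_cost": {"value": intervention_cost, "currency": "USD"},
            }
        ],
    }


def generate_toy_fixture(
    kind: str,
    annual_death: float = 0.1,
    event_prob: float = 0.05,
    horizon: int = 60,
    discount_rate: float = 0.0,
    intervention_cost: float = 0.0,
) -> ToyFixture:
    """Analytically solvable fixtures for engine verification.

    ``two_state``: alive/dead with annual death probability; utilities 1 for
    alive, costs zero apart from an optional flat annual intervention cost.
    Discounted life-years have the geometric/annuity closed form
    ``sum_t ((1-q)/(1+r))^(t+1)``.

    ``three_state``: adds a CVD event channel (probability ``event_prob``
    per year) whose states carry utility 1 and zero cost, so totals equal
    the two-state closed form exactly — the decrement-free limit.
    """
    if kind not in ("two_state", "three_state"):
        raise ValueError(f"unknown toy fixture kind {kind!r}")
    eps = event_prob if kind == "three_state" else 0.0
    config = _toy_config(annual_death, eps, horizon, discount_rate, intervention_cost)
    v = 1.0 / (1.0 + discount_rate)
    qalys = _geometric_discounted_sum(1.0 - annual_death, v, horizon)
    expected = {
        "total_qaly": qalys,
        "total_cost": intervention_cost * qalys,
        "life_years_undiscounted": _geometric_discounted_sum(
            1.0 - annual_death, 1.0, horizon
        ),
    }
    params = {
        "annual_death": annual_death,
        "event_prob": eps,
        "horizon": horizon,
        "discount_rate": discount_rate,
        "intervention_cost": intervention_cost,
    }
    return ToyFixture(config=config, expected=expected, params=params)
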