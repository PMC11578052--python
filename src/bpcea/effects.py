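"""Translate blood-pressure effects into hazard multipliers on transitions.

Trials report intervention effectiveness as a systolic blood pressure (SBP)
reduction (salt substitution ≈2 mm Hg; antihypertensive drugs ≈5.6 mm Hg).
Epidemiological evidence supplies hazard ratios (HRs) per reference SBP
reduction (typically 10 mm Hg) for each CVD outcome and age band.  Under the
standard log-linear assumption, an HR for a different SBP reduction is
obtained by exponent scaling, and effects of combined interventions multiply.

Hazard ratios are applied to annual transition probabilities in the *rate*
domain — convert probability to a rate, multiply the rate, convert back —
which keeps probabilities in [0, 1) and makes composition of multipliers
exact.  Partial adherence is a mixture in probability space between the
fully-treated and untreated probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence


def ten_year_to_annual(p: float, horizon_years: float = 10.0) -> float:
    """Convert a cumulative probability over ``horizon_years`` to annual.

    Uses ``r = 1 - exp(ln(1 - p) / h)``, the constant-rate conversion; the
    exact inverse is ``p = 1 - (1 - r)**h``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"cumulative probability must be in [0, 1), got {p}")
    if horizon_years <= 0:
        raise ValueError(f"horizon_years must be positive, got {horizon_years}")
    return 1.0 - math.exp(math.log1p(-p) / horizon_years)


def scale_hazard_ratio(hr_ref: float, reference_delta: float, target_delta: float) -> float:
    """Rescale an HR from a reference SBP reduction to a target reduction.

    Log-linearity in SBP: ``HR(d) = HR(ref) ** (d / ref)``.  ``target_delta``
    of zero returns 1 (no effect).
    """
    if hr_ref <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr_ref}")
    if reference_delta <= 0:
        raise ValueError(f"reference_delta must be positive, got {reference_delta}")
    if target_delta < 0:
        raise ValueError(f"target_delta must be non-negative, got {target_delta}")
    return hr_ref ** (target_delta / reference_delta)


def combine_effects(multipliers: Sequence[float]) -> float:
    """Product of hazard multipliers; the empty product is 1 by convention."""
    out = 1.0
    for m in multipliers:
        if m <= 0:
            raise ValueError(f"hazard multipliers must be positive, got {m}")
        out *= m
    return out


def apply_multiplier_to_probability(p_annual: float, hr: float) -> float:
    """Apply a hazard multiplier to an annual probability in the rate domain.

    ``p' = 1 - exp(-hr * (-ln(1 - p)))``, equivalently ``1 - (1-p)**hr``.
    """
    if hr < 0:
        raise ValueError(f"hazard multiplier must be non-negative, got {hr}")
    if not 0.0 <= p_annual < 1.0:
        raise ValueError(
            f"annual probability must be in [0, 1), got {p_annual}"
        )
    if hr == 0.0:
        return 0.0
    if hr == 1.0 or p_annual == 0.0:
        return p_annual
    return -math.expm1(hr * math.log1p(-p_annual))


def apply_effect_with_adherence(p_annual: float, hr: float, fraction: float = 1.0) -> float:
    """Mixture of treated and untreated annual probabilities.

    A fraction ``f`` of the cohort experiences the hazard-multiplied
    probability and ``1 - f`` the baseline one, so the adjusted probability
    is ``f * p(hr) + (1 - f) * p``.  The mixture is exact in probability
    space rather than an approximate averaged HR.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"adherent fraction must be in [0, 1], got {fraction}")
    treated = apply_multiplier_to_probability(p_annual, hr)
    return fraction * treated + (1.0 - fraction) * p_annual


@dataclass(frozen=True)
class BloodPressureEffect:
    """An intervention's SBP reduction in mm Hg."""

    delta_sbp: float

    def __post_init__(self) -> None:
        if self.delta_sbp < 0:
            raise ValueError(f"delta_sbp must be non-negative, got {self.delta_sbp}")


@dataclass(frozen=True)
class HazardRatioSet:
    """Per-outcome, per-age-band hazard ratios at a reference SBP reduction.

    ``hr[outcome]`` is a tuple with one HR per age band; a pooled single-HR
    evidence source (e.g. the 0.89 per 5 mm Hg meta-analysis estimate) is
    represented by identical values across outcomes and bands.
    """

    reference_delta: float
    hr: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if self.reference_delta <= 0:
            raise ValueError(
                f"reference_delta must be positive, got {self.reference_delta}"
            )
        for outcome, values in self.hr.items():
            for v in values:
                if v <= 0:
                    raise ValueError(
                        f"hazard ratio for {outcome!r} must be positive, got {v}"
                    )

    @classmethod
    def pooled(
        cls, hr: float, reference_delta: float, outcomes: Sequence[str], n_bands: int
    ) -> "HazardRatioSet":
        return cls(
            reference_delta=reference_delta,
            hr={o: (hr,) * n_bands for o in outcomes},
        )

    def multiplier(self, outcome: str, band: int, target_delta: float | None) -> float:
        """HR for ``outcome`` at age ``band``, rescaled to ``target_delta``.

        ``target_delta`` of ``None`` applies the evidence HR as-is.
        """
        hr_ref = self.hr[outcome][band]
        if target_delta is None:
            return hr_ref
        return scale_hazard_ratio(hr_ref, self.reference_delta, target_delta)


@dataclass(frozen=True)
class AdherenceSchedule:
    """Piecewise-constant adherent fraction by years since strategy start.

    ``steps`` is a sequence of ``(until_year, fraction)`` pairs; the fraction
    applies while ``years_since_start < until_year``.  ``final_fraction``
    applies afterwards.  The default is full adherence forever.
    """

    steps: tuple[tuple[float, float], ...] = ()
    final_fraction: float = 1.0

    def __post_init__(self) -> None:
        last = 0.0
        for until, frac in self.steps:
            if until <= last:
                raise ValueError("adherence step boundaries must be increasing")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"adherent fraction must be in [0, 1], got {frac}")
            last = until
        if not 0.0 <= self.final_fraction <= 1.0:
            raise ValueError(
                f"adherent fraction must be in [0, 1], got {self.final_fraction}"
            )

    def fraction_at(self, years_since_start: float) -> float:
        for until, frac in self.steps:
            if years_since_start < until:
                return frac
        return self.final_fraction


FULL_ADHERENCE = AdherenceSchedule()

#: Adherence variant reported for antihypertensive drugs: 75% of the cohort
#: still on treatment during the first five years, 50% afterwards.
DRUG_ADHERENCE_VARIANT = AdherenceSchedule(steps=((5.0, 0.75),), final_fraction=0.50)


@dataclass(frozen=True)
class EffectComponent:
    """One intervention component's evidence wiring.

    ``delta_sbp`` of ``None`` means the evidence HR is applied directly
    (used for the pooled per-5-mm-Hg drug-trial variant); otherwise the HR
    is rescaled log-linearly from the evidence's reference reduction.
    """

    evidence: HazardRatioSet
    delta_sbp: float | None
    adherence: AdherenceSchedule = FULL_ADHERENCE


@dataclass(frozen=True)
class InterventionSpec:
    """A named strategy: annual cost plus zero or more effect components.

    The no-intervention comparator has no components.  The combination
    strategy carries one component per constituent intervention; their
    hazard multipliers compose multiplicatively (adherence mixtures are
    applied per component, in listed order).
    """

    name: str
    annual_cost: float
    components: tuple[EffectComponent, ...] = ()

    def __post_init__(self) -> None:
        if self.annual_cost < 0:
            raise ValueError(f"annual_cost must be non-negative, got {self.annual_cost}")

    def outcome_effects(
        self, outcome: str, band: int, years_since_start: float
    ) -> tuple[tuple[float, float], ...]:
        """(hazard multiplier, adherent fraction) per component for one cell."""
        out = []
        for comp in self.components:
            hr = comp.evidence.multiplier(outcome, band, comp.delta_sbp)
            frac = comp.adherence.fraction_at(years_since_start)
            out.append((hr, frac))
        return tuple(out)


def apply_components_to_probability(
    p_annual: float, effects: Sequence[tuple[float, float]]
) -> float:
    """Apply a pipeline of (hr, adherence) components to an annual probability."""
    p = p_annual
    for hr, frac in effects:
        p = apply_effect_with_adherence(p, hr, frac)
    return p
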