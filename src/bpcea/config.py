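"""Parameter-file schema, validation and currency normalization.

A model configuration is a YAML or JSON document with five sections:
``run`` (start age, horizon, discounting, WTP, behavioural switches),
``transitions`` (10-year probabilities by age band, tagged with an explicit
``horizon_years`` so the annual conversion is auditable), ``economics``
(acute/chronic costs and state utilities), ``evidence`` (named
hazard-ratio blocks) and ``interventions`` (strategies wiring costs and
evidence together).  Monetary fields declare their currency (USD or RMB)
and are normalized to USD at the configured exchange rate (default 6.9
RMB/USD, the 2019 value).

Validation is strict: schema violations raise :class:`ConfigError` with a
JSON-pointer-style path; unknown keys produce warnings; all probabilities
must lie in [0, 1) and utilities in [0, 1].
"""

from __future__ import annotations

import copy
import json
import warnings
from pathlib import Path
from typing import Any, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .states import DISEASE_FREE, EVENTS, FATAL_CVD, NON_CVD_DEATH, OUTCOMES

DEFAULT_RMB_PER_USD = 6.9


class ConfigError(ValueError):
    """A parameter file failed schema validation."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="allow")


class CostValue(_Section):
    value: float = Field(ge=0)
    currency: Literal["USD", "RMB"] = "USD"

    def to_usd(self, rmb_per_usd: float) -> float:
        return self.value if self.currency == "USD" else self.value / rmb_per_usd


class RunSection(_Section):
    start_age: float = 40.0
    max_age: float = 100.0
    discount_rate: float = Field(default=0.05, ge=0)
    discount_convention: Literal["start_of_cycle", "end_of_cycle"] = "end_of_cycle"
    wtp_usd: float = Field(default=10264.8, gt=0)
    currency_rate_rmb_per_usd: float = Field(default=DEFAULT_RMB_PER_USD, gt=0)
    half_cycle_correction: bool = False
    intervention_cost_states: Literal["alive", "disease_free"] = "alive"
    effects_apply_to_recurrence: bool = True
    #: Cap on how long intervention effects persist after strategy start
    #: (years); None extends the trial effects for the lifetime horizon.
    effect_duration_years: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _ages(self) -> "RunSection":
        if self.start_age >= self.max_age:
            raise ValueError("start_age must be below max_age")
        return self


def _check_prob_list(values: list[float], where: str) -> None:
    for i, p in enumerate(values):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"{where}/{i}: probability {p} outside [0, 1)")


class TransitionsSection(_Section):
    horizon_years: float = Field(default=10.0, gt=0)
    bands: list[tuple[int, int]] = Field(
        default=[(35, 44), (45, 54), (55, 64), (65, 75)]
    )
    first_event: dict[str, list[float]]
    fatal_cvd: list[float]
    non_cvd_death: list[float]
    between_events: dict[str, dict[str, list[float]]]

    @model_validator(mode="after")
    def _shape(self) -> "TransitionsSection":
        nb = len(self.bands)
        if nb < 1:
            raise ValueError("bands: at least one age band required")
        for lo, hi in self.bands:
            if lo >= hi:
                raise ValueError(f"bands: invalid band ({lo}, {hi})")
        for ev in EVENTS:
            if ev not in self.first_event:
                raise ValueError(f"first_event/{ev}: missing")
        for ev, values in self.first_event.items():
            if ev not in EVENTS:
                raise ValueError(f"first_event/{ev}: unknown event type")
            if len(values) != nb:
                raise ValueError(f"first_event/{ev}: expected {nb} values")
            _check_prob_list(values, f"first_event/{ev}")
        for name, values in (("fatal_cvd", self.fatal_cvd), ("non_cvd_death", self.non_cvd_death)):
            if len(values) != nb:
                raise ValueError(f"{name}: expected {nb} values")
            _check_prob_list(values, name)
        valid_dest = set(EVENTS) | {FATAL_CVD, NON_CVD_DEATH}
        for ev in EVENTS:
            if ev not in self.between_events:
                raise ValueError(f"between_events/{ev}: missing")
            for dest, values in self.between_events[ev].items():
                if dest not in valid_dest:
                    raise ValueError(f"between_events/{ev}/{dest}: unknown destination")
                if len(values) != nb:
                    raise ValueError(f"between_events/{ev}/{dest}: expected {nb} values")
                _check_prob_list(values, f"between_events/{ev}/{dest}")
        return self


class EconomicsSection(_Section):
    acute_cost: dict[str, CostValue]
    chronic_annual_cost: dict[str, CostValue]
    utilities: dict[str, float]

    @model_validator(mode="after")
    def _complete(self) -> "EconomicsSection":
        for ev in EVENTS:
            if ev not in self.acute_cost:
                raise ValueError(f"acute_cost/{ev}: missing")
            if ev not in self.chronic_annual_cost:
                raise ValueError(f"chronic_annual_cost/{ev}: missing")
        for key in list(self.acute_cost) + list(self.chronic_annual_cost):
            if key not in EVENTS:
                raise ValueError(f"costs/{key}: unknown event type")
        required = [DISEASE_FREE] + [
            f"{stage}_{ev}" for ev in EVENTS for stage in ("acute", "chronic")
        ]
        for st in required:
            if st not in self.utilities:
                raise ValueError(f"utilities/{st}: missing")
        for st, u in self.utilities.items():
            if st not in required:
                raise ValueError(f"utilities/{st}: unknown state")
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utilities/{st}: utility {u} outside [0, 1]")
        if self.utilities[DISEASE_FREE] != 1.0:
            raise ValueError(
                f"utilities/{DISEASE_FREE}: untreated disease-free utility must be 1"
            )
        return self


class EvidenceBlock(_Section):
    reference_delta_mmhg: float = Field(gt=0)
    hr: dict[str, list[float]]

    @model_validator(mode="after")
    def _hrs(self) -> "EvidenceBlock":
        for outcome, values in self.hr.items():
            if outcome not in OUTCOMES:
                raise ValueError(f"hr/{outcome}: unknown outcome")
            for i, v in enumerate(values):
                if v <= 0:
                    raise ValueError(f"hr/{outcome}/{i}: hazard ratio {v} must be > 0")
        for outcome in OUTCOMES:
            if outcome not in self.hr:
                raise ValueError(f"hr/{outcome}: missing")
        return self


class AdherenceSection(_Section):
    steps: list[tuple[float, float]] = []
    final_fraction: float = 1.0


class ComponentSection(_Section):
    evidence: str
    #: SBP reduction in mm Hg; omit (null) to apply the evidence HR as-is.
    delta_sbp_mmhg: float | None = Field(default=None, ge=0)
    adherence: AdherenceSection | None = None


class InterventionSection(_Section):
    name: str
    annual_cost: CostValue
    components: list[ComponentSection] = []


class ModelConfig(BaseModel):
    """Validated model configuration; see module docstring for the layout."""

    model_config = ConfigDict(extra="allow")

    run: RunSection = Field(default_factory=RunSection)
    transitions: TransitionsSection
    economics: EconomicsSection
    evidence: dict[str, EvidenceBlock]
    interventions: list[InterventionSection]

    #: The raw (pre-validation) dict, kept for parameter overrides.
    _raw: dict | None = None

    @model_validator(mode="after")
    def _cross_refs(self) -> "ModelConfig":
        names = [iv.name for iv in self.interventions]
        if len(set(names)) != len(names):
            raise ValueError("interventions: duplicate strategy names")
        if len(names) < 1:
            raise ValueError("interventions: at least one strategy required")
        nb = len(self.transitions.bands)
        for key, block in self.evidence.items():
            for outcome, values in block.hr.items():
                if len(values) != nb:
                    raise ValueError(
                        f"evidence/{key}/hr/{outcome}: expected {nb} values "
                        "(one per age band)"
                    )
        for iv in self.interventions:
            for j, comp in enumerate(iv.components):
                if comp.evidence not in self.evidence:
                    raise ValueError(
                        f"interventions/{iv.name}/components/{j}/evidence: "
                        f"unknown evidence block {comp.evidence!r}"
                    )
        return self

    @property
    def raw(self) -> dict:
        if self._raw is None:
            return self.model_dump(mode="json", exclude_none=True)
        return self._raw

    def strategy_names(self) -> list[str]:
        return [iv.name for iv in self.interventions]


def _warn_extras(model: BaseModel, path: str = "") -> None:
    extra = getattr(model, "model_extra", None) or {}
    for key in extra:
        warnings.warn(f"unknown key {path}/{key} ignored", stacklevel=3)
    for name in type(model).model_fields:
        value = getattr(model, name, None)
        if isinstance(value, BaseModel):
            _warn_extras(value, f"{path}/{name}")
        elif isinstance(value, list):
            for i, item in enumerate(value):
                if isinstance(item, BaseModel):
                    _warn_extras(item, f"{path}/{name}/{i}")
        elif isinstance(value, dict):
            for k, item in value.items():
                if isinstance(item, BaseModel):
                    _warn_extras(item, f"{path}/{name}/{k}")


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = "/" + "/".join(str(part) for part in e["loc"])
        lines.append(f"{loc}: {e['msg']}")
    return "; ".join(lines)


def validate_config(data: Mapping[str, Any]) -> ModelConfig:
    """Validate a configuration dict, returning the typed model."""
    try:
        cfg = ModelConfig.model_validate(dict(data))
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from None
    cfg._raw = copy.deepcopy(dict(data))
    _warn_extras(cfg)
    # Loader-level warning (not error) for a non-monotone age gradient.
    for ev, values in cfg.transitions.first_event.items():
        if any(b < a for a, b in zip(values, values[1:])):
            warnings.warn(
                f"transitions/first_event/{ev}: probabilities are not "
                "non-decreasing across age bands",
                stacklevel=2,
            )
    return cfg


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML or JSON parameter file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the document root")
    return validate_config(data)


def dump_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a configuration back out (YAML for .yaml/.yml, else JSON)."""
    path = Path(path)
    data = cfg.raw
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=2)


def set_by_path(data: dict, path: str, value: Any) -> dict:
    """Return a deep copy of ``data`` with the dotted ``path`` set to ``value``.

    List elements are addressed by integer index, or — for lists of mappings
    with a ``name`` key, such as the interventions list — by name.
    """
    out = copy.deepcopy(data)
    node: Any = out
    parts = path.split(".")
    for i, part in enumerate(parts):
        last = i == len(parts) - 1
        if isinstance(node, list):
            if part.lstrip("-").isdigit():
                key: Any = int(part)
            else:
                matches = [
                    j
                    for j, item in enumerate(node)
                    if isinstance(item, dict) and item.get("name") == part
                ]
                if not matches:
                    raise KeyError(f"no list element named {part!r} in path {path!r}")
                key = matches[0]
            if last:
                node[key] = value
            else:
                node = node[key]
        elif isinstance(node, dict):
            if last:
                node[part] = value
            else:
                if part not in node:
                    raise KeyError(f"path {path!r}: missing key {part!r}")
                node = node[part]
        else:
            raise KeyError(f"path {path!r}: cannot descend into {type(node).__name__}")
    return out


def apply_overrides(cfg: ModelConfig, overrides: Mapping[str, Any]) -> ModelConfig:
    """Re-validate the configuration with dotted-path parameter overrides."""
    data = cfg.raw
    for path, value in overrides.items():
        data = set_by_path(data, path, value)
    return validate_config(data)
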