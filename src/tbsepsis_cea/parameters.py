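"""Model parameters and structural configuration.

:class:`ParameterSet` mirrors the case study's input table field-for-field:
TB prevalence among the HIV-positive septic cohort, treatment outcome
probabilities (with the published sensitivity ranges where given),
disability weights, and unit costs, plus the three diagnostic profiles
(urine LAM, sputum Xpert MTB/RIF, combined LAM+Xpert).

:class:`StructureConfig` pins down the structural readings the source
analysis leaves open — how treated-TB mortality is factorised, whether
standard-of-care patients with missed TB can reach delayed empiric therapy
and in what state its survivors end, whether the acute sepsis disability
decrement applies, and whether delayed treatment is costed inside the trial
window.  Every field is explicit so a serialized run is unambiguous; the
calibration harness (:mod:`tbsepsis_cea.cea`) searches over these axes.
"""

from __future__ import annotations

import hashlib
import json
from decimal import Decimal
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .diagnostics import DiagnosticProfile

__all__ = [
    "Parameter",
    "ParameterSet",
    "StructureConfig",
    "MortalityMode",
    "load_parameters",
    "write_parameters",
    "default_parameters",
    "parameter_hash",
    "PROBABILITY_FIELDS",
    "COST_FIELDS",
]

MortalityMode = Literal["mortality_direct", "success_mediated", "empiric_success_mediated"]

#: scalar ParameterSet fields constrained to [0, 1]
PROBABILITY_FIELDS = (
    "prevalence_tb",
    "p_treatment_success_sensitive",
    "p_resistance",
    "p_death_treated_tb",
    "p_death_untreated_tb",
    "p_death_suspect_no_tb",
    "p_delayed_empiric",
    "dw_tb_hiv",
    "dw_tb_treatment",
    "dw_hiv_art",
    "dw_severe_sepsis",
)

#: scalar ParameterSet fields in USD (nonnegative, unbounded above)
COST_FIELDS = ("cost_tb_treatment",)


class Parameter(BaseModel):
    """A point value with an optional (low, high) sensitivity range."""

    model_config = ConfigDict(frozen=True)

    value: float
    low: Optional[float] = None
    high: Optional[float] = None

    @model_validator(mode="after")
    def _range_brackets_value(self) -> "Parameter":
        if (self.low is None) != (self.high is None):
            raise ValueError("low and high must be given together")
        if self.low is not None and not (self.low <= self.value <= self.high):
            raise ValueError(
                f"range must bracket the base value: {self.low} <= {self.value} <= {self.high}"
            )
        return self

    @property
    def has_range(self) -> bool:
        return self.low is not None


def _p(value: float, low: float | None = None, high: float | None = None) -> Parameter:
    return Parameter(value=value, low=low, high=high)


class ParameterSet(BaseModel):
    """Every input of the decision model, with optional sensitivity ranges."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    prevalence_tb: Parameter
    p_treatment_success_sensitive: Parameter
    p_resistance: Parameter
    p_death_treated_tb: Parameter
    p_death_untreated_tb: Parameter
    p_death_suspect_no_tb: Parameter
    dw_tb_hiv: Parameter
    dw_tb_treatment: Parameter
    dw_hiv_art: Parameter
    dw_severe_sepsis: Parameter
    cost_tb_treatment: Parameter
    #: probability that a missed-TB patient who survives the initial untreated
    #: period actually receives delayed empiric therapy (WHO fallback after
    #: 3-5 days of failed standard antibiotics)
    p_delayed_empiric: Parameter
    #: model time horizon in years (the trial's short follow-up window; the
    #: source analysis never states its length — see cea.calibrate)
    horizon_years: float = 1.0
    diagnostics: dict[str, DiagnosticProfile] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _domains(self) -> "ParameterSet":
        for name in PROBABILITY_FIELDS:
            p: Parameter = getattr(self, name)
            for label, v in (("value", p.value), ("low", p.low), ("high", p.high)):
                if v is not None and not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}.{label} = {v} outside [0, 1]")
        for name in COST_FIELDS:
            p = getattr(self, name)
            if p.value < 0 or (p.low is not None and p.low < 0):
                raise ValueError(f"{name} must be >= 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        return self

    # -- convenience -------------------------------------------------------

    def scalar_names(self) -> tuple[str, ...]:
        return PROBABILITY_FIELDS + COST_FIELDS

    def value_of(self, name: str) -> float:
        """Base value of a scalar parameter or dotted diagnostic field.

        Dotted names address diagnostics, e.g. ``"diagnostics.xpert.sensitivity"``.
        """
        if name.startswith("diagnostics."):
            _, diag, attr = name.split(".")
            return float(getattr(self.diagnostics[diag], attr))
        return getattr(self, name).value

    def range_of(self, name: str) -> tuple[float, float] | None:
        if name.startswith("diagnostics."):
            return None
        p: Parameter = getattr(self, name)
        return (p.low, p.high) if p.has_range else None

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with one scalar (or dotted diagnostic field) replaced.

        The replacement becomes the new base value; any range on the field is
        dropped (an excursion has no range of its own).
        """
        if name.startswith("diagnostics."):
            _, diag, attr = name.split(".")
            prof = self.diagnostics[diag]
            kwargs = {
                "name": prof.name,
                "sensitivity": prof.sensitivity,
                "specificity": prof.specificity,
                "unit_cost": prof.unit_cost,
            }
            kwargs[attr] = value
            diags = dict(self.diagnostics)
            diags[diag] = DiagnosticProfile(**kwargs)
            return self.model_copy(update={"diagnostics": diags})
        return self.model_copy(update={name: Parameter(value=value)})

    def with_horizon(self, horizon_years: float) -> "ParameterSet":
        return self.model_copy(update={"horizon_years": float(horizon_years)})


class StructureConfig(BaseModel):
    """Structural readings of the decision model, all set explicitly."""

    model_config = ConfigDict(frozen=True)

    #: how treated-TB outcomes are factorised: the directly measured 13.5%
    #: mortality; the success/resistance factorisation; or arm-specific
    #: (empiric arm and delayed empiric use success/resistance — the
    #: investigators' preliminary efficacy estimate — while standard-of-care
    #: confirmed-TB treatment uses the direct mortality).
    mortality_mode: MortalityMode = "mortality_direct"
    #: what happens to rifampin-resistant patients under first-line therapy:
    #: mortality of untreated TB, or the treated mortality (staying on a
    #: partially effective regimen); survivors remain in the TB/HIV state.
    resistance_outcome: Literal["untreated_mortality", "treated_mortality"] = "untreated_mortality"
    #: standard-of-care patients with missed TB can reach delayed empiric
    #: therapy after surviving the initial untreated period (WHO fallback).
    soc_delayed_empiric: bool = True
    #: uptake probability for delayed empiric therapy among initial-period
    #: survivors; None means use ParameterSet.p_delayed_empiric.
    delayed_uptake: Optional[float] = None
    #: terminal state of delayed-treatment survivors: fully treated, or still
    #: carrying the TB/HIV disability for the horizon (treatment came late).
    delayed_survivor_state: Literal["survived_tb_treated", "survived_tb_untreated"] = (
        "survived_tb_treated"
    )
    #: whether delayed empiric therapy is costed inside the analytic window
    #: (it starts after the day 3-5 reassessment and may fall outside the
    #: trial's costed window).
    count_delayed_treatment_cost: bool = True
    #: acute severe-sepsis disability decrement applied to all survivors.
    sepsis_dw_applied: bool = True
    #: length of the acute sepsis phase, in days.
    acute_days: float = 7.0
    #: both arms incur the diagnostic cost (true in the trial, where
    #: diagnostics run in both arms; set False for policy analyses).
    arm_shared_diagnostic_cost: bool = True
    #: selective-arm factorisation: branch on the test result first (marginal
    #: positivity then PPV/NPV) or on disease first (prevalence then
    #: conditional test result).  Rollback-equivalent.
    factorization: Literal["test_first", "disease_first"] = "test_first"


# --------------------------------------------------------------------------
# Serialisation.  The file schema accepts percentages or fractions with an
# explicit units key, either per-file or per-field:
#
#   probabilities:
#     units: percent
#     prevalence_tb: {value: 50}
#     p_treatment_success_sensitive: {value: 80, low: 66, high: 92}
#   ...
# --------------------------------------------------------------------------

_PERCENT = {"percent", "%"}
_FRACTION = {"fraction", "proportion"}


def _scale(raw: float, units: str, field: str) -> float:
    if units in _PERCENT:
        return raw / 100.0
    if units in _FRACTION:
        return raw
    raise ValueError(f"unknown units {units!r} for field {field}")


def _parse_parameter(obj, units: str, field: str, is_probability: bool) -> Parameter:
    if isinstance(obj, (int, float)):
        obj = {"value": obj}
    if not isinstance(obj, dict) or "value" not in obj:
        raise ValueError(f"field {field!r} must be a number or a mapping with 'value'")
    units = obj.get("units", units)
    scale = (lambda v: _scale(float(v), units, field)) if is_probability else float

    def get(key):
        return scale(obj[key]) if key in obj and obj[key] is not None else None

    value = scale(obj["value"]) if is_probability else float(obj["value"])
    p = Parameter(value=value, low=get("low"), high=get("high"))
    if is_probability and not 0.0 <= p.value <= 1.0:
        raise ValueError(f"{field} = {p.value} outside [0, 1] after unit resolution")
    return p


def _params_from_mapping(doc: dict) -> ParameterSet:
    try:
        probs = doc["probabilities"]
        utils = doc["utilities"]
        costs = doc["costs"]
        diags = doc["diagnostics"]
    except KeyError as e:
        raise ValueError(f"parameter file missing section: {e.args[0]}") from None

    p_units = probs.get("units", "fraction")
    u_units = utils.get("units", "fraction")

    fields: dict[str, Parameter] = {}
    for name in PROBABILITY_FIELDS:
        section, units = (utils, u_units) if name.startswith("dw_") else (probs, p_units)
        if name not in section:
            raise ValueError(f"parameter file missing field: {name}")
        fields[name] = _parse_parameter(section[name], units, name, is_probability=True)
    for name in COST_FIELDS:
        if name not in costs:
            raise ValueError(f"parameter file missing field: {name}")
        fields[name] = _parse_parameter(costs[name], "fraction", name, is_probability=False)

    d_units = diags.get("units", "fraction")
    profiles: dict[str, DiagnosticProfile] = {}
    for key, spec in diags.items():
        if key == "units":
            continue
        profiles[key] = DiagnosticProfile(
            name=spec.get("name", key),
            sensitivity=_scale(float(spec["sensitivity"]), spec.get("units", d_units), key),
            specificity=_scale(float(spec["specificity"]), spec.get("units", d_units), key),
            # exact decimal -> float once, so 4.19 + 17.42 == 21.61 in reports
            unit_cost=float(Decimal(str(spec["unit_cost"]))),
        )

    return ParameterSet(
        **fields,
        horizon_years=float(doc.get("horizon_years", 1.0)),
        diagnostics=profiles,
    )


def load_parameters(path) -> ParameterSet:
    """Read and fully validate a YAML/JSON parameter file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
    return _params_from_mapping(doc)


def write_parameters(params: ParameterSet, path) -> None:
    """Write a ParameterSet back to YAML/JSON (fractions, lossless round-trip)."""
    path = Path(path)

    def enc(p: Parameter) -> dict:
        d = {"value": p.value}
        if p.has_range:
            d["low"] = p.low
            d["high"] = p.high
        return d

    doc = {
        "probabilities": {
            "units": "fraction",
            **{n: enc(getattr(params, n)) for n in PROBABILITY_FIELDS if not n.startswith("dw_")},
        },
        "utilities": {
            "units": "fraction",
            **{n: enc(getattr(params, n)) for n in PROBABILITY_FIELDS if n.startswith("dw_")},
        },
        "costs": {n: enc(getattr(params, n)) for n in COST_FIELDS},
        "diagnostics": {
            "units": "fraction",
            **{
                key: {
                    "name": d.name,
                    "sensitivity": d.sensitivity,
                    "specificity": d.specificity,
                    "unit_cost": round(d.unit_cost, 2),
                }
                for key, d in params.diagnostics.items()
            },
        },
        "horizon_years": params.horizon_years,
    }
    with open(path, "w") as fh:
        if path.suffix in {".yaml", ".yml"}:
            yaml.safe_dump(doc, fh, sort_keys=False)
        else:
            json.dump(doc, fh, indent=2)


def default_parameters() -> ParameterSet:
    """The packaged base-case parameter table (Uganda HIV/TB-sepsis cohort)."""
    return load_parameters(Path(__file__).parent / "data" / "base_case.yaml")


def parameter_hash(params: ParameterSet) -> str:
    """Stable sha256 over the canonical JSON encoding of a ParameterSet."""
    payload = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
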