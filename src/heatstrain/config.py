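"""Structured run configuration.

A YAML file (all sections optional) can override any model constant:

.. code-block:: yaml

    clothing: {insulation: 0.12, clothed_proportion: 0.5}
    heat_balance: {risk_threshold: 1.5}
    sweat: {acclimatization_effect: 0.0}
    metabolic: {mass_exponent: 1.0}
    solar_scale: 0.9

Unknown keys are rejected before any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .heat_balance import ClothingParameters, HeatBalanceConfig
from .physiology import MetabolicModel, SweatModelCoefficients

__all__ = ["ModelSet", "load_model_set"]


@dataclass(frozen=True)
class ModelSet:
    """The four model-constant bundles plus the solar scale factor."""

    clothing: ClothingParameters = field(default_factory=ClothingParameters)
    heat_balance: HeatBalanceConfig = field(default_factory=HeatBalanceConfig)
    sweat: SweatModelCoefficients = field(default_factory=SweatModelCoefficients)
    metabolic: MetabolicModel = field(default_factory=MetabolicModel)
    solar_scale: float = 1.0


_SECTIONS = {
    "clothing": ClothingParameters,
    "heat_balance": HeatBalanceConfig,
    "sweat": SweatModelCoefficients,
    "metabolic": MetabolicModel,
}


def _build(cls, overrides: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} option(s): {sorted(unknown)}; valid: {sorted(valid)}"
        )
    return cls(**overrides)


def load_model_set(path: str | Path | None = None, overrides: dict | None = None) -> ModelSet:
    """Build a :class:`ModelSet` from a YAML file and/or an override dict.

    ``overrides`` (same nesting as the file) wins over the file, which
    wins over defaults.  Every value is type-checked by the target
    dataclass before any simulation starts.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data = loaded
    for section, values in (overrides or {}).items():
        if isinstance(values, dict):
            data.setdefault(section, {}).update(values)
        else:
            data[section] = values
    unknown = set(data) - set(_SECTIONS) - {"solar_scale"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {
        name: _build(cls, data.get(name, {}) or {}) for name, cls in _SECTIONS.items()
    }
    kwargs["solar_scale"] = float(data.get("solar_scale", 1.0))
    return ModelSet(**kwargs)
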