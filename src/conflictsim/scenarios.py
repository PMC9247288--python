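"""Named scenario variants of the fitness model.

A scenario is a declarative set of parameter overrides representing an
intervention or shock (contraception, a public-health programme, an economic
shock, women's education, household "monitoring" of the wife with or without
compensatory childcare, and added maternal mortality).  Eight built-in
scenarios cover these; user-defined scenarios load from a JSON config file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .model import ModelParameters, ParameterError


class ScenarioError(ValueError):
    """A scenario definition or config file is invalid."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter overrides.

    ``overrides`` maps :class:`~conflictsim.model.ModelParameters` field names
    to values; unknown names are rejected when the scenario is applied or
    loaded.
    """

    name: str
    description: str = ""
    overrides: dict[str, object] = field(default_factory=dict)

    def apply(self, base: ModelParameters) -> ModelParameters:
        return apply_scenario(base, self)


_BUILTINS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec(
        "basic",
        "Basic model: all ramps active, no intervention.",
        {},
    ),
    ScenarioSpec(
        "contraception",
        "Family-planning intervention fixing the inter-birth interval at "
        "3 years across all marital ages.",
        {"ibi_override": 3.0},
    ),
    ScenarioSpec(
        "public_health",
        "Public-health intervention reducing child mortality risk by 10%.",
        {"mortality_multiplier": 0.9},
    ),
    ScenarioSpec(
        "economic_shock",
        "Economic/environmental shock increasing child mortality by 20%.",
        {"mortality_multiplier": 1.2},
    ),
    ScenarioSpec(
        "education",
        "Women's education: IBI fixed at 3 years, 10% lower child mortality, "
        "paternity uncertainty fixed at 0.2 across all marital ages.",
        {"ibi_override": 3.0, "mortality_multiplier": 0.9, "pu_override": 0.2},
    ),
    ScenarioSpec(
        "monitoring_with_support",
        "Household monitoring of the wife (infidelity fixed at 0.01, IBI at "
        "2 years) with other household members compensating for lost maternal "
        "childcare, so mortality is unchanged.",
        {"ibi_override": 2.0, "pu_override": 0.01},
    ),
    ScenarioSpec(
        "monitoring_without_support",
        "Household monitoring without compensatory childcare: post-natal "
        "mortality rises 20% and stunting risk is tripled.",
        {
            "ibi_override": 2.0,
            "pu_override": 0.01,
            "mortality_multiplier": 1.2,
            "stunting_multiplier": 3.0,
        },
    ),
    ScenarioSpec(
        "maternal_mortality",
        "Basic model plus maternal mortality declining (cubically) with "
        "marriage age.",
        {"maternal_mortality_enabled": True},
    ),
)


def builtin_scenarios() -> list[ScenarioSpec]:
    """The eight built-in scenarios, in canonical report order."""
    return list(_BUILTINS)


def get_scenario(name: str) -> ScenarioSpec:
    """Look a built-in scenario up by name."""
    for spec in _BUILTINS:
        if spec.name == name:
            return spec
    known = ", ".join(s.name for s in _BUILTINS)
    raise ScenarioError(f"unknown scenario {name!r}; built-ins are: {known}")


def apply_scenario(base: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """Return a new parameter set with the scenario's overrides applied.

    The base is never mutated; an override naming an unknown field raises
    :class:`ScenarioError` identifying the key and scenario.
    """
    try:
        return base.with_overrides(**spec.overrides)
    except ParameterError as exc:
        raise ScenarioError(f"scenario {spec.name!r}: {exc}") from exc


def _spec_from_obj(obj: object, source: str) -> ScenarioSpec:
    if not isinstance(obj, dict):
        raise ScenarioError(f"{source}: scenario entry must be an object, got {obj!r}")
    unknown = set(obj) - {"name", "description", "overrides"}
    if unknown:
        raise ScenarioError(
            f"{source}: unknown scenario key(s): {', '.join(sorted(unknown))}"
        )
    name = obj.get("name")
    if not isinstance(name, str) or not name:
        raise ScenarioError(f"{source}: scenario 'name' must be a non-empty string")
    overrides = obj.get("overrides", {})
    if not isinstance(overrides, dict):
        raise ScenarioError(f"{source}: scenario {name!r} 'overrides' must be an object")
    spec = ScenarioSpec(name, str(obj.get("description", "")), dict(overrides))
    # fail fast on bad override keys/values, not at first use
    apply_scenario(ModelParameters(), spec)
    return spec


def load_scenarios(path: str | Path) -> list[ScenarioSpec]:
    """Load scenarios from a JSON file (top-level list of scenario objects).

    Raises :class:`ScenarioError` on parse failure, duplicate names, or
    unknown override keys.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ScenarioError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(data, list):
        raise ScenarioError(f"{path}: top level must be a list of scenario objects")
    specs = [_spec_from_obj(obj, str(path)) for obj in data]
    seen: set[str] = set()
    for spec in specs:
        if spec.name in seen:
            raise ScenarioError(f"{path}: duplicate scenario name {spec.name!r}")
        seen.add(spec.name)
    return specs


def dump_scenarios(specs: Iterable[ScenarioSpec], path: str | Path) -> None:
    """Write scenarios to a JSON file in the format ``load_scenarios`` reads."""
    payload = [
        {"name": s.name, "description": s.description, "overrides": s.overrides}
        for s in specs
    ]
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
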