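"""Rotator-cuff deficiency scenarios.

The intact case plus five deficiency situations studied during
abduction; under each scenario the listed muscles lose their activation
entirely.  Deficiency is modelled as a zero force capacity (upper bound
0 N) while the muscle stays in the model, so traces report an explicit
0 N force for torn muscles and output schemas are stable across
scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ShoulderModel

__all__ = ["SCENARIOS", "ScenarioSpec", "get_scenario", "apply_scenario"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cuff-deficiency situation: id plus the muscles that are lost."""

    id: str
    deficient_muscles: frozenset


SCENARIOS = {
    "INTACT": ScenarioSpec("INTACT", frozenset()),
    "Q1": ScenarioSpec("Q1", frozenset({"infraspinatus"})),
    "Q2": ScenarioSpec("Q2", frozenset({"supraspinatus"})),
    "Q3": ScenarioSpec("Q3", frozenset({"supraspinatus", "infraspinatus"})),
    "Q4": ScenarioSpec("Q4", frozenset({"subscapularis"})),
    "Q5": ScenarioSpec("Q5", frozenset({"supraspinatus", "infraspinatus",
                                        "subscapularis", "teres_minor"})),
}


def get_scenario(scenario_id: str) -> ScenarioSpec:
    try:
        return SCENARIOS[scenario_id.upper()]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; expected one of "
            f"{sorted(SCENARIOS)}") from None


def apply_scenario(model: ShoulderModel,
                   scenario: ScenarioSpec | str) -> ShoulderModel:
    """Return a copy of ``model`` with the scenario's muscles disabled.

    The original model is left untouched.  Applying a scenario is
    idempotent, and applying two scenarios in sequence unions their
    deficiency sets.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    names = set(model.muscle_names)
    unknown = scenario.deficient_muscles - names
    if unknown:
        raise KeyError(f"scenario {scenario.id}: muscles not in model: "
                       f"{sorted(unknown)}")
    out = model.copy()
    for mus in out.muscles:
        if mus.name in scenario.deficient_muscles:
            mus.deficient = True
    return out
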