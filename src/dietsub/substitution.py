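"""Beverage-substitution scenarios.

A scenario replaces every diary entry whose food belongs to a set of
target beverage categories with a single substitute food at unchanged
as-consumed mass ("matching volume" under a density of 1 g/mL, since
diary amounts are recorded in grams).  Replacement is an entry-level
food-identity swap, so the substituted dataset is a first-class dataset:
mass is conserved per child per day by construction and every downstream
stage (adequacy, statistics) runs on it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dietsub.composition import CompositionTable, SOFT_DRINK_CATEGORIES
from dietsub.records import DietaryDataset

__all__ = [
    "ScenarioError",
    "SubstitutionScenario",
    "ChangeSummary",
    "apply_scenario",
    "change_summary",
    "preset_scenarios",
    "PRESET_SUBSTITUTES",
]


class ScenarioError(ValueError):
    """Raised for invalid scenario definitions."""


@dataclass(frozen=True)
class SubstitutionScenario:
    """Replace all entries of ``target_categories`` with one substitute."""

    name: str
    substitute_food_id: str
    target_categories: frozenset[str] = field(default_factory=lambda: SOFT_DRINK_CATEGORIES)

    def __post_init__(self) -> None:
        if not self.target_categories:
            raise ScenarioError(f"scenario {self.name!r}: empty target set")
        unknown = self.target_categories - SOFT_DRINK_CATEGORIES
        if unknown:
            raise ScenarioError(
                f"scenario {self.name!r}: unknown target categories {sorted(unknown)}"
            )

    def validate_against(self, foods: CompositionTable) -> None:
        if self.substitute_food_id not in foods:
            raise ScenarioError(
                f"scenario {self.name!r}: substitute {self.substitute_food_id!r} "
                "not in composition table"
            )
        if foods[self.substitute_food_id].category in self.target_categories:
            raise ScenarioError(
                f"scenario {self.name!r}: substitute falls inside its own target set"
            )


# The three built-in models: soymilk, cow's milk, fortified milk powder.
PRESET_SUBSTITUTES: dict[str, str] = {
    "model1": "soymilk",
    "model2": "cow_milk",
    "model3": "fmp_psc",
}


def preset_scenarios(foods: CompositionTable | None = None) -> list[SubstitutionScenario]:
    """The three standard scenarios, optionally validated against a table."""
    scenarios = [
        SubstitutionScenario(name, substitute) for name, substitute in PRESET_SUBSTITUTES.items()
    ]
    if foods is not None:
        for s in scenarios:
            s.validate_against(foods)
    return scenarios


def apply_scenario(dataset: DietaryDataset, scenario: SubstitutionScenario) -> DietaryDataset:
    """Return a new dataset with targeted entries swapped to the substitute.

    Amounts, days, children and all non-target entries are untouched;
    the input dataset is not modified.
    """
    scenario.validate_against(dataset.foods)
    entries = dataset.entries.copy()
    categories = entries["food_id"].map(dataset.foods.category_of)
    mask = categories.isin(scenario.target_categories)
    entries.loc[mask, "food_id"] = scenario.substitute_food_id
    return dataset.with_entries(entries)


@dataclass(frozen=True)
class ChangeSummary:
    """Median, min and max of per-child daily change in one component,
    computed over the whole cohort (non-consumers contribute exactly 0)."""

    component: str
    median: float
    minimum: float
    maximum: float
    n: int


def change_summary(
    before: DietaryDataset, after: DietaryDataset, component: str = "energy"
) -> ChangeSummary:
    """Per-child (after - before) mean daily component across all children."""
    deltas = per_child_change(before, after, component)
    return ChangeSummary(
        component=component,
        median=float(np.median(deltas)),
        minimum=float(deltas.min()),
        maximum=float(deltas.max()),
        n=len(deltas),
    )


def per_child_change(
    before: DietaryDataset, after: DietaryDataset, component: str = "energy"
) -> np.ndarray:
    """Per-child delta vector (after - before), aligned to the roster order."""
    if set(before.children) != set(after.children):
        raise ScenarioError("before/after datasets cover different children")
    b = before.intake_frame()[component]
    a = after.intake_frame()[component].reindex(b.index)
    return (a - b).to_numpy()
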