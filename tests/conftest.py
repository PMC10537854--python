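import numpy as np
import pandas as pd
import pytest

from dietsub.composition import (
    CompositionTable,
    FoodItem,
    NutrientVector,
    load_composition_table,
    packaged_composition_path,
)
from dietsub.records import Child, DietaryDataset


@pytest.fixture(scope="session")
def substitutes() -> CompositionTable:
    """The packaged soymilk / cow's milk / FMP-PSC composition table."""
    return load_composition_table(packaged_composition_path())


def make_food(food_id, category="carbonated", form="liquid", factor=1.0, dairy=False, **amounts):
    """Small helper: a food with only the named components non-zero."""
    return FoodItem(
        food_id,
        food_id,
        category,
        NutrientVector.from_dict(amounts),
        form=form,
        reconstitution_factor=factor,
        dairy_drink=dairy,
    )


def make_dataset(foods, entries, children=None, diary_days=4):
    """Build a dataset from (child_id, day, food_id, amount) tuples.

    ``children`` maps child_id -> age_months (default 60 months).
    """
    df = pd.DataFrame(entries, columns=["child_id", "day", "food_id", "amount_g"])
    if children is None:
        children = {cid: 60 for cid in df["child_id"].unique()}
    kids = [Child(cid, age) for cid, age in children.items()]
    if not isinstance(foods, CompositionTable):
        foods = CompositionTable(foods)
    return DietaryDataset(kids, df, foods, diary_days=diary_days)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
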