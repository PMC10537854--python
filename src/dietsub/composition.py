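"""Food-composition handling: nutrient vectors, food items, and table I/O.

All composition values are stored per 100 g of the food's *reference
basis* (as-consumed weight for liquids and solids, powder weight for
powdered drinks).  :func:`as_consumed_profile` converts a powdered food
to the drinkable basis via its reconstitution factor.

A "/" (or empty) cell in a composition file means the component was not
present or not analysed.  Such cells are carried as value 0 with a
missingness flag, so that arithmetic treats them as zero contribution
while the flag survives addition and scaling and can be echoed in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NUTRIENTS",
    "NUTRIENT_UNITS",
    "NUTRIENT_COLUMNS",
    "CATEGORIES",
    "SOFT_DRINK_CATEGORIES",
    "CompositionError",
    "NutrientVector",
    "FoodItem",
    "CompositionTable",
    "as_consumed_profile",
    "scale",
    "load_composition_table",
    "write_composition_table",
    "packaged_composition_path",
]

# Fixed, ordered component set.  Vitamin A is carried under a declared
# label (RE or RAE) with no conversion between the two systems.
NUTRIENTS: tuple[str, ...] = (
    "energy",
    "carbohydrate",
    "protein",
    "fat",
    "calcium",
    "iron",
    "zinc",
    "iodine",
    "potassium",
    "vitamin_a",
    "vitamin_b1",
    "vitamin_b2",
    "vitamin_b3",
    "vitamin_b6",
    "vitamin_b9",
    "vitamin_b12",
    "vitamin_c",
    "vitamin_d",
)

NUTRIENT_UNITS: dict[str, str] = {
    "energy": "kcal",
    "carbohydrate": "g",
    "protein": "g",
    "fat": "g",
    "calcium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "iodine": "ug",
    "potassium": "mg",
    "vitamin_a": "ug RE",  # label may be overridden per table (RE vs RAE)
    "vitamin_b1": "mg",
    "vitamin_b2": "mg",
    "vitamin_b3": "mg NE",
    "vitamin_b6": "mg",
    "vitamin_b9": "ug DFE",
    "vitamin_b12": "ug",
    "vitamin_c": "mg",
    "vitamin_d": "ug",
}

# CSV column name for each component.
NUTRIENT_COLUMNS: dict[str, str] = {
    "energy": "energy_kcal",
    "carbohydrate": "carbohydrate_g",
    "protein": "protein_g",
    "fat": "fat_g",
    "calcium": "calcium_mg",
    "iron": "iron_mg",
    "zinc": "zinc_mg",
    "iodine": "iodine_ug",
    "potassium": "potassium_mg",
    "vitamin_a": "vita_ug",
    "vitamin_b1": "vitb1_mg",
    "vitamin_b2": "vitb2_mg",
    "vitamin_b3": "vitb3_mgne",
    "vitamin_b6": "vitb6_mg",
    "vitamin_b9": "vitb9_ugdfe",
    "vitamin_b12": "vitb12_ug",
    "vitamin_c": "vitc_mg",
    "vitamin_d": "vitd_ug",
}
_COLUMN_TO_NUTRIENT = {v: k for k, v in NUTRIENT_COLUMNS.items()}

# Survey beverage taxonomy: the seven soft-drink categories plus the
# non-soft-drink food classes used by the rest of the pipeline.
SOFT_DRINK_CATEGORIES: frozenset[str] = frozenset(
    {
        "carbonated",
        "fruit_vegetable",
        "protein_drink",
        "tea",
        "botanical",
        "flavored",
        "solid",
    }
)
CATEGORIES: frozenset[str] = SOFT_DRINK_CATEGORIES | {
    "dairy_product",
    "supplement",
    "other",
}

_N = len(NUTRIENTS)
_INDEX = {name: i for i, name in enumerate(NUTRIENTS)}


class CompositionError(ValueError):
    """Raised when a composition table or food item fails validation."""


class NutrientVector:
    """Ordered 18-component nutrient amount vector with missingness flags.

    Values are non-negative floats.  A component flagged missing at its
    source (a "/" cell) enters arithmetic as 0; through addition the
    flags OR together, so a flagged component in a total means "at least
    one contributor was unanalysed" while measured contributions still
    accumulate — the value is then a lower bound, which reports can mark.
    """

    __slots__ = ("values", "missing")

    def __init__(
        self,
        values: np.ndarray | Iterable[float] | None = None,
        missing: np.ndarray | Iterable[bool] | None = None,
    ):
        v = np.zeros(_N) if values is None else np.asarray(values, dtype=float).copy()
        if v.shape != (_N,):
            raise CompositionError(f"expected {_N} components, got shape {v.shape}")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise CompositionError("nutrient values must be finite and >= 0")
        m = (
            np.zeros(_N, dtype=bool)
            if missing is None
            else np.asarray(missing, dtype=bool).copy()
        )
        if m.shape != (_N,):
            raise CompositionError("missing mask must have one flag per component")
        self.values = v
        self.missing = m

    @classmethod
    def from_dict(cls, amounts: Mapping[str, float | None]) -> "NutrientVector":
        """Build from a name->amount mapping; ``None`` marks missing."""
        v = np.zeros(_N)
        m = np.zeros(_N, dtype=bool)
        for name, amount in amounts.items():
            if name not in _INDEX:
                raise CompositionError(f"unknown nutrient {name!r}")
            if amount is None:
                m[_INDEX[name]] = True
            else:
                v[_INDEX[name]] = float(amount)
        return cls(v, m)

    @classmethod
    def zeros(cls) -> "NutrientVector":
        return cls()

    def __getitem__(self, nutrient: str) -> float:
        return float(self.values[_INDEX[nutrient]])

    def is_missing(self, nutrient: str) -> bool:
        return bool(self.missing[_INDEX[nutrient]])

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(self.values + other.values, self.missing | other.missing)

    def __mul__(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise CompositionError("cannot scale by a negative factor")
        return NutrientVector(self.values * factor, self.missing.copy())

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return np.array_equal(self.values, other.values) and np.array_equal(
            self.missing, other.missing
        )

    def allclose(self, other: "NutrientVector", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.values, other.values, rtol=rtol, atol=atol))

    def as_dict(self) -> dict[str, float | None]:
        return {
            name: (None if self.missing[i] else float(self.values[i]))
            for i, name in enumerate(NUTRIENTS)
        }

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(
            f"{n}={'/' if self.missing[i] else self.values[i]:}" for i, n in enumerate(NUTRIENTS)
        )
        return f"NutrientVector({parts})"


@dataclass(frozen=True)
class FoodItem:
    """A food with a per-100 g composition on its reference basis.

    ``reconstitution_factor`` is grams of reference basis (powder) per
    gram as consumed; it is exactly 1.0 for liquids and solids eaten as
    recorded, and < 1 for powders diluted before drinking.
    ``dairy_drink`` flags dairy-based beverages orthogonally to the
    seven-category taxonomy (a dairy drink is typically a protein drink).
    """

    food_id: str
    name: str
    category: str
    composition: NutrientVector
    form: str = "liquid"
    reconstitution_factor: float = 1.0
    dairy_drink: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CompositionError(
                f"food {self.food_id!r}: unknown category {self.category!r}"
            )
        if self.form not in ("liquid", "powder", "solid"):
            raise CompositionError(f"food {self.food_id!r}: unknown form {self.form!r}")
        if not 0 < self.reconstitution_factor <= 1:
            raise CompositionError(
                f"food {self.food_id!r}: reconstitution_factor must be in (0, 1]"
            )
        if self.form != "powder" and self.reconstitution_factor != 1.0:
            raise CompositionError(
                f"food {self.food_id!r}: non-powder foods must have factor 1.0"
            )

    @property
    def is_soft_drink(self) -> bool:
        return self.category in SOFT_DRINK_CATEGORIES


def as_consumed_profile(item: FoodItem) -> NutrientVector:
    """Composition per 100 g of the food as actually consumed.

    Liquids and solids are returned unchanged; powders are multiplied by
    the reconstitution factor (g powder per g beverage).
    """
    if item.form == "powder":
        return item.composition * item.reconstitution_factor
    return item.composition


def scale(profile: NutrientVector, grams: float) -> NutrientVector:
    """Nutrient amounts contributed by ``grams`` of a per-100 g profile."""
    if grams < 0:
        raise CompositionError("grams must be >= 0")
    return profile * (grams / 100.0)


class CompositionTable:
    """Mapping of food_id to :class:`FoodItem` with a unit declaration."""

    def __init__(self, foods: Iterable[FoodItem] = (), vitamin_a_label: str = "RE"):
        self._foods: dict[str, FoodItem] = {}
        if vitamin_a_label not in ("RE", "RAE"):
            raise CompositionError("vitamin A label must be 'RE' or 'RAE'")
        self.vitamin_a_label = vitamin_a_label
        for item in foods:
            self.add(item)

    def add(self, item: FoodItem) -> None:
        if item.food_id in self._foods:
            raise CompositionError(f"duplicate food_id {item.food_id!r}")
        self._foods[item.food_id] = item

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._foods[food_id]
        except KeyError:
            raise KeyError(f"unknown food_id {food_id!r}") from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._foods

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self._foods.values())

    def __len__(self) -> int:
        return len(self._foods)

    @property
    def food_ids(self) -> list[str]:
        return list(self._foods)

    def with_food(self, item: FoodItem) -> "CompositionTable":
        """A copy of this table with one additional (or replaced) food."""
        foods = dict(self._foods)
        foods[item.food_id] = item
        return CompositionTable(foods.values(), self.vitamin_a_label)

    def category_of(self, food_id: str) -> str:
        return self[food_id].category

    def as_consumed_frame(self) -> pd.DataFrame:
        """Per-100 g as-consumed composition matrix, rows food_id."""
        data = {fid: as_consumed_profile(item).values for fid, item in self._foods.items()}
        return pd.DataFrame.from_dict(data, orient="index", columns=list(NUTRIENTS))

    def missing_frame(self) -> pd.DataFrame:
        data = {fid: item.composition.missing for fid, item in self._foods.items()}
        return pd.DataFrame.from_dict(data, orient="index", columns=list(NUTRIENTS))


_META_COLUMNS = ["food_id", "name", "category", "form", "reconstitution_factor"]


def _parse_cell(raw: object, row_label: str, column: str) -> float | None:
    """Parse one composition cell; '/' or blank means missing."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text in ("", "/", "nan"):
        return None
    try:
        value = float(text)
    except ValueError:
        raise CompositionError(
            f"row {row_label!r}, column {column!r}: cannot parse {text!r}"
        ) from None
    if value < 0:
        raise CompositionError(
            f"row {row_label!r}, column {column!r}: negative value {value}"
        )
    return value


def load_composition_table(path: str | Path, vitamin_a_label: str = "RE") -> CompositionTable:
    """Load a composition table from delimited text.

    Expected header: ``food_id,name,category,form,reconstitution_factor``
    followed by the 18 component columns (see :data:`NUTRIENT_COLUMNS`);
    an optional ``dairy_drink`` column holds 0/1 flags.  "/" or an empty
    cell marks a missing component.  Validation failures name the
    offending row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = set(_META_COLUMNS) | set(_COLUMN_TO_NUTRIENT) | {"dairy_drink"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise CompositionError(f"unknown column(s): {unknown}")
    missing_cols = [c for c in _META_COLUMNS + list(NUTRIENT_COLUMNS.values()) if c not in df.columns]
    if missing_cols:
        raise CompositionError(f"missing column(s): {missing_cols}")

    table = CompositionTable(vitamin_a_label=vitamin_a_label)
    for _, row in df.iterrows():
        fid = row["food_id"].strip()
        amounts: dict[str, float | None] = {}
        for nutrient, column in NUTRIENT_COLUMNS.items():
            amounts[nutrient] = _parse_cell(row[column], fid, column)
        factor_raw = _parse_cell(row["reconstitution_factor"], fid, "reconstitution_factor")
        if factor_raw is None:
            raise CompositionError(f"row {fid!r}: reconstitution_factor is required")
        form = row["form"].strip()
        if form != "powder" and factor_raw != 1.0:
            raise CompositionError(
                f"row {fid!r}, column 'reconstitution_factor': "
                f"{form} foods must have factor 1.0, got {factor_raw}"
            )
        dairy = str(row.get("dairy_drink", "0")).strip() in ("1", "true", "True")
        item = FoodItem(
            food_id=fid,
            name=row["name"].strip(),
            category=row["category"].strip(),
            composition=NutrientVector.from_dict(amounts),
            form=form,
            reconstitution_factor=factor_raw,
            dairy_drink=dairy,
        )
        table.add(item)
    return table


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    """Write a table back to CSV; missing components become '/'. """
    rows = []
    for item in table:
        row: dict[str, object] = {
            "food_id": item.food_id,
            "name": item.name,
            "category": item.category,
            "form": item.form,
            "reconstitution_factor": item.reconstitution_factor,
            "dairy_drink": int(item.dairy_drink),
        }
        for nutrient, column in NUTRIENT_COLUMNS.items():
            if item.composition.is_missing(nutrient):
                row[column] = "/"
            else:
                row[column] = repr(item.composition[nutrient])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def packaged_composition_path() -> Path:
    """Path of the packaged substitute-beverage composition file.

    The file holds the per-100 g compositions of soymilk, cow's milk and
    FMP-PSC (formulated milk powder for preschool children) used by the
    three built-in substitution scenarios; the milk-powder row is on the
    powder basis with a default label dilution of 14.7 g per 100 mL.
    """
    return Path(str(resources.files("dietsub").joinpath("data/substitutes.csv")))
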