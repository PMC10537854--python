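"""Multi-day individual dietary records: data model, I/O, aggregation.

A dataset couples a roster of children (36-72 months old), a flat table
of diary entries (child, day, food, grams as consumed), and a food
composition table.  Per-child intakes are averaged over the declared
diary length, so days without any entry count as zero-intake days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from dietsub.composition import (
    NUTRIENTS,
    CompositionTable,
    NutrientVector,
    SOFT_DRINK_CATEGORIES,
    as_consumed_profile,
    scale,
)
from dietsub.formatting import percent

__all__ = [
    "AGE_BANDS",
    "RecordsError",
    "Child",
    "ConsumerSummary",
    "DietaryDataset",
    "load_records",
    "write_records",
    "mean_daily_intake",
    "daily_intake_frame",
    "consumer_summary",
]

logger = logging.getLogger(__name__)

# Survey age strata (months).  The lower invariant bound is 36 months;
# a 36-month-old falls in the first stratum.
AGE_BANDS: tuple[tuple[int, int], ...] = ((37, 48), (49, 60), (61, 72))
AGE_GROUP_LABELS: tuple[str, ...] = tuple(f"{lo}-{hi}" for lo, hi in AGE_BANDS)

ENTRY_COLUMNS = ["child_id", "day", "food_id", "amount_g"]


class RecordsError(ValueError):
    """Raised on invalid dietary-record input."""


@dataclass(frozen=True)
class Child:
    child_id: str
    age_months: int
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if not 36 <= self.age_months <= 72:
            raise RecordsError(
                f"child {self.child_id!r}: age {self.age_months} months outside 36-72"
            )
        if self.sex not in ("M", "F", "unknown"):
            raise RecordsError(f"child {self.child_id!r}: sex must be M, F or unknown")

    @property
    def age_group(self) -> str:
        for (lo, hi), label in zip(AGE_BANDS, AGE_GROUP_LABELS):
            if self.age_months <= hi:
                return label
        raise AssertionError("unreachable: age validated in __post_init__")


@dataclass(frozen=True)
class ConsumerSummary:
    """Consumption summary for one stratum: counts plus the median
    (P25, P75) of mean daily grams among consumers only."""

    n_consumers: int
    n_total: int
    median: float | None
    p25: float | None
    p75: float | None

    @property
    def percent(self) -> float:
        return percent(self.n_consumers, self.n_total)


class DietaryDataset:
    """Children + diary entries + composition table; the pipeline unit.

    ``entries`` is a DataFrame with columns child_id, day, food_id,
    amount_g.  Treated as immutable after construction: scenario
    application returns a new dataset.
    """

    def __init__(
        self,
        children: Iterable[Child],
        entries: pd.DataFrame,
        foods: CompositionTable,
        diary_days: int = 4,
        n_excluded: int = 0,
    ):
        self.children: dict[str, Child] = {}
        for child in children:
            if child.child_id in self.children:
                raise RecordsError(f"duplicate child_id {child.child_id!r}")
            self.children[child.child_id] = child
        self.entries = entries.reset_index(drop=True)[ENTRY_COLUMNS].copy()
        self.foods = foods
        self.diary_days = int(diary_days)
        self.n_excluded = n_excluded
        self._intake_cache: pd.DataFrame | None = None
        self._validate()

    def _validate(self) -> None:
        if self.diary_days < 1:
            raise RecordsError("diary_days must be >= 1")
        e = self.entries
        bad_child = ~e["child_id"].isin(self.children)
        if bad_child.any():
            row = int(np.flatnonzero(bad_child.to_numpy())[0])
            raise RecordsError(f"entry row {row}: unknown child_id {e.at[row, 'child_id']!r}")
        bad_food = ~e["food_id"].isin(set(self.foods.food_ids))
        if bad_food.any():
            row = int(np.flatnonzero(bad_food.to_numpy())[0])
            raise RecordsError(f"entry row {row}: unresolvable food_id {e.at[row, 'food_id']!r}")
        days = e["day"].to_numpy()
        bad_day = (days < 1) | (days > self.diary_days)
        if bad_day.any():
            row = int(np.flatnonzero(bad_day)[0])
            raise RecordsError(
                f"entry row {row}: day {days[row]} outside 1..{self.diary_days}"
            )
        amounts = e["amount_g"].to_numpy(dtype=float)
        if np.any(amounts < 0) or np.any(~np.isfinite(amounts)):
            row = int(np.flatnonzero((amounts < 0) | ~np.isfinite(amounts))[0])
            raise RecordsError(f"entry row {row}: invalid amount {amounts[row]}")
        with_entries = set(e["child_id"])
        missing = set(self.children) - with_entries
        if missing:
            raise RecordsError(
                f"children without any diary entry: {sorted(missing)[:5]} "
                "(exclude them at load time)"
            )

    @property
    def n_children(self) -> int:
        return len(self.children)

    @property
    def child_ids(self) -> list[str]:
        return list(self.children)

    def ages(self) -> pd.Series:
        return pd.Series({cid: c.age_months for cid, c in self.children.items()})

    def age_groups(self) -> pd.Series:
        return pd.Series({cid: c.age_group for cid, c in self.children.items()})

    def with_entries(self, entries: pd.DataFrame, foods: CompositionTable | None = None) -> "DietaryDataset":
        return DietaryDataset(
            self.children.values(),
            entries,
            self.foods if foods is None else foods,
            self.diary_days,
            self.n_excluded,
        )

    def intake_frame(self) -> pd.DataFrame:
        """Mean daily intake per child (rows) and nutrient (columns)."""
        if self._intake_cache is None:
            self._intake_cache = daily_intake_frame(self)
        return self._intake_cache


def load_records(
    path: str | Path,
    foods: CompositionTable,
    diary_days: int = 4,
) -> DietaryDataset:
    """Load diary entries from delimited text.

    Expected header: ``child_id,age_months,sex,day,food_id,amount_g``.
    Rows with an empty food_id are roster placeholders (a child who
    reported no meal); children left with zero real entries are dropped
    and counted in ``n_excluded``.
    """
    df = pd.read_csv(path, dtype={"child_id": str, "food_id": str}, keep_default_na=False)
    required = ["child_id", "age_months", "sex", "day", "food_id", "amount_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordsError(f"missing column(s): {missing}")

    roster = df.drop_duplicates("child_id")
    children = {}
    for _, row in roster.iterrows():
        sex = str(row["sex"]).strip() or "unknown"
        children[row["child_id"]] = Child(row["child_id"], int(row["age_months"]), sex)

    real = df[df["food_id"].str.strip() != ""].copy()
    real["day"] = real["day"].astype(int)
    real["amount_g"] = real["amount_g"].astype(float)
    kept_ids = set(real["child_id"])
    excluded = [cid for cid in children if cid not in kept_ids]
    if excluded:
        logger.info("excluded %d child(ren) with no meals: %s", len(excluded), excluded[:5])
    kept_children = [c for cid, c in children.items() if cid in kept_ids]
    return DietaryDataset(
        kept_children,
        real[ENTRY_COLUMNS],
        foods,
        diary_days=diary_days,
        n_excluded=len(excluded),
    )


def write_records(dataset: DietaryDataset, path: str | Path) -> None:
    df = dataset.entries.copy()
    df["age_months"] = df["child_id"].map(lambda cid: dataset.children[cid].age_months)
    df["sex"] = df["child_id"].map(lambda cid: dataset.children[cid].sex)
    df[["child_id", "age_months", "sex", "day", "food_id", "amount_g"]].to_csv(path, index=False)


def mean_daily_intake(dataset: DietaryDataset, child_id: str) -> NutrientVector:
    """Mean daily nutrient intake of one child over the diary window.

    Each entry contributes ``scale(as_consumed_profile(food), amount)``;
    the sum is divided by the diary length, so unreported days count as
    zero-intake days.  Missingness flags propagate from consumed foods.
    """
    if child_id not in dataset.children:
        raise RecordsError(f"unknown child {child_id!r}")
    total = NutrientVector.zeros()
    sub = dataset.entries[dataset.entries["child_id"] == child_id]
    for food_id, amount in zip(sub["food_id"], sub["amount_g"]):
        total = total + scale(as_consumed_profile(dataset.foods[food_id]), amount)
    return total * (1.0 / dataset.diary_days)


def daily_intake_frame(dataset: DietaryDataset) -> pd.DataFrame:
    """Vectorised mean daily intakes for all children (child x nutrient)."""
    comp = dataset.foods.as_consumed_frame()  # per 100 g as consumed
    e = dataset.entries
    contrib = comp.loc[e["food_id"]].to_numpy() * (e["amount_g"].to_numpy()[:, None] / 100.0)
    contrib_df = pd.DataFrame(contrib, columns=list(NUTRIENTS))
    contrib_df["child_id"] = e["child_id"].to_numpy()
    totals = contrib_df.groupby("child_id").sum()
    # children exist in entries by construction; order by roster
    totals = totals.reindex(dataset.child_ids).fillna(0.0)
    return totals / dataset.diary_days


def _consumer_grams(dataset: DietaryDataset, food_ids: set[str]) -> pd.Series:
    """Mean daily grams of the selected foods per consuming child."""
    e = dataset.entries
    sel = e[e["food_id"].isin(food_ids)]
    grams = sel.groupby("child_id")["amount_g"].sum() / dataset.diary_days
    return grams


def consumer_summary(
    dataset: DietaryDataset,
    categories: frozenset[str] | set[str] | None = None,
    dairy_only: bool = False,
    by_age: bool = True,
) -> dict[str, ConsumerSummary]:
    """Consumption summary per age stratum plus "All".

    A consumer is any child with at least one entry of the selected
    foods on any diary day.  ``categories`` defaults to the seven
    soft-drink categories; ``dairy_only`` restricts to foods flagged as
    dairy drinks (orthogonal to the category taxonomy).  Quantiles use
    linear interpolation and cover consumers only.
    """
    categories = frozenset(categories) if categories is not None else SOFT_DRINK_CATEGORIES
    if not categories:
        raise RecordsError("categories must be non-empty")
    selected = {item.food_id for item in dataset.foods if item.category in categories}
    if dairy_only:
        selected = {fid for fid in selected if dataset.foods[fid].dairy_drink}
    grams = _consumer_grams(dataset, selected)
    groups = dataset.age_groups()

    def summarise(child_ids: list[str]) -> ConsumerSummary:
        g = grams[grams.index.isin(child_ids)]
        n = len(g)
        if n == 0:
            return ConsumerSummary(0, len(child_ids), None, None, None)
        p25, med, p75 = np.percentile(g.to_numpy(), [25, 50, 75], method="linear")
        return ConsumerSummary(n, len(child_ids), float(med), float(p25), float(p75))

    out = {"All": summarise(dataset.child_ids)}
    if by_age:
        for label in AGE_GROUP_LABELS:
            ids = [cid for cid in dataset.child_ids if groups[cid] == label]
            out[label] = summarise(ids)
    return out
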