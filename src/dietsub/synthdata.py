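"""Seeded generator of survey-like preschool dietary cohorts.

The survey microdata this pipeline targets is not publicly deposited, so
every stage is exercised on synthetic cohorts that reproduce the
published marginals: 676 children in three age strata (224/226/226
across 37-48/49-60/61-72 months), four diary days, per-stratum
soft-drink consumption probabilities of 22.77/23.45/32.74 % (26.33 %
overall), a consumer daily-amount distribution quantile-matched to the
printed P25/P75 of 25/75 g/d, and a beverage mix dominated by dairy
drinks.  The background diet is drawn from a pool of about twenty
synthetic foods whose compositions are plausible Chinese-food-table
values; portion habits are tuned only so that baseline cohort medians
land near the magnitudes a real preschool cohort shows, which is all the
adequacy logic needs.

Consumer daily amounts are log-normal with parameters fitted to the
(P25, P75) pair; the implied median (sqrt(P25*P75)) is reported by
``CohortSpec.implied_median`` and sits within ~8 % of the 40 g/d target
median, the residual being the price of a two-parameter fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from dietsub.composition import (
    CompositionTable,
    FoodItem,
    NutrientVector,
    SOFT_DRINK_CATEGORIES,
    as_consumed_profile,
    load_composition_table,
    packaged_composition_path,
)
from dietsub.records import AGE_BANDS, Child, DietaryDataset, ENTRY_COLUMNS

__all__ = ["CohortSpec", "default_composition_table", "generate", "null_cohort"]

_Z75 = float(norm.ppf(0.75))


@dataclass(frozen=True)
class CohortSpec:
    """Marginal targets and knobs for cohort generation."""

    n_children: int = 676
    strata_sizes: tuple[int, int, int] = (224, 226, 226)
    diary_days: int = 4
    # P(child consumes any soft drink within the diary window), per stratum
    consumption_prob: tuple[float, float, float] = (0.2277, 0.2345, 0.3274)
    # share of soft-drink consumers whose drink is a dairy drink (133/178)
    dairy_share: float = 0.7472
    # consumer mean-daily-amount distribution targets (g/d)
    amount_median: float = 40.0
    amount_p25: float = 25.0
    amount_p75: float = 75.0
    # within-window day clustering: P(drink day | consumer), independent days
    drink_day_prob: float = 0.5

    def __post_init__(self) -> None:
        if sum(self.strata_sizes) != self.n_children:
            raise ValueError("strata sizes must sum to n_children")
        if self.diary_days < 1:
            raise ValueError("diary_days must be >= 1")
        for p in (*self.consumption_prob, self.dairy_share, self.drink_day_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0 < self.amount_p25 < self.amount_median < self.amount_p75:
            raise ValueError("need 0 < P25 < median < P75 for the amount distribution")

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) from a two-parameter quantile match on (P25, P75)."""
        mu = 0.5 * (np.log(self.amount_p25) + np.log(self.amount_p75))
        sigma = (np.log(self.amount_p75) - np.log(self.amount_p25)) / (2 * _Z75)
        return float(mu), float(sigma)

    @property
    def implied_median(self) -> float:
        """Median of the fitted amount distribution, sqrt(P25 * P75)."""
        return float(np.exp(self.lognormal_params[0]))


# ---------------------------------------------------------------------------
# Synthetic food pool.
#
# Composition dicts are per 100 g as consumed (None = component not
# analysed, carried as 0 with a missingness flag, as in real food
# tables).  Habit tuples: (child_prob, day_prob, mean_grams, gamma_shape).
# ---------------------------------------------------------------------------

_BG = {
    "rice": (
        dict(energy=116, carbohydrate=25.9, protein=2.6, fat=0.3, calcium=7, iron=1.3,
             zinc=0.92, iodine=None, potassium=30, vitamin_b1=0.02, vitamin_b2=0.03,
             vitamin_b3=1.3, vitamin_b6=0.03, vitamin_b9=4, vitamin_d=None),
        (1.0, 0.95, 220, 6),
    ),
    "wheat_bun": (
        dict(energy=223, carbohydrate=47, protein=7, fat=1.1, calcium=38, iron=1.8,
             zinc=0.71, iodine=None, potassium=138, vitamin_b1=0.04, vitamin_b2=0.05,
             vitamin_b3=1.1, vitamin_b6=0.05, vitamin_b9=8, vitamin_d=None),
        (0.8, 0.5, 80, 4),
    ),
    "noodles": (
        dict(energy=110, carbohydrate=24, protein=3.9, fat=0.4, calcium=11, iron=1.2,
             zinc=0.38, iodine=None, potassium=45, vitamin_b1=0.05, vitamin_b2=0.02,
             vitamin_b3=0.9, vitamin_b6=0.04, vitamin_b9=4, vitamin_d=None),
        (0.8, 0.45, 130, 4),
    ),
    "egg": (
        dict(energy=144, carbohydrate=2.8, protein=13.3, fat=8.8, calcium=56, iron=2.0,
             zinc=1.1, iodine=27, potassium=154, vitamin_a=234, vitamin_b1=0.11,
             vitamin_b2=0.27, vitamin_b3=0.2, vitamin_b6=0.06, vitamin_b9=47,
             vitamin_b12=1.1, vitamin_d=None),
        (0.95, 0.7, 45, 4),
    ),
    "pork": (
        dict(energy=395, protein=13.2, fat=37, calcium=6, iron=1.6, zinc=2.06,
             iodine=None, potassium=204, vitamin_a=18, vitamin_b1=0.22, vitamin_b2=0.16,
             vitamin_b3=3.5, vitamin_b6=0.33, vitamin_b9=3, vitamin_b12=0.6,
             vitamin_d=None),
        (0.9, 0.6, 60, 4),
    ),
    "chicken": (
        dict(energy=167, carbohydrate=1.3, protein=19.3, fat=9.4, calcium=9, iron=1.4,
             zinc=1.09, iodine=None, potassium=251, vitamin_a=48, vitamin_b1=0.05,
             vitamin_b2=0.09, vitamin_b3=5.6, vitamin_b6=0.3, vitamin_b9=8,
             vitamin_b12=0.3, vitamin_d=None),
        (0.7, 0.3, 40, 4),
    ),
    "fish": (
        dict(energy=113, protein=18.6, fat=4.1, calcium=50, iron=0.5, zinc=0.94,
             iodine=15, potassium=334, vitamin_a=25, vitamin_b1=0.03, vitamin_b2=0.09,
             vitamin_b3=2.7, vitamin_b6=0.19, vitamin_b9=9, vitamin_b12=1.4,
             vitamin_d=2.0),
        (0.55, 0.3, 45, 4),
    ),
    "tofu": (
        dict(energy=84, carbohydrate=3.8, protein=8.1, fat=3.7, calcium=164, iron=1.9,
             zinc=1.11, iodine=None, potassium=125, vitamin_b9=15, vitamin_d=None),
        (0.6, 0.3, 40, 4),
    ),
    "milk": (
        dict(energy=54, carbohydrate=3.4, protein=3.0, fat=3.2, calcium=104, iron=0.3,
             zinc=0.42, iodine=1.9, potassium=109, vitamin_a=24, vitamin_b1=0.03,
             vitamin_b2=0.14, vitamin_b3=0.1, vitamin_b6=0.036, vitamin_b9=5,
             vitamin_b12=0.2, vitamin_c=1, vitamin_d=None),
        (0.85, 0.7, 250, 5),
    ),
    "yogurt": (
        dict(energy=72, carbohydrate=9.3, protein=2.5, fat=2.7, calcium=118, iron=0.4,
             zinc=0.53, iodine=0.9, potassium=150, vitamin_a=26, vitamin_b1=0.03,
             vitamin_b2=0.15, vitamin_b3=0.2, vitamin_b6=0.02, vitamin_b9=5,
             vitamin_b12=0.3, vitamin_c=1, vitamin_d=None),
        (0.5, 0.3, 90, 4),
    ),
    "leafy_veg": (
        dict(energy=15, carbohydrate=1.6, protein=1.5, fat=0.3, calcium=108, iron=1.9,
             zinc=0.33, iodine=None, potassium=178, vitamin_a=103, vitamin_b1=0.02,
             vitamin_b2=0.05, vitamin_b3=0.7, vitamin_b6=0.08, vitamin_b9=66,
             vitamin_c=28, vitamin_d=None),
        (1.0, 0.85, 70, 4),
    ),
    "carrot": (
        dict(energy=39, carbohydrate=8.8, protein=1.0, fat=0.2, calcium=32, iron=1.0,
             zinc=0.23, iodine=None, potassium=190, vitamin_a=344, vitamin_b6=0.16,
             vitamin_b9=17, vitamin_c=13, vitamin_d=None),
        (0.6, 0.3, 35, 4),
    ),
    "tomato": (
        dict(energy=20, carbohydrate=4.0, protein=0.9, calcium=10, iron=0.4,
             iodine=None, potassium=163, vitamin_a=92, vitamin_b9=15, vitamin_c=19,
             vitamin_d=None),
        (0.6, 0.35, 60, 4),
    ),
    "fruit": (
        dict(energy=54, carbohydrate=13.5, protein=0.3, calcium=6, iron=0.4, zinc=0.14,
             iodine=None, potassium=130, vitamin_a=4, vitamin_b1=0.02, vitamin_b2=0.02,
             vitamin_b3=0.3, vitamin_b6=0.05, vitamin_b9=6, vitamin_c=18,
             vitamin_d=None),
        (0.95, 0.65, 130, 4),
    ),
    "banana": (
        dict(energy=93, carbohydrate=22, protein=1.4, calcium=7, iron=0.4, iodine=None,
             potassium=256, vitamin_b6=0.37, vitamin_b9=27, vitamin_c=8,
             vitamin_d=None),
        (0.5, 0.3, 70, 4),
    ),
    "potato": (
        dict(energy=77, carbohydrate=17.2, protein=2.0, calcium=8, iron=0.8, zinc=0.37,
             iodine=None, potassium=342, vitamin_b1=0.08, vitamin_b6=0.27,
             vitamin_b9=21, vitamin_c=27, vitamin_d=None),
        (0.7, 0.35, 60, 4),
    ),
    "kelp": (
        dict(energy=77, carbohydrate=23, protein=1.8, calcium=348, iron=4.7, zinc=0.65,
             iodine=9000, potassium=761, vitamin_d=None),
        (0.4, 0.25, 12, 3),
    ),
    "iodized_salt": (
        dict(iodine=2500, vitamin_d=None),
        (0.7, 1.0, 2.5, 8),
    ),
    "pork_liver": (
        dict(energy=129, carbohydrate=5, protein=19.3, fat=3.5, calcium=6, iron=22.6,
             zinc=5.78, iodine=None, potassium=235, vitamin_a=4972, vitamin_b1=0.21,
             vitamin_b2=2.08, vitamin_b3=15, vitamin_b6=0.29, vitamin_b9=425,
             vitamin_b12=26, vitamin_c=20, vitamin_d=None),
        (0.3, 0.12, 25, 3),
    ),
    "cooking_oil": (
        dict(energy=899, fat=99.9, iodine=None, vitamin_d=None),
        (1.0, 1.0, 10, 8),
    ),
    "biscuit": (
        dict(energy=478, carbohydrate=71, protein=9, fat=16.6, calcium=40, iron=2.0,
             zinc=0.87, iodine=None, potassium=100, vitamin_b1=0.06, vitamin_b2=0.06,
             vitamin_b3=1.0, vitamin_b9=10, vitamin_d=None),
        (0.8, 0.5, 40, 4),
    ),
}

# Dietary supplement: label values per 100 g of preparation, consumed
# about 1 g/day by a minority; never a substitution target.
_SUPPLEMENT = (
    "supp_multivit",
    dict(vitamin_c=3000, vitamin_d=400, vitamin_a=8000, vitamin_b1=30, vitamin_b2=30),
    (0.15, 0.8, 1.0, 10),
)

# Soft drinks: one representative per category, plus a dairy drink
# (category protein_drink with the dairy flag set, the dominant type).
_SOFT_DRINKS: dict[str, tuple[str, bool, str, float, dict]] = {
    # food_id: (category, dairy_drink, form, reconstitution_factor, comp)
    "sd_dairy": (
        "protein_drink", True, "liquid", 1.0,
        dict(energy=64, carbohydrate=10.5, protein=1.0, fat=1.8, calcium=35,
             potassium=60, vitamin_a=8, vitamin_b2=0.03, vitamin_b12=0.05),
    ),
    "sd_carbonated": ("carbonated", False, "liquid", 1.0, dict(energy=43, carbohydrate=10.6, potassium=1)),
    "sd_fruit_vegetable": (
        "fruit_vegetable", False, "liquid", 1.0,
        dict(energy=45, carbohydrate=11, potassium=60, vitamin_a=5, vitamin_b9=3, vitamin_c=10),
    ),
    "sd_protein_drink": (
        "protein_drink", False, "liquid", 1.0,
        dict(energy=46, carbohydrate=8, protein=1.0, fat=1.0, calcium=20, potassium=50,
             vitamin_b1=0.01, vitamin_b2=0.02),
    ),
    "sd_tea": ("tea", False, "liquid", 1.0, dict(energy=35, carbohydrate=8.5, potassium=10)),
    "sd_botanical": ("botanical", False, "liquid", 1.0, dict(energy=38, carbohydrate=9.4, potassium=5)),
    "sd_flavored": ("flavored", False, "liquid", 1.0, dict(energy=42, carbohydrate=10.4, potassium=3, vitamin_c=5)),
    "sd_solid": (
        "solid", False, "powder", 0.12,
        dict(energy=390, carbohydrate=88, protein=2, fat=3, calcium=80, iron=1.0,
             zinc=0.5, potassium=150, vitamin_a=50, vitamin_b1=0.1, vitamin_b2=0.1,
             vitamin_b3=0.5, vitamin_b6=0.05, vitamin_b9=10, vitamin_c=30),
    ),
}

_NON_DAIRY_CATEGORY_FOOD = {
    "carbonated": "sd_carbonated",
    "fruit_vegetable": "sd_fruit_vegetable",
    "protein_drink": "sd_protein_drink",
    "tea": "sd_tea",
    "botanical": "sd_botanical",
    "flavored": "sd_flavored",
    "solid": "sd_solid",
}
_NON_DAIRY_ORDER = tuple(sorted(_NON_DAIRY_CATEGORY_FOOD))


def default_composition_table() -> CompositionTable:
    """Substitute beverages (packaged file) + synthetic survey food pool."""
    table = load_composition_table(packaged_composition_path())
    for food_id, (comp, _) in _BG.items():
        category = "dairy_product" if food_id in ("milk", "yogurt") else "other"
        table.add(FoodItem(food_id, food_id.replace("_", " "), category,
                           NutrientVector.from_dict(comp), form="solid" if food_id != "milk" else "liquid",
                           reconstitution_factor=1.0))
    sid, scomp, _ = _SUPPLEMENT
    table.add(FoodItem(sid, "multivitamin supplement", "supplement",
                       NutrientVector.from_dict(scomp), form="solid"))
    for food_id, (category, dairy, form, factor, comp) in _SOFT_DRINKS.items():
        table.add(FoodItem(food_id, food_id.replace("_", " "), category,
                           NutrientVector.from_dict(comp), form=form,
                           reconstitution_factor=factor, dairy_drink=dairy))
    return table


def _make_children(spec: CohortSpec, rng: np.random.Generator) -> tuple[list[Child], np.ndarray]:
    children: list[Child] = []
    strata = np.repeat(np.arange(3), spec.strata_sizes)
    for i, s in enumerate(strata):
        lo, hi = AGE_BANDS[s]
        age = int(rng.integers(lo, hi + 1))
        children.append(Child(f"c{i:04d}", age))
    return children, strata


def generate(
    spec: CohortSpec | None = None,
    seed: int | None = 0,
    foods: CompositionTable | None = None,
) -> DietaryDataset:
    """Draw one reproducible cohort under ``spec``.

    For a fixed seed the output is byte-identical across calls.  Every
    child ends up with at least one diary entry; soft-drink consumers
    get their mean-daily amount drawn from the fitted log-normal and
    split evenly over a random subset of drink days, so the mean daily
    grams over the window equal the drawn amount exactly.
    """
    spec = spec if spec is not None else CohortSpec()
    foods = foods if foods is not None else default_composition_table()
    rng = np.random.default_rng(seed)
    n, days = spec.n_children, spec.diary_days
    children, strata = _make_children(spec, rng)
    ids = np.array([c.child_id for c in children])

    # child-level appetite heterogeneity: real cohorts show much wider
    # between-child spread than independent per-day portion draws give
    appetite = rng.lognormal(0.0, 0.35, n)

    parts: list[pd.DataFrame] = []
    habits = [(fid, habit) for fid, (_, habit) in _BG.items()]
    habits.append((_SUPPLEMENT[0], _SUPPLEMENT[2]))
    for food_id, (child_prob, day_prob, mean_g, shape) in habits:
        eats = rng.random(n) < child_prob
        day_mask = (rng.random((n, days)) < day_prob) & eats[:, None]
        amounts = rng.gamma(shape, mean_g / shape, (n, days)) * appetite[:, None]
        rows, cols = np.nonzero(day_mask)
        if len(rows):
            parts.append(pd.DataFrame({
                "child_id": ids[rows],
                "day": cols + 1,
                "food_id": food_id,
                "amount_g": amounts[rows, cols],
            }))

    # soft drinks
    probs = np.asarray(spec.consumption_prob)[strata]
    consumer = rng.random(n) < probs
    mu, sigma = spec.lognormal_params
    amount_daily = rng.lognormal(mu, sigma, n)
    is_dairy = rng.random(n) < spec.dairy_share
    cat_pick = rng.integers(0, len(_NON_DAIRY_ORDER), n)
    drink_days = rng.random((n, days)) < spec.drink_day_prob
    forced_day = rng.integers(0, days, n)
    none_mask = ~drink_days.any(axis=1)
    drink_days[none_mask, forced_day[none_mask]] = True
    k_days = drink_days.sum(axis=1)
    per_day = amount_daily * days / k_days
    food_pick = np.where(
        is_dairy, "sd_dairy",
        np.array([_NON_DAIRY_CATEGORY_FOOD[_NON_DAIRY_ORDER[j]] for j in cat_pick]),
    )
    rows, cols = np.nonzero(drink_days & consumer[:, None])
    if len(rows):
        parts.append(pd.DataFrame({
            "child_id": ids[rows],
            "day": cols + 1,
            "food_id": food_pick[rows],
            "amount_g": per_day[rows],
        }))

    entries = pd.concat(parts, ignore_index=True)
    # guarantee >= 1 entry per child (vanishingly rare with these habits)
    covered = set(entries["child_id"])
    orphans = [cid for cid in ids if cid not in covered]
    if orphans:
        entries = pd.concat([entries, pd.DataFrame({
            "child_id": orphans, "day": 1, "food_id": "rice", "amount_g": 100.0,
        })], ignore_index=True)
    entries = entries.sort_values(["child_id", "day", "food_id"], kind="stable")
    return DietaryDataset(children, entries[ENTRY_COLUMNS], foods, diary_days=days)


def null_cohort(
    spec: CohortSpec | None = None,
    seed: int | None = 0,
    substitute_food_id: str = "soymilk",
    foods: CompositionTable | None = None,
) -> DietaryDataset:
    """A cohort whose soft drinks all share the substitute's composition.

    Every soft-drink entry is pointed at a "null drink" whose as-consumed
    profile equals the substitute's, so any scenario replacing it with
    that substitute changes no child's intake: an exact no-effect ground
    truth for null-scenario fixed-point suites.
    """
    base = foods if foods is not None else default_composition_table()
    null_item = FoodItem(
        "null_drink",
        "null drink (synthetic; matches substitute profile)",
        "flavored",
        as_consumed_profile(base[substitute_food_id]),
        form="liquid",
    )
    ds = generate(spec, seed, base.with_food(null_item))
    entries = ds.entries.copy()
    categories = entries["food_id"].map(ds.foods.category_of)
    mask = categories.isin(SOFT_DRINK_CATEGORIES) & (entries["food_id"] != "null_drink")
    entries.loc[mask, "food_id"] = "null_drink"
    return ds.with_entries(entries)
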