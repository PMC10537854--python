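"""EAR/AI cut-point evaluation of nutrient adequacy.

A child's mean daily intake of a nutrient is classed *inadequate* when
it is strictly below the age-band reference value: the estimated average
requirement (EAR) where one exists, the adequate intake (AI) otherwise
(here: potassium).  Nutrients without a population reference (fat,
energy) are typed ``none`` and return ``not_evaluable``.  Prevalence is
the count of inadequate children with the percentage rounded half-up to
two decimals.

The packaged reference file transcribes 2013 Chinese DRI EAR/AI values
for preschool children as a single 37-72-month band; band edges are
configurable through the file format, so a 48-month boundary can be
expressed by adding rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from dietsub.formatting import percent
from dietsub.composition import NUTRIENTS
from dietsub.records import DietaryDataset

__all__ = [
    "AdequacyError",
    "DRIReference",
    "load_dri",
    "packaged_dri_path",
    "classify_child",
    "prevalence",
    "intake_distribution",
]

INADEQUATE = "inadequate"
ADEQUATE = "adequate"
NOT_EVALUABLE = "not_evaluable"


class AdequacyError(ValueError):
    """Raised for invalid reference files or lookups."""


@dataclass(frozen=True)
class _Band:
    reference_type: str  # EAR | AI
    age_min: int
    age_max: int
    value: float
    units: str
    upper_level: float | None = None


class DRIReference:
    """Per-nutrient EAR/AI reference values keyed by age band (months)."""

    def __init__(self, bands: dict[str, list[_Band]], none_typed: set[str]):
        self._bands = bands
        self._none = none_typed

    def reference_type(self, nutrient: str) -> str:
        if nutrient in self._none:
            return "none"
        if nutrient in self._bands:
            return self._bands[nutrient][0].reference_type
        raise AdequacyError(f"nutrient {nutrient!r} has no reference entry")

    def lookup(self, nutrient: str, age_months: int) -> _Band:
        if nutrient in self._none:
            raise AdequacyError(f"nutrient {nutrient!r} is typed 'none'")
        if nutrient not in self._bands:
            raise AdequacyError(f"nutrient {nutrient!r} has no reference entry")
        for band in self._bands[nutrient]:
            if band.age_min <= age_months <= band.age_max:
                return band
        raise AdequacyError(
            f"age {age_months} months outside all bands for {nutrient!r}"
        )

    def values_for_ages(self, nutrient: str, ages: pd.Series) -> np.ndarray:
        """Vectorised cut-point per child for one nutrient."""
        return np.array([self.lookup(nutrient, int(a)).value for a in ages])

    @property
    def nutrients(self) -> list[str]:
        return sorted(self._bands.keys() | self._none)


def load_dri(path: str | Path) -> DRIReference:
    """Load a reference file: ``nutrient,reference_type,age_min_months,
    age_max_months,value,units[,upper_level]``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["nutrient", "reference_type", "age_min_months", "age_max_months", "value", "units"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AdequacyError(f"missing column(s): {missing}")
    bands: dict[str, list[_Band]] = {}
    none_typed: set[str] = set()
    for _, row in df.iterrows():
        nutrient = row["nutrient"].strip()
        if nutrient not in NUTRIENTS:
            raise AdequacyError(f"unknown nutrient {nutrient!r} in reference file")
        ref_type = row["reference_type"].strip()
        if ref_type == "none":
            none_typed.add(nutrient)
            continue
        if ref_type not in ("EAR", "AI"):
            raise AdequacyError(f"{nutrient!r}: reference_type must be EAR, AI or none")
        value = float(row["value"])
        if value <= 0:
            raise AdequacyError(f"{nutrient!r}: reference value must be > 0")
        upper_raw = str(row.get("upper_level", "")).strip()
        upper = float(upper_raw) if upper_raw not in ("", "/") else None
        bands.setdefault(nutrient, []).append(
            _Band(
                reference_type=ref_type,
                age_min=int(row["age_min_months"]),
                age_max=int(row["age_max_months"]),
                value=value,
                units=row["units"].strip(),
                upper_level=upper,
            )
        )
    for nutrient, blist in bands.items():
        types = {b.reference_type for b in blist}
        if len(types) > 1:
            raise AdequacyError(f"{nutrient!r}: mixed reference types across bands")
    return DRIReference(bands, none_typed)


def packaged_dri_path() -> Path:
    """Packaged 2013 Chinese DRI EAR/AI transcription for 3-6 year olds."""
    return Path(str(resources.files("dietsub").joinpath("data/dri_cn2013_preschool.csv")))


def classify_child(
    intake: float, nutrient: str, reference: DRIReference, age_months: int
) -> str:
    """Cut-point classification of one child's mean daily intake."""
    if reference.reference_type(nutrient) == "none":
        return NOT_EVALUABLE
    band = reference.lookup(nutrient, age_months)
    return INADEQUATE if intake < band.value else ADEQUATE


def inadequacy_flags(
    dataset: DietaryDataset, nutrient: str, reference: DRIReference
) -> pd.Series:
    """Boolean inadequacy flag per child (roster order)."""
    if reference.reference_type(nutrient) == "none":
        raise AdequacyError(f"nutrient {nutrient!r} is not evaluable (type 'none')")
    intakes = dataset.intake_frame()[nutrient]
    cutoffs = reference.values_for_ages(nutrient, dataset.ages().reindex(intakes.index))
    return pd.Series(intakes.to_numpy() < cutoffs, index=intakes.index)


def prevalence(
    dataset: DietaryDataset, nutrient: str, reference: DRIReference
) -> tuple[int, float]:
    """(count, percent) of children with inadequate intake."""
    flags = inadequacy_flags(dataset, nutrient, reference)
    count = int(flags.sum())
    return count, percent(count, dataset.n_children)


def intake_distribution(dataset: DietaryDataset, nutrient: str) -> tuple[float, float, float]:
    """(median, p25, p75) of per-child mean daily intake, all children."""
    if dataset.n_children == 0:
        raise AdequacyError("empty cohort")
    x = dataset.intake_frame()[nutrient].to_numpy()
    p25, med, p75 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), float(p25), float(p75)
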