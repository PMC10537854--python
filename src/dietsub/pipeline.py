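"""End-to-end orchestration: scenarios -> adequacy -> tests -> tables.

``run_pipeline`` takes a validated dataset, applies the three
substitution scenarios, and assembles the five survey-style tables:

* consumption summary (soft drinks and dairy drinks by age stratum,
  with chi-square / Kruskal-Wallis comparisons across strata);
* total energy with per-child change summaries and the a-f letters;
* macronutrients, minerals and vitamins: median (P25, P75) intakes,
  inadequacy counts N (%), and a-f letters from Wilcoxon (intakes) and
  McNemar (inadequacy flags) comparisons.

CSV outputs keep full precision; the text rendering applies the survey
formatting conventions (two decimals for intakes and percents, three
for p-values, trailing letter markers).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dietsub._version import __version__ as _version
from dietsub.adequacy import DRIReference, inadequacy_flags, intake_distribution, prevalence
from dietsub.formatting import fmt_median_iqr, fmt_p, fmt_percent_pair
from dietsub.records import AGE_GROUP_LABELS, DietaryDataset, consumer_summary, _consumer_grams
from dietsub.stats import (
    annotate,
    chi_square_independence,
    kruskal_wallis,
    mcnemar,
    wilcoxon_signed_rank,
)
from dietsub.substitution import SubstitutionScenario, apply_scenario, per_child_change, preset_scenarios

__all__ = ["ScenarioReport", "run_pipeline", "render_tables", "MACRONUTRIENTS", "MINERALS", "VITAMINS"]

MACRONUTRIENTS = ("carbohydrate", "protein", "fat")
MINERALS = ("calcium", "iron", "zinc", "iodine", "potassium")
VITAMINS = (
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

_GROUPS = ("before", "model1", "model2", "model3")
# the six pairwise comparisons: (letter, group A, group B)
_COMPARISONS = (
    ("a", "before", "model1"),
    ("b", "before", "model2"),
    ("c", "before", "model3"),
    ("d", "model1", "model2"),
    ("e", "model1", "model3"),
    ("f", "model2", "model3"),
)


@dataclass
class ScenarioReport:
    """All rendered tables plus run metadata (seed, config hash, version)."""

    consumption: pd.DataFrame
    consumption_tests: pd.DataFrame
    energy_summary: pd.DataFrame
    macronutrient_summary: pd.DataFrame
    mineral_summary: pd.DataFrame
    vitamin_summary: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "consumption": self.consumption,
            "consumption_tests": self.consumption_tests,
            "energy_summary": self.energy_summary,
            "macronutrient_summary": self.macronutrient_summary,
            "mineral_summary": self.mineral_summary,
            "vitamin_summary": self.vitamin_summary,
        }


def _config_hash(dataset: DietaryDataset, scenarios, dri: DRIReference, alpha: float, seed) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(dataset.entries, index=False).to_numpy().tobytes())
    h.update(pd.util.hash_pandas_object(dataset.foods.as_consumed_frame()).to_numpy().tobytes())
    for s in scenarios:
        h.update(f"{s.name}|{s.substitute_food_id}|{sorted(s.target_categories)}".encode())
    for nutrient in dri.nutrients:
        h.update(nutrient.encode())
        if dri.reference_type(nutrient) != "none":
            for band in dri._bands[nutrient]:
                h.update(f"{band.age_min}-{band.age_max}:{band.value}".encode())
    h.update(f"alpha={alpha};seed={seed};days={dataset.diary_days}".encode())
    return h.hexdigest()


def _consumption_table(dataset: DietaryDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    tests = []
    for label, dairy_only in (("soft_drinks", False), ("dairy_drinks", True)):
        summaries = consumer_summary(dataset, dairy_only=dairy_only)
        for stratum, s in summaries.items():
            rows.append({
                "drink_type": label,
                "stratum": stratum,
                "n_consumers": s.n_consumers,
                "n_total": s.n_total,
                "percent": s.percent,
                "median_g": s.median,
                "p25_g": s.p25,
                "p75_g": s.p75,
            })
        by_age = [summaries[g] for g in AGE_GROUP_LABELS]
        counts = np.array([
            [s.n_consumers for s in by_age],
            [s.n_total - s.n_consumers for s in by_age],
        ])
        if counts.sum(axis=1).min() > 0:
            chi = chi_square_independence(counts)
            tests.append({
                "drink_type": label, "comparison": "consumer_share_by_age",
                "test": chi.test_name, "statistic": chi.statistic, "p_value": chi.p_value,
            })
        else:
            # a consumer status shared by every child (or by none) leaves
            # nothing to compare across age groups
            tests.append({
                "drink_type": label, "comparison": "consumer_share_by_age",
                "test": "chi-square", "statistic": np.nan, "p_value": np.nan,
            })
        # amount comparison among consumers across strata
        grams_groups = []
        groups_series = dataset.age_groups()
        selected = {item.food_id for item in dataset.foods if item.is_soft_drink}
        if dairy_only:
            selected = {fid for fid in selected if dataset.foods[fid].dairy_drink}
        grams = _consumer_grams(dataset, selected)
        for g in AGE_GROUP_LABELS:
            ids = groups_series[groups_series == g].index
            vals = grams[grams.index.isin(ids)].to_numpy()
            if len(vals):
                grams_groups.append(vals)
        if len(grams_groups) >= 2:
            kw = kruskal_wallis(grams_groups)
            tests.append({
                "drink_type": label, "comparison": "amount_by_age",
                "test": kw.test_name, "statistic": kw.statistic, "p_value": kw.p_value,
            })
    return pd.DataFrame(rows), pd.DataFrame(tests)


def _pairwise_pvalues(values: dict[str, np.ndarray], test) -> dict[str, float]:
    return {
        letter: test(values[a], values[b]).p_value for letter, a, b in _COMPARISONS
    }


def _energy_table(frames: dict[str, pd.DataFrame], datasets: dict[str, DietaryDataset], alpha: float) -> pd.DataFrame:
    energy = {g: frames[g]["energy"].to_numpy() for g in _GROUPS}
    letters = annotate(_pairwise_pvalues(energy, wilcoxon_signed_rank), alpha)
    deltas = {
        g: per_child_change(datasets["before"], datasets[g], "energy") for g in _GROUPS[1:]
    }
    kw = kruskal_wallis(list(deltas.values()))
    rows = []
    for g in _GROUPS:
        p25, med, p75 = np.percentile(energy[g], [25, 50, 75], method="linear")
        row = {
            "group": g, "median": med, "p25": p25, "p75": p75,
            "letters": letters.letters(g),
            "change_median": np.nan, "change_min": np.nan, "change_max": np.nan,
        }
        if g != "before":
            d = deltas[g]
            row.update(change_median=float(np.median(d)), change_min=float(d.min()),
                       change_max=float(d.max()))
        rows.append(row)
    df = pd.DataFrame(rows)
    df["kw_change_p"] = kw.p_value
    return df


def _nutrient_table(
    nutrients: tuple[str, ...],
    frames: dict[str, pd.DataFrame],
    datasets: dict[str, DietaryDataset],
    dri: DRIReference,
    alpha: float,
) -> pd.DataFrame:
    rows = []
    for nutrient in nutrients:
        values = {g: frames[g][nutrient].to_numpy() for g in _GROUPS}
        letters_intake = annotate(_pairwise_pvalues(values, wilcoxon_signed_rank), alpha)
        evaluable = dri.reference_type(nutrient) != "none"
        if evaluable:
            flags = {g: inadequacy_flags(datasets[g], nutrient, dri).to_numpy() for g in _GROUPS}
            letters_prev = annotate(_pairwise_pvalues(flags, mcnemar), alpha)
        for g in _GROUPS:
            med, p25, p75 = intake_distribution(datasets[g], nutrient)
            row = {
                "nutrient": nutrient, "group": g,
                "median": med, "p25": p25, "p75": p75,
                "letters_intake": letters_intake.letters(g),
                "n_inadequate": pd.NA, "pct_inadequate": np.nan,
                "letters_prevalence": "",
            }
            if evaluable:
                count, pct = prevalence(datasets[g], nutrient, dri)
                row.update(
                    n_inadequate=count, pct_inadequate=pct,
                    letters_prevalence=letters_prev.letters(g),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    dataset: DietaryDataset,
    dri: DRIReference,
    scenarios: list[SubstitutionScenario] | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ScenarioReport:
    """Apply scenarios to ``dataset`` and assemble the full report.

    ``scenarios`` must contain exactly three models (default: the
    soymilk / cow's milk / FMP-PSC presets) so the a-f letter scheme is
    well defined.  Deterministic for fixed inputs and seed.
    """
    scenarios = scenarios if scenarios is not None else preset_scenarios(dataset.foods)
    if len(scenarios) != 3:
        raise ValueError("the letter annotation scheme requires exactly three scenarios")
    datasets: dict[str, DietaryDataset] = {"before": dataset}
    for group, scenario in zip(_GROUPS[1:], scenarios):
        datasets[group] = apply_scenario(dataset, scenario)
    frames = {g: ds.intake_frame() for g, ds in datasets.items()}

    consumption, consumption_tests = _consumption_table(dataset)
    energy_summary = _energy_table(frames, datasets, alpha)
    macronutrient_summary = _nutrient_table(MACRONUTRIENTS, frames, datasets, dri, alpha)
    mineral_summary = _nutrient_table(MINERALS, frames, datasets, dri, alpha)
    vitamin_summary = _nutrient_table(VITAMINS, frames, datasets, dri, alpha)

    meta = {
        "software_version": _version,
        "seed": seed,
        "alpha": alpha,
        "n_children": dataset.n_children,
        "diary_days": dataset.diary_days,
        "n_excluded": dataset.n_excluded,
        "scenarios": {s.name: s.substitute_food_id for s in scenarios},
        "vitamin_a_label": dataset.foods.vitamin_a_label,
        "config_hash": _config_hash(dataset, scenarios, dri, alpha, seed),
    }
    return ScenarioReport(consumption, consumption_tests, energy_summary, macronutrient_summary, mineral_summary, vitamin_summary, meta)


def _render_text(report: ScenarioReport) -> str:
    lines: list[str] = []
    n = report.meta["n_children"]
    lines.append(f"Beverage-substitution report (n = {n}, alpha = {report.meta['alpha']})")
    lines.append(f"config hash: {report.meta['config_hash'][:16]}  version: {report.meta['software_version']}")
    lines.append("")
    lines.append("Consumption before simulation")
    for _, r in report.consumption.iterrows():
        if r["n_consumers"] and r["median_g"] is not None and not pd.isna(r["median_g"]):
            dist = fmt_median_iqr(r["median_g"], r["p25_g"], r["p75_g"], 1)
        else:
            dist = "/"
        lines.append(
            f"  {r['drink_type']:<13} {r['stratum']:<6} "
            f"{fmt_percent_pair(int(r['n_consumers']), int(r['n_total'])):<16} g/d {dist}"
        )
    for _, r in report.consumption_tests.iterrows():
        lines.append(f"  {r['drink_type']} {r['comparison']}: p = {fmt_p(r['p_value'])}")
    lines.append("")
    lines.append("Total energy (kcal/d)")
    for _, r in report.energy_summary.iterrows():
        main = fmt_median_iqr(r["median"], r["p25"], r["p75"]) + (f" {r['letters']}" if r["letters"] else "")
        if pd.isna(r["change_median"]):
            change = "/"
        else:
            change = fmt_median_iqr(r["change_median"], r["change_min"], r["change_max"])
        lines.append(f"  {r['group']:<7} {main:<34} change {change}")
    lines.append(f"  Kruskal-Wallis on model changes: p = {fmt_p(report.energy_summary['kw_change_p'].iloc[0])}")
    for title, df in (
        ("Macronutrients", report.macronutrient_summary),
        ("Minerals", report.mineral_summary),
        ("Vitamins", report.vitamin_summary),
    ):
        lines.append("")
        lines.append(title)
        for _, r in df.iterrows():
            main = fmt_median_iqr(r["median"], r["p25"], r["p75"])
            if r["letters_intake"]:
                main += f" {r['letters_intake']}"
            if pd.isna(r["n_inadequate"]):
                prev = "/"
            else:
                prev = fmt_percent_pair(int(r["n_inadequate"]), n)
                if r["letters_prevalence"]:
                    prev += f" {r['letters_prevalence']}"
            lines.append(f"  {r['nutrient']:<13} {r['group']:<7} {main:<34} N(%) {prev}")
    lines.append("")
    return "\n".join(lines)


def render_tables(report: ScenarioReport, outdir: str | Path, formats: tuple[str, ...] = ("csv", "text")) -> list[Path]:
    """Write one full-precision CSV per summary table, report.txt and run_meta.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "csv" in formats:
        for name, df in report.tables().items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
    if "text" in formats:
        path = outdir / "report.txt"
        path.write_text(_render_text(report))
        written.append(path)
    meta_path = outdir / "run_meta.json"
    meta_path.write_text(json.dumps(report.meta, indent=2, default=str))
    written.append(meta_path)
    return written
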