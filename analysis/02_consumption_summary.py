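"""Soft-drink consumption by age band in the simulated cohort.

Reads the records written by 01_simulate_cohort.py and tabulates consumer
counts, percentages and amount quantiles for all soft drinks and for the
dairy-drink subset, with the across-age tests.
"""

from pathlib import Path

import pandas as pd

from dietsub.pipeline import run_pipeline
from dietsub.adequacy import load_dri, packaged_dri_path
from dietsub.records import load_records
from dietsub.synthdata import default_composition_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    foods = default_composition_table()
    dataset = load_records(OUT / "cohort_records.csv", foods)
    report = run_pipeline(dataset, load_dri(packaged_dri_path()))
    report.consumption.to_csv(OUT / "consumption_by_age.csv", index=False)
    report.consumption_tests.to_csv(OUT / "consumption_tests.csv", index=False)
    with pd.option_context("display.width", 120):
        print(report.consumption.to_string(index=False))
        print()
        print(report.consumption_tests.to_string(index=False))


if __name__ == "__main__":
    main()
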