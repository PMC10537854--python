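"""Draw the default synthetic cohort and store its diary records."""

from pathlib import Path

from dietsub.records import write_records
from dietsub.synthdata import CohortSpec, generate

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = CohortSpec()
    dataset = generate(spec, seed=SEED)
    write_records(dataset, OUT / "cohort_records.csv")
    print(f"cohort: {dataset.n_children} children, "
          f"{len(dataset.entries)} diary entries over {dataset.diary_days} days")
    print(f"records written to {OUT / 'cohort_records.csv'}")


if __name__ == "__main__":
    main()
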