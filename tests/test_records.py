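import numpy as np
import pytest

from dietsub.formatting import percent, round_half_up
from dietsub.records import (
    Child,
    RecordsError,
    consumer_summary,
    daily_intake_frame,
    load_records,
    mean_daily_intake,
    write_records,
)
from conftest import make_dataset, make_food
from oracles import percentiles_linear

RECORDS_HEADER = "child_id,age_months,sex,day,food_id,amount_g"


def _records_file(tmp_path, *rows):
    path = tmp_path / "records.csv"
    path.write_text("\n".join([RECORDS_HEADER, *rows]) + "\n")
    return path


class TestLoading:
    def test_minimal_file(self, tmp_path, substitutes):
        path = _records_file(
            tmp_path,
            "k1,60,M,1,cow_milk,100",
            "k1,60,M,2,cow_milk,150",
            "k1,60,M,4,soymilk,200",
        )
        ds = load_records(path, substitutes)
        assert ds.n_children == 1 and len(ds.entries) == 3 and ds.n_excluded == 0

    def test_child_without_meals_is_excluded_and_counted(self, tmp_path, substitutes):
        path = _records_file(
            tmp_path,
            "k1,60,M,1,cow_milk,100",
            "k2,48,F,1,,0",  # roster placeholder: no meal recorded
        )
        ds = load_records(path, substitutes)
        assert ds.n_children == 1 and "k2" not in ds.children
        assert ds.n_excluded == 1

    def test_day_out_of_range_rejected(self, tmp_path, substitutes):
        path = _records_file(tmp_path, "k1,60,M,5,cow_milk,100")
        with pytest.raises(RecordsError, match="day 5"):
            load_records(path, substitutes)

    def test_unresolvable_food_rejected(self, tmp_path, substitutes):
        path = _records_file(tmp_path, "k1,60,M,1,latte,100")
        with pytest.raises(RecordsError, match="latte"):
            load_records(path, substitutes)

    def test_age_outside_window_rejected(self):
        with pytest.raises(RecordsError):
            Child("x", 80)

    def test_age_group_assignment(self):
        assert Child("a", 37).age_group == "37-48"
        assert Child("b", 48).age_group == "37-48"
        assert Child("c", 49).age_group == "49-60"
        assert Child("d", 72).age_group == "61-72"

    def test_write_read_round_trip(self, tmp_path, substitutes):
        ds = make_dataset(substitutes, [("k1", 1, "cow_milk", 100.0), ("k1", 3, "soymilk", 50.0)])
        out = tmp_path / "rt.csv"
        write_records(ds, out)
        back = load_records(out, substitutes)
        assert back.entries["amount_g"].tolist() == ds.entries["amount_g"].tolist()


class TestMeanDailyIntake:
    def test_daily_milk_every_day(self, substitutes):
        ds = make_dataset(substitutes, [("k1", d, "cow_milk", 100.0) for d in range(1, 5)])
        assert mean_daily_intake(ds, "k1")["calcium"] == pytest.approx(104)

    def test_zero_amount_gives_zero_vector(self, substitutes):
        ds = make_dataset(substitutes, [("k1", 1, "cow_milk", 0.0)])
        assert np.all(mean_daily_intake(ds, "k1").values == 0)

    def test_single_day_averaged_over_diary(self, substitutes):
        # 200 g soymilk on one of four days: 200 * 31 / 100 / 4 kcal/d
        ds = make_dataset(substitutes, [("k1", 1, "soymilk", 200.0)])
        assert mean_daily_intake(ds, "k1")["energy"] == pytest.approx(15.5)

    def test_unknown_child_rejected(self, substitutes):
        ds = make_dataset(substitutes, [("k1", 1, "soymilk", 200.0)])
        with pytest.raises(RecordsError):
            mean_daily_intake(ds, "nope")

    def test_additive_over_disjoint_entry_subsets(self, substitutes, rng):
        entries = [
            ("k1", int(rng.integers(1, 5)), fid, float(rng.uniform(0, 300)))
            for fid in ["cow_milk", "soymilk", "fmp_psc"]
            for _ in range(4)
        ]
        full = make_dataset(substitutes, entries)
        part1 = make_dataset(substitutes, entries[:6])
        part2 = make_dataset(substitutes, entries[6:])
        combined = mean_daily_intake(part1, "k1").values + mean_daily_intake(part2, "k1").values
        assert np.allclose(mean_daily_intake(full, "k1").values, combined)

    def test_vectorised_frame_matches_per_child_path(self, substitutes, rng):
        entries = [
            (f"k{i}", int(rng.integers(1, 5)), rng.choice(["cow_milk", "soymilk", "fmp_psc"]),
             float(rng.uniform(0, 200)))
            for i in range(5)
            for _ in range(3)
        ]
        ds = make_dataset(substitutes, entries)
        frame = daily_intake_frame(ds)
        for cid in ds.child_ids:
            assert np.allclose(frame.loc[cid].to_numpy(), mean_daily_intake(ds, cid).values)


class TestConsumerSummary:
    @pytest.fixture
    def drinks(self):
        return [
            make_food("cola", "carbonated", energy=43),
            make_food("milk_drink", "protein_drink", dairy=True, energy=64),
            make_food("water", "other"),
        ]

    def test_consumer_counts_and_percent(self, drinks):
        entries = [("k1", 1, "cola", 100.0), ("k2", 1, "water", 100.0), ("k3", 2, "water", 50.0)]
        children = {"k1": 40, "k2": 55, "k3": 65}
        out = consumer_summary(make_dataset(drinks, entries, children))
        assert out["All"].n_consumers == 1 and out["All"].n_total == 3
        assert out["All"].percent == 33.33
        assert out["37-48"].n_consumers == 1 and out["49-60"].n_consumers == 0

    def test_stratum_counts_sum_to_all(self, drinks, rng):
        entries, children = [], {}
        for i in range(60):
            cid = f"k{i}"
            children[cid] = int(rng.integers(37, 73))
            fid = "cola" if rng.random() < 0.4 else "water"
            entries.append((cid, int(rng.integers(1, 5)), fid, float(rng.uniform(10, 300))))
        out = consumer_summary(make_dataset(drinks, entries, children))
        assert sum(out[g].n_consumers for g in ("37-48", "49-60", "61-72")) == out["All"].n_consumers

    def test_no_consumers_leaves_quantiles_absent(self, drinks):
        out = consumer_summary(make_dataset(drinks, [("k1", 1, "water", 100.0)]))
        assert out["All"].n_consumers == 0 and out["All"].percent == 0.0
        assert out["All"].median is None

    def test_quantiles_match_sort_based_oracle(self, drinks, rng):
        entries = []
        grams = {}
        for i in range(17):
            cid = f"k{i}"
            total = float(rng.uniform(20, 400))
            grams[cid] = total / 4
            entries.append((cid, 1, "cola", total))
        out = consumer_summary(make_dataset(drinks, entries))
        p25, med, p75 = percentiles_linear(grams.values())
        assert out["All"].median == pytest.approx(med)
        assert out["All"].p25 == pytest.approx(p25)
        assert out["All"].p75 == pytest.approx(p75)

    def test_dairy_only_filter(self, drinks):
        entries = [("k1", 1, "cola", 100.0), ("k2", 1, "milk_drink", 80.0)]
        out = consumer_summary(make_dataset(drinks, entries), dairy_only=True)
        assert out["All"].n_consumers == 1


class TestPercentFormatting:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (178, 676, 26.33),
            (133, 676, 19.67),
            (619, 676, 91.57),
            (233, 676, 34.47),
            (482, 676, 71.30),
            (405, 676, 59.91),
        ],
    )
    def test_survey_count_percent_pairs(self, count, total, expected):
        assert percent(count, total) == expected

    def test_half_up_ties(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(2.675, 2) == 2.68
        assert round_half_up(0.0269, 3) == 0.027
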