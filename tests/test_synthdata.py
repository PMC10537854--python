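import numpy as np
import pytest

from dietsub.adequacy import load_dri, packaged_dri_path, prevalence
from dietsub.composition import SOFT_DRINK_CATEGORIES
from dietsub.records import _consumer_grams, consumer_summary
from dietsub.stats import mcnemar, wilcoxon_signed_rank
from dietsub.substitution import SubstitutionScenario, apply_scenario, per_child_change
from dietsub.synthdata import CohortSpec, default_composition_table, generate, null_cohort
from oracles import percentiles_linear

SMALL = CohortSpec(n_children=90, strata_sizes=(30, 30, 30))


class TestSpec:
    def test_default_matches_survey_frame(self):
        spec = CohortSpec()
        assert spec.n_children == 676
        assert spec.strata_sizes == (224, 226, 226)
        assert spec.diary_days == 4

    def test_strata_must_sum(self):
        with pytest.raises(ValueError):
            CohortSpec(n_children=10, strata_sizes=(3, 3, 3))

    def test_quantile_order_enforced(self):
        with pytest.raises(ValueError):
            CohortSpec(amount_p25=80.0, amount_median=40.0, amount_p75=75.0)

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            CohortSpec(dairy_share=1.2)

    def test_lognormal_params_reproduce_target_quantiles(self):
        mu, sigma = CohortSpec().lognormal_params
        from scipy.stats import norm

        z = norm.ppf(0.75)
        assert np.exp(mu - sigma * z) == pytest.approx(25.0)
        assert np.exp(mu + sigma * z) == pytest.approx(75.0)
        assert CohortSpec().implied_median == pytest.approx(np.sqrt(25 * 75))


class TestGenerate:
    def test_byte_identical_for_fixed_seed(self):
        a = generate(SMALL, seed=7)
        b = generate(SMALL, seed=7)
        assert a.entries.equals(b.entries)
        assert [c.age_months for c in a.children.values()] == [
            c.age_months for c in b.children.values()
        ]

    def test_different_seeds_differ(self):
        a = generate(SMALL, seed=7)
        b = generate(SMALL, seed=8)
        assert not a.entries.equals(b.entries)

    def test_every_child_has_an_entry(self):
        ds = generate(SMALL, seed=3)
        assert set(ds.entries["child_id"]) == set(ds.children)

    def test_ages_respect_strata(self):
        ds = generate(SMALL, seed=3)
        groups = [c.age_group for c in ds.children.values()]
        assert groups.count("37-48") == 30
        assert groups.count("49-60") == 30
        assert groups.count("61-72") == 30

    def test_zero_consumption_prob_gives_no_soft_drinks(self):
        spec = CohortSpec(
            n_children=60, strata_sizes=(20, 20, 20), consumption_prob=(0.0, 0.0, 0.0)
        )
        ds = generate(spec, seed=4)
        cats = ds.entries["food_id"].map(ds.foods.category_of)
        assert not cats.isin(SOFT_DRINK_CATEGORIES).any()

    def test_consumer_daily_amount_recovered_exactly(self):
        # per-day splits must average back to the drawn mean-daily amount,
        # so consumer grams follow the fitted log-normal with no smearing
        ds = generate(CohortSpec(), seed=21)
        sd_ids = {f for f in ds.foods.food_ids if ds.foods.category_of(f) in SOFT_DRINK_CATEGORIES}
        grams = _consumer_grams(ds, sd_ids).to_numpy()
        mu, sigma = CohortSpec().lognormal_params
        lg = np.log(grams)
        assert lg.mean() == pytest.approx(mu, abs=4 * sigma / np.sqrt(len(lg)))

    def test_amount_quantiles_near_targets_single_cohort(self):
        ds = generate(CohortSpec(), seed=22)
        sd_ids = {f for f in ds.foods.food_ids if ds.foods.category_of(f) in SOFT_DRINK_CATEGORIES}
        grams = _consumer_grams(ds, sd_ids).tolist()
        p25, _, p75 = percentiles_linear(grams)
        assert p25 == pytest.approx(25.0, rel=0.25)
        assert p75 == pytest.approx(75.0, rel=0.25)

    def test_consumer_share_near_target(self):
        ds = generate(CohortSpec(), seed=23)
        out = consumer_summary(ds)
        assert out["All"].percent == pytest.approx(26.33, abs=6.0)

    def test_loads_against_packaged_reference(self):
        ds = generate(SMALL, seed=5)
        dri = load_dri(packaged_dri_path())
        count, pct = prevalence(ds, "calcium", dri)
        assert 0 <= count <= 90 and 0 <= pct <= 100


class TestNullCohort:
    def test_null_scenario_is_exact_fixed_point(self):
        ds = null_cohort(SMALL, seed=9, substitute_food_id="soymilk")
        after = apply_scenario(ds, SubstitutionScenario("model1", "soymilk"))
        deltas = per_child_change(ds, after, "energy")
        assert np.all(np.asarray(deltas) == 0.0)

    def test_null_scenario_zero_discordance(self):
        ds = null_cohort(SMALL, seed=9, substitute_food_id="cow_milk")
        after = apply_scenario(ds, SubstitutionScenario("model2", "cow_milk"))
        dri = load_dri(packaged_dri_path())
        from dietsub.adequacy import inadequacy_flags

        before_flags = inadequacy_flags(ds, "calcium", dri)
        after_flags = inadequacy_flags(after, "calcium", dri)
        res = mcnemar(before_flags.to_numpy(), after_flags.to_numpy())
        assert res.n_effective == 0 and res.p_value == 1.0

    def test_null_scenario_wilcoxon_degenerate(self):
        ds = null_cohort(SMALL, seed=9)
        after = apply_scenario(ds, SubstitutionScenario("model1", "soymilk"))
        x = ds.intake_frame()["energy"].to_numpy()
        y = after.intake_frame()["energy"].to_numpy()
        res = wilcoxon_signed_rank(x, y)
        assert res.p_value == 1.0 and res.n_effective == 0

    def test_null_drink_present_only_where_soft_drinks_were(self):
        base = generate(SMALL, seed=9, foods=None)
        ds = null_cohort(SMALL, seed=9)
        cats = base.entries["food_id"].map(base.foods.category_of)
        n_sd = int(cats.isin(SOFT_DRINK_CATEGORIES).sum())
        assert int((ds.entries["food_id"] == "null_drink").sum()) == n_sd
        # amounts untouched
        assert np.allclose(
            ds.entries["amount_g"].to_numpy(), base.entries["amount_g"].to_numpy()
        )


class TestRecovery:
    """Multi-seed marginal recovery at reduced replication (the full
    500-seed version lives in the acceptance suite)."""

    def test_consumer_share_unbiased_over_seeds(self):
        spec = CohortSpec()
        shares = []
        for seed in range(40):
            ds = generate(spec, seed=seed)
            out = consumer_summary(ds)
            shares.append(out["All"].n_consumers / out["All"].n_total)
        target = np.dot(spec.consumption_prob, spec.strata_sizes) / spec.n_children
        se = np.sqrt(target * (1 - target) / spec.n_children / 40)
        assert np.mean(shares) == pytest.approx(target, abs=4 * se)

    def test_dairy_share_unbiased_over_seeds(self):
        spec = CohortSpec()
        num = den = 0
        for seed in range(30):
            ds = generate(spec, seed=seed)
            den += consumer_summary(ds)["All"].n_consumers
            num += consumer_summary(ds, dairy_only=True)["All"].n_consumers
        se = np.sqrt(spec.dairy_share * (1 - spec.dairy_share) / den)
        assert num / den == pytest.approx(spec.dairy_share, abs=4 * se)
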