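import numpy as np
import pandas as pd
import pytest

from bevmod import (
    MILK_NFS_PER_CUP,
    NUTRIENTS,
    ScenarioConfig,
    ScenarioError,
    add_milk,
    daily_totals,
    daily_totals_frame,
    isocaloric_replace,
    lookup_nutrients_frame,
)
from bevmod.scenarios import apply_replacement_to_items


def _subjects(n=2, age=3):
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": age,
            "gender": "male",
            "ethnicity": "non_hispanic_white",
            "pir_category": ">1.85",
            "weight": 1.0,
            "stratum": [i % 2 for i in range(n)] if n >= 4 else 0,
            "psu": [i % 2 for i in range(n)],
        }
    )


def _items(reference, rows):
    """rows: (subject_id, occasion, food_code, grams)."""
    df = pd.DataFrame(rows, columns=["subject_id", "occasion", "food_code", "grams"])
    df["wweia_code"] = reference.loc[df["food_code"], "wweia_code"].to_numpy()
    nutr = lookup_nutrients_frame(df["food_code"], df["grams"], reference)
    return pd.concat([df, nutr], axis=1)


class TestDailyTotals:
    def test_no_items_zero_vector(self, reference):
        empty = pd.DataFrame(columns=["subject_id", *NUTRIENTS])
        assert np.all(daily_totals(empty).values == 0)

    def test_single_item_identity(self, reference):
        items = _items(reference, [("S0", "lunch", "92410310", 200.0)])
        v = daily_totals(items)
        assert v["energy"] == pytest.approx(82.0)

    def test_two_items_componentwise_sum(self, reference):
        items = _items(
            reference,
            [("S0", "lunch", "92410310", 200.0), ("S0", "dinner", "64100100", 100.0)],
        )
        v = daily_totals(items)
        parts = [daily_totals(items.iloc[[i]]) for i in range(2)]
        assert v.isclose(parts[0] + parts[1], atol=1e-12)

    def test_multiple_subjects_rejected(self, reference):
        items = _items(
            reference,
            [("S0", "lunch", "92410310", 100.0), ("S1", "lunch", "92410310", 100.0)],
        )
        with pytest.raises(ScenarioError):
            daily_totals(items)

    def test_frame_gives_zero_rows_for_itemless_subjects(self, reference):
        subjects = _subjects(2)
        items = _items(reference, [("S0", "lunch", "92410310", 100.0)])
        totals = daily_totals_frame(items, subjects)
        assert totals.loc["S1"].sum() == 0.0


class TestAddMilk:
    def test_zero_cups_identity(self, small_dataset):
        subjects, items = small_dataset
        res = add_milk(subjects, items, ScenarioConfig(scenario="add_milk", cups_added=0.0))
        pd.testing.assert_frame_equal(res.baseline, res.adjusted)

    def test_delta_is_exactly_one_cup_for_every_subject(self, small_dataset):
        subjects, items = small_dataset
        res = add_milk(subjects, items)
        delta = res.adjusted - res.baseline
        assert np.allclose(delta.to_numpy(), MILK_NFS_PER_CUP.values, atol=1e-9)

    def test_population_mean_shift_equals_per_cup(self, small_dataset):
        # weights cancel: adjusted mean − baseline mean = per-cup vector
        from bevmod import SurveyDesign, population_ratio_mean

        subjects, items = small_dataset
        res = add_milk(subjects, items)
        design = res.design()
        for nut in ("calcium", "vitamin_d", "fiber"):
            b = population_ratio_mean(res.baseline[nut], design).point
            a = population_ratio_mean(res.adjusted[nut], design).point
            assert a - b == pytest.approx(MILK_NFS_PER_CUP[nut], abs=1e-9)

    def test_age_1_excluded_by_default(self, small_dataset):
        subjects, items = small_dataset
        res = add_milk(subjects, items)
        assert set(res.subjects["age"]) == {2, 3, 4, 5}

    def test_paired_tests_flag_constant_shift_as_degenerate(self, small_dataset):
        subjects, items = small_dataset
        tests = add_milk(subjects, items).paired_tests().set_index("nutrient")
        assert tests.loc["calcium", "degenerate"]
        assert tests.loc["fiber", "mean_difference"] == 0.0


class TestIsocaloricReplace:
    def test_single_lunch_soft_drink_becomes_one_cup(self, reference):
        subjects = _subjects(2)
        grams = 100.0 * 122.0 / 41.0  # cola delivering exactly 122 kcal
        items = _items(
            reference,
            [
                ("S0", "lunch", "92410310", grams),
                ("S0", "breakfast", "57123000", 50.0),
                ("S1", "breakfast", "57123000", 50.0),
            ],
        )
        res = isocaloric_replace(subjects, items)
        assert res.milk_cups_added["S0"] == pytest.approx(1.0)
        assert res.milk_grams_added["S0"] == pytest.approx(225.0)
        assert res.n_items_replaced["S0"] == 1
        assert res.adjusted.loc["S0", "energy"] == pytest.approx(
            res.baseline.loc["S0", "energy"], abs=1e-9
        )
        assert res.adjusted.loc["S0", "calcium"] == pytest.approx(
            res.baseline.loc["S0", "calcium"] - grams * 0.02 + 290.0
        )

    def test_no_replaceable_items_unchanged(self, reference):
        subjects = _subjects(1)
        items = _items(
            reference,
            [("S0", "breakfast", "92410310", 100.0), ("S0", "lunch", "11100000", 225.0)],
        )
        res = isocaloric_replace(subjects, items)
        pd.testing.assert_frame_equal(res.baseline, res.adjusted)
        assert res.milk_cups_added["S0"] == 0.0

    def test_energy_conserved_per_subject(self, small_dataset):
        subjects, items = small_dataset
        res = isocaloric_replace(subjects, items)
        diff = (res.adjusted["energy"] - res.baseline["energy"]).abs()
        assert diff.max() <= 1e-9

    def test_direction_of_nutrient_shifts(self, small_dataset):
        # restricting the replaced set to sugar-rich, micronutrient-poor
        # beverages (SSB and caloric coffee/tea), milk strictly lowers the
        # sugars and strictly raises its signature micronutrients
        subjects, items = small_dataset
        config = ScenarioConfig(
            scenario="isocaloric_replace",
            replaced_categories={"cb"},
            exempt_juice=True,
        )
        res = isocaloric_replace(subjects, items, config)
        moved = res.milk_cups_added > 0
        assert moved.any()
        delta = (res.adjusted - res.baseline).loc[moved]
        assert (delta["added_sugars"] < 0).all()
        assert (delta["total_sugars"] < 0).all()
        assert (delta["calcium"] > 0).all()
        assert (delta["vitamin_d"] > 0).all()
        assert (delta["vitamin_b12"] > 0).all()
        assert (delta["protein"] > 0).all()

    def test_default_replacement_never_raises_added_sugars(self, small_dataset):
        subjects, items = small_dataset
        res = isocaloric_replace(subjects, items)
        delta = res.adjusted["added_sugars"] - res.baseline["added_sugars"]
        assert (delta <= 1e-12).all()

    def test_idempotent(self, small_dataset):
        subjects, items = small_dataset
        config = ScenarioConfig(scenario="isocaloric_replace")
        once = apply_replacement_to_items(items, config)
        res2 = isocaloric_replace(subjects, once, config)
        assert (res2.milk_cups_added == 0).all()
        pd.testing.assert_frame_equal(res2.baseline, res2.adjusted)

    def test_enlarging_replaced_set_never_decreases_milk(self, small_dataset):
        subjects, items = small_dataset
        narrow = ScenarioConfig(
            scenario="isocaloric_replace", replaced_categories={"ssb"}
        )
        wide = ScenarioConfig(
            scenario="isocaloric_replace",
            replaced_categories={"ssb", "cb", "milk_substitutes"},
        )
        g_narrow = isocaloric_replace(subjects, items, narrow).milk_grams_added
        g_wide = isocaloric_replace(subjects, items, wide).milk_grams_added
        assert (g_wide >= g_narrow - 1e-12).all()

    def test_negative_energy_rejected(self, reference):
        subjects = _subjects(1)
        items = _items(reference, [("S0", "lunch", "92410310", 100.0)])
        items.loc[0, "energy"] = -5.0
        with pytest.raises(ScenarioError):
            isocaloric_replace(subjects, items)

    def test_mean_cups_replacers_at_least_all(self, small_dataset):
        subjects, items = small_dataset
        res = isocaloric_replace(subjects, items)
        assert (
            res.mean_cups_added("replacers").point
            >= res.mean_cups_added("all").point
        )
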