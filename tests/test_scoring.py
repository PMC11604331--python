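"""Point allocation, special rules, classification and engine properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriscope import (
    ScoreFlags,
    classify,
    component_points,
    detect_red_meat,
    detect_sweeteners,
    negative_points,
    positive_points,
    score_record,
)

CLASS_ORDER = "ABCDE"


def brute_force_points(value, grid, convention="strict"):
    """Independent oracle: points of the highest cutoff passed by value."""
    crossed = sum(
        1
        for c in grid.cutoffs
        if value > c or (convention == "inclusive" and value == c)
    )
    return 0 if crossed == 0 else grid.points[crossed - 1]


class TestComponentPoints:
    def test_zero_earns_zero_on_every_grid(self, scheme):
        for cat in scheme.categories.values():
            for grid in cat.grids.values():
                assert component_points(0.0, grid) == 0

    def test_negative_value_rejected(self, scheme):
        grid = scheme.category("general_solid").grids["sugars"]
        with pytest.raises(ValueError, match="negative"):
            component_points(-0.1, grid)

    def test_transcribed_sugar_grid_at_13_5_g(self, scheme):
        grid = scheme.category("general_solid").grids["sugars"]
        # 13.5 g sits between the 10 g and 14 g cutoffs under both conventions
        assert component_points(13.5, grid, "strict") == 3
        assert component_points(13.5, grid, "inclusive") == 3

    def test_sugar_17_vs_13_5_differs_by_two_under_inclusive_reading(self, scheme):
        # the worked breakfast-cereal example: 17 -> 13.5 g per 100 g sugar
        # loses two points when a value on a cutoff already earns its points
        grid = scheme.category("general_solid").grids["sugars"]
        diff = component_points(17, grid, "inclusive") - component_points(
            13.5, grid, "inclusive"
        )
        assert diff == 2
        # under the strictly-greater reading the same change is one point
        assert component_points(17, grid) - component_points(13.5, grid) == 1

    @pytest.mark.parametrize("convention", ["strict", "inclusive"])
    def test_agrees_with_brute_force_on_random_values(self, scheme, convention):
        rng = np.random.default_rng(42)
        for cat in scheme.categories.values():
            for grid in cat.grids.values():
                hi = grid.cutoffs[-1] * 1.5
                values = np.concatenate(
                    [rng.uniform(0, hi, 400), np.array(grid.cutoffs)]
                )
                for v in values:
                    assert component_points(float(v), grid, convention) == (
                        brute_force_points(float(v), grid, convention)
                    )

    def test_points_non_decreasing_in_value(self, scheme):
        grid = scheme.category("general_solid").grids["salt"]
        values = np.linspace(0, 5, 200)
        pts = [component_points(float(v), grid) for v in values]
        assert pts == sorted(pts)


class TestNegativePoints:
    def test_all_zero_composition_scores_zero(self, scheme, make_record):
        rec = make_record(energy_kj=0, sugars_g=0, sfa_g=0, salt_g=0)
        n, _ = negative_points(rec, scheme, "general_solid")
        assert n == 0

    def test_sum_equals_componentwise_points(self, scheme, make_record):
        rec = make_record(energy_kj=1400, sugars_g=22, sfa_g=3.2, salt_g=1.1)
        grids = scheme.category("general_solid").grids
        expected = (
            brute_force_points(1400, grids["energy"])
            + brute_force_points(22, grids["sugars"])
            + brute_force_points(3.2, grids["sfa"])
            + brute_force_points(1.1, grids["salt"])
        )
        n, parts = negative_points(rec, scheme, "general_solid")
        assert n == expected == sum(parts.values())

    def test_fats_record_without_total_fat_errors(self, scheme, make_record):
        rec = make_record(food_group="fats_and_oils", total_fat_g=None)
        with pytest.raises(ValueError, match="total fat"):
            negative_points(rec, scheme, "fats_oils_nuts_seeds")

    def test_fats_use_sfa_to_fat_ratio(self, scheme, make_record):
        rec = make_record(
            food_group="fats_and_oils", sfa_g=30.0, total_fat_g=100.0,
            energy_kj=0, sugars_g=0, salt_g=0,
        )
        _, parts = negative_points(rec, scheme, "fats_oils_nuts_seeds")
        grids = scheme.category("fats_oils_nuts_seeds").grids
        assert parts["sfa_fat_ratio"] == brute_force_points(30.0, grids["sfa_fat_ratio"])

    def test_sweetener_penalty_only_for_beverages(self, scheme, make_record):
        rec = make_record(food_group="soft_drinks", energy_kj=100, sugars_g=5,
                          sfa_g=0, salt_g=0)
        flags = ScoreFlags(has_sweeteners=True)
        n_bev, parts = negative_points(rec, scheme, "beverage", flags)
        assert parts["sweeteners"] == scheme.rules.sweetener_points
        n_solid, solid_parts = negative_points(rec, scheme, "general_solid", flags)
        assert "sweeteners" not in solid_parts


class TestPositivePoints:
    def test_zero_favourables_score_zero(self, scheme, make_record):
        rec = make_record(protein_g=0, fibre_g=0, fvl_pct=0)
        p, counted, _ = positive_points(rec, 0, scheme, "general_solid")
        assert p == 0 and counted

    def test_unimputed_fibre_is_a_precondition_failure(self, scheme, make_record):
        rec = make_record(fibre_g=None)
        with pytest.raises(ValueError, match="fibre"):
            positive_points(rec, 0, scheme, "general_solid")

    def test_red_meat_protein_capped(self, scheme, make_record):
        rec = make_record(protein_g=25.0)
        p_plain, _, parts_plain = positive_points(rec, 0, scheme, "general_solid")
        p_red, _, parts_red = positive_points(
            rec, 0, scheme, "general_solid", ScoreFlags(is_red_meat=True)
        )
        assert parts_red["protein"] == scheme.rules.red_meat_protein_cap
        assert parts_plain["protein"] > parts_red["protein"]
        assert p_red <= p_plain  # cap monotonicity

    def test_protein_dropped_above_negative_threshold(self, scheme, make_record):
        rec = make_record(protein_g=10.0, fibre_g=0, fvl_pct=0)
        _, counted_low, _ = positive_points(rec, 10, scheme, "general_solid")
        _, counted_high, _ = positive_points(rec, 11, scheme, "general_solid")
        assert counted_low and not counted_high

    def test_max_fvl_points_exempt_from_protein_drop(self, scheme, make_record):
        rec = make_record(protein_g=10.0, fibre_g=0, fvl_pct=95.0)
        _, counted, parts = positive_points(rec, 20, scheme, "general_solid")
        assert parts["fvl"] == 5 and counted

    def test_cheese_protein_always_counted(self, scheme, make_record):
        rec = make_record(food_group="cheeses", protein_g=24.0, fibre_g=0, fvl_pct=0)
        _, counted, _ = positive_points(
            rec, 20, scheme, "general_solid", ScoreFlags(is_cheese=True)
        )
        assert counted

    def test_beverage_protein_never_dropped(self, scheme, make_record):
        rec = make_record(food_group="soft_drinks", protein_g=3.5, fibre_g=0, fvl_pct=0)
        _, counted, _ = positive_points(rec, 25, scheme, "beverage")
        assert counted


class TestClassify:
    @pytest.mark.parametrize(
        "final_sum,letter",
        [(0, "A"), (1, "B"), (2, "B"), (3, "C"), (10, "C"), (11, "D"), (19, "E")],
    )
    def test_general_solid_anchor_intervals(self, scheme, final_sum, letter):
        assert classify(final_sum, "general_solid", scheme) == letter

    def test_non_integer_sum_rejected(self, scheme):
        with pytest.raises(ValueError, match="integer"):
            classify(2.5, "general_solid", scheme)

    def test_letters_non_decreasing_over_attainable_sums(self, scheme):
        for category in scheme.categories:
            letters = [classify(s, category, scheme) for s in range(-30, 60)]
            indices = [CLASS_ORDER.index(c) for c in letters]
            assert indices == sorted(indices)


class TestKeywordDetection:
    def test_sweetener_in_ingredients_detected(self, scheme):
        assert detect_sweeteners("cola light", "water, aspartame, e150d",
                                 scheme.sweetener_keywords)

    def test_empty_texts_never_match(self, scheme):
        assert not detect_red_meat("", "", scheme.red_meat_keywords)
        assert not detect_sweeteners("", "", scheme.sweetener_keywords)

    def test_empty_keyword_list_never_matches(self):
        assert not detect_red_meat("beef burger", "beef", [])

    def test_matching_is_case_insensitive_and_folds_diacritics(self, scheme):
        assert detect_red_meat("Boeuf Bourguignon", "BŒUF, carottes", ["boeuf"])
        assert detect_sweeteners("Thé glacé", "STÉVIA extract", ["stevia"])


class TestScoreRecord:
    def test_mineral_water_is_class_a(self, scheme, taxonomy, make_record):
        rec = make_record(
            food_group="soft_drinks", is_water=True,
            energy_kj=0, sugars_g=0, sfa_g=0, salt_g=0, protein_g=0,
            fibre_g=0, fvl_pct=0,
        )
        assert score_record(rec, scheme, taxonomy).nutri_class == "A"

    def test_non_water_beverage_never_class_a(self, scheme, taxonomy, make_record):
        rng = np.random.default_rng(7)
        for _ in range(200):
            rec = make_record(
                food_group="soft_drinks",
                energy_kj=float(rng.uniform(0, 400)),
                sugars_g=float(rng.uniform(0, 15)),
                sfa_g=float(rng.uniform(0, 2)),
                salt_g=float(rng.uniform(0, 0.5)),
                protein_g=float(rng.uniform(0, 4)),
                fibre_g=float(rng.uniform(0, 2)),
                fvl_pct=float(rng.uniform(0, 100)),
            )
            assert score_record(rec, scheme, taxonomy).nutri_class in "BCDE"

    def test_general_solid_sum_two_is_class_b(self, scheme, taxonomy, make_record):
        # composition engineered to a final sum of exactly 2
        rec = make_record(
            energy_kj=700, sugars_g=0, sfa_g=0, salt_g=0,
            protein_g=0, fibre_g=0, fvl_pct=0,
        )
        result = score_record(rec, scheme, taxonomy)
        assert result.final_sum == 2
        assert result.nutri_class == "B"

    def test_scoring_is_pure(self, scheme, taxonomy, make_record):
        rec = make_record(ingredients="oats, aspartame")
        assert score_record(rec, scheme, taxonomy) == score_record(
            rec, scheme, taxonomy
        )

    def test_final_sum_is_negative_minus_applied_positive(
        self, scheme, taxonomy, make_record
    ):
        res = score_record(make_record(), scheme, taxonomy)
        assert res.final_sum == res.negative_sum - res.positive_sum


def _record(**comp):
    from nutriscope import FoodRecord

    return FoodRecord(
        ean="1", food_group="breakfast_cereals", year=2018, **comp
    )


@st.composite
def compositions(draw):
    return dict(
        energy_kj=draw(st.floats(0, 3800)),
        sugars_g=draw(st.floats(0, 90)),
        sfa_g=draw(st.floats(0, 40)),
        salt_g=draw(st.floats(0, 5)),
        protein_g=draw(st.floats(0, 30)),
        fibre_g=draw(st.floats(0, 12)),
        fvl_pct=draw(st.floats(0, 100)),
    )


class TestMonotonicity:
    """Raising an unfavourable component never improves the final sum or
    class; raising a favourable one never worsens them."""

    @settings(max_examples=150, derandomize=True)
    @given(comp=compositions(), bump=st.floats(0.01, 10))
    @pytest.mark.parametrize("component", ["sugars_g", "sfa_g", "salt_g", "energy_kj"])
    def test_unfavourable_increase_never_improves(
        self, scheme, taxonomy, comp, bump, component
    ):
        base = _record(**comp)
        factor = 40 if component == "energy_kj" else 1
        bumped_value = comp[component] + bump * factor
        if component == "sugars_g":
            bumped_value = min(bumped_value, 100.0)
        bumped = _record(**{**comp, component: bumped_value})
        r0 = score_record(base, scheme, taxonomy)
        r1 = score_record(bumped, scheme, taxonomy)
        assert r1.final_sum >= r0.final_sum
        assert CLASS_ORDER.index(r1.nutri_class) >= CLASS_ORDER.index(r0.nutri_class)

    @settings(max_examples=150, derandomize=True)
    @given(comp=compositions(), bump=st.floats(0.01, 10))
    @pytest.mark.parametrize("component", ["protein_g", "fibre_g", "fvl_pct"])
    def test_favourable_increase_never_worsens(
        self, scheme, taxonomy, comp, bump, component
    ):
        base = _record(**comp)
        bumped_value = comp[component] + bump
        if component == "fvl_pct":
            bumped_value = min(bumped_value, 100.0)
        bumped = _record(**{**comp, component: bumped_value})
        r0 = score_record(base, scheme, taxonomy)
        r1 = score_record(bumped, scheme, taxonomy)
        assert r1.final_sum <= r0.final_sum
        assert CLASS_ORDER.index(r1.nutri_class) <= CLASS_ORDER.index(r0.nutri_class)
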