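"""Stage-2 recipe engine: measures, matching, nutrient summation."""

import itertools

import pytest

from nutridbk.fct import CompiledFCT, FoodItem, Source
from nutridbk.nutrients import NutrientVector
from nutridbk.recipes import (
    IngredientLine,
    MeasureConversionTable,
    Recipe,
    RecipeError,
    UnmatchedIngredientError,
    UnresolvableUnitError,
    compute_recipe_nutrients,
    match_ingredient,
    resolve_grams,
    resolve_recipe,
)
from nutridbk.retention import RetentionFactor, RetentionTable


def _item(code, source=Source.IFCT2017, **nutrients):
    return FoodItem(food_code=code, name=code, source=source, nutrients=NutrientVector(**nutrients))


def _fct(*items):
    return CompiledFCT.from_items(items)


def _line(name, qty, unit, code=None, grams=None):
    return IngredientLine(raw_name=name, quantity=qty, unit=unit, matched_code=code, resolved_grams=grams)


class TestResolveGrams:
    def test_grams_pass_through(self):
        assert resolve_grams(_line("x", 100, "g"), MeasureConversionTable()) == 100

    def test_household_measures_via_millilitres_and_density(self):
        table = MeasureConversionTable()
        assert resolve_grams(_line("oil", 1, "tbsp"), table) == pytest.approx(15.0)
        dense = MeasureConversionTable(density_g_per_ml={"OIL": 0.92})
        assert resolve_grams(_line("oil", 2, "tsp", code="OIL"), dense) == pytest.approx(9.2)

    def test_ml_uses_density_and_sprig_uses_gram_equivalent(self):
        table = MeasureConversionTable(density_g_per_ml={"MILK": 1.03})
        assert resolve_grams(_line("milk", 100, "ml", code="MILK"), table) == pytest.approx(103.0)
        assert resolve_grams(_line("curry leaf", 3, "sprig"), table) == pytest.approx(3.0)

    def test_unknown_unit_is_an_error_naming_the_line(self):
        with pytest.raises(UnresolvableUnitError, match="katori.*coriander.*R77"):
            resolve_grams(_line("coriander", 1, "katori"), MeasureConversionTable(), "R77")

    def test_non_positive_measure_equivalents_rejected(self):
        with pytest.raises(RecipeError):
            MeasureConversionTable(volume_ml={"tbsp": 0.0})


class TestMatchIngredient:
    def test_highest_priority_source_wins(self):
        fct = _fct(_item("I1"), _item("U1", Source.UKFCT))
        mapping = {"onion": [(Source.UKFCT, "U1"), (Source.IFCT2017, "I1")]}
        assert match_ingredient("onion", mapping, fct) == "I1"

    def test_falls_back_to_uk_when_national_tables_lack_the_food(self):
        fct = _fct(_item("U1", Source.UKFCT))
        mapping = {"leek": [(Source.IFCT2017, "missing"), (Source.UKFCT, "U1")]}
        assert match_ingredient("leek", mapping, fct) == "U1"

    def test_unmapped_ingredient_raises(self):
        with pytest.raises(UnmatchedIngredientError):
            match_ingredient("mystery", {}, _fct(_item("I1")))

    def test_mapped_code_absent_from_databank_raises(self):
        with pytest.raises(UnmatchedIngredientError, match="ghost"):
            match_ingredient("ghost", {"ghost": [(Source.USDA, "nope")]}, _fct(_item("I1")))


class TestComputeRecipeNutrients:
    def test_single_ingredient_identity_recipe(self):
        x = _item("X", energy_kj=418.4, energy_kcal=100, protein_g=7, iron_mg=3)
        recipe = Recipe("R1", "plain rice", [_line("X", 100, "g", "X", 100.0)], total_weight_g=100)
        out = compute_recipe_nutrients(recipe, _fct(x))
        assert out.per_100g == x.nutrients
        assert out.coverage == 1.0

    def test_hand_computed_two_ingredient_recipe(self):
        a = _item("A", protein_g=10)
        b = _item("B", protein_g=2)
        recipe = Recipe(
            "R2", "dal", [_line("A", 50, "g", "A", 50.0), _line("B", 150, "g", "B", 150.0)],
            total_weight_g=200, n_servings=4,
        )
        out = compute_recipe_nutrients(recipe, _fct(a, b))
        assert out.total["protein_g"] == pytest.approx(8.0)
        assert out.per_100g["protein_g"] == pytest.approx(4.0)
        assert out.per_serving["protein_g"] == pytest.approx(2.0)

    def test_missing_serving_info_flags_and_nulls_per_serving(self):
        recipe = Recipe(
            "R3", "mango pickle", [_line("A", 100, "g", "A", 100.0)],
            category="pickles and preserves",
        )
        out = compute_recipe_nutrients(recipe, _fct(_item("A", sodium_mg=900)))
        assert out.per_serving is None and out.per_serving_missing

    def test_serving_size_used_when_n_servings_absent(self):
        recipe = Recipe(
            "R4", "kheer", [_line("A", 200, "g", "A", 200.0)], serving_size_g=50,
        )
        out = compute_recipe_nutrients(recipe, _fct(_item("A", carb_g=20)))
        # 40 g carb total over 200 g -> 20 per 100 g -> 10 per 50 g serving
        assert out.per_serving["carb_g"] == pytest.approx(10.0)

    def test_total_weight_defaults_to_ingredient_sum_and_override_wins(self):
        fct = _fct(_item("A", fat_g=10))
        base = Recipe("R5", "x", [_line("A", 50, "g", "A", 50.0)])
        assert compute_recipe_nutrients(base, fct).total_weight_g == 50.0
        cooked = Recipe("R5b", "x", [_line("A", 50, "g", "A", 50.0)], total_weight_g=40.0)
        out = compute_recipe_nutrients(cooked, fct)
        assert out.per_100g["fat_g"] == pytest.approx(5.0 * 100 / 40)

    def test_conservation_between_total_and_per_100g(self):
        fct = _fct(_item("A", protein_g=3.3, iron_mg=0.7), _item("B", protein_g=8.1))
        recipe = Recipe(
            "R6", "x", [_line("A", 73.5, "g", "A", 73.5), _line("B", 41.2, "g", "B", 41.2)],
            total_weight_g=101.3,
        )
        out = compute_recipe_nutrients(recipe, fct)
        for f in ("protein_g", "iron_mg"):
            assert out.per_100g[f] * out.total_weight_g / 100 == pytest.approx(
                out.total[f], rel=1e-9
            )

    def test_doubling_everything_doubles_total_but_not_per_100g(self):
        fct = _fct(_item("A", zinc_mg=4.0))
        one = Recipe("R7", "x", [_line("A", 80, "g", "A", 80.0)], total_weight_g=80)
        two = Recipe("R7b", "x", [_line("A", 160, "g", "A", 160.0)], total_weight_g=160)
        o1, o2 = (compute_recipe_nutrients(r, fct) for r in (one, two))
        assert o2.total["zinc_mg"] == pytest.approx(2 * o1.total["zinc_mg"], rel=1e-12)
        assert o2.per_100g["zinc_mg"] == pytest.approx(o1.per_100g["zinc_mg"], rel=1e-12)

    def test_ingredient_order_does_not_matter(self):
        items = [_item(c, iron_mg=i + 0.25, fibre_g=2 * i + 0.1) for i, c in enumerate("ABCD")]
        fct = _fct(*items)
        lines = [_line(c, 10.0 * (i + 1), "g", c, 10.0 * (i + 1)) for i, c in enumerate("ABCD")]
        results = []
        for perm in itertools.permutations(lines):
            r = Recipe("R8", "x", list(perm), total_weight_g=100)
            results.append(compute_recipe_nutrients(r, fct))
        for f in ("iron_mg", "fibre_g"):
            vals = {round(res.per_100g[f], 12) for res in results}
            assert len(vals) == 1

    def test_all_ones_retention_is_identical_to_no_retention(self):
        fct = _fct(_item("A", iron_mg=3, vitc_mg=40, protein_g=5))
        ones = RetentionTable(
            factors={"ID": RetentionFactor("ID", "identity", {f: 1.0 for f in ("iron_mg", "vitc_mg")})},
            assignment={"A": "ID"},
        )
        recipe = Recipe("R9", "x", [_line("A", 100, "g", "A", 100.0)], total_weight_g=100)
        with_ones = compute_recipe_nutrients(recipe, fct, ones)
        without = compute_recipe_nutrients(recipe, fct, None)
        assert with_ones.per_100g == without.per_100g
        assert with_ones.retention_applied and not without.retention_applied

    def test_completeness_flag_set_iff_a_contributing_item_was_null(self):
        fct = _fct(_item("A", iron_mg=2), _item("B", zinc_mg=1))  # B lacks iron, A lacks zinc
        recipe = Recipe(
            "R10", "x", [_line("A", 50, "g", "A", 50.0), _line("B", 50, "g", "B", 50.0)],
            total_weight_g=100,
        )
        out = compute_recipe_nutrients(recipe, fct)
        assert {"iron_mg", "zinc_mg"} <= out.per_100g.incomplete
        assert "protein_g" in out.per_100g.incomplete  # null on both -> still flagged
        assert out.per_100g["protein_g"] is None

    def test_zero_total_weight_and_no_matched_lines_are_errors(self):
        fct = _fct(_item("A", iron_mg=1))
        with pytest.raises(RecipeError, match="total weight"):
            compute_recipe_nutrients(
                Recipe("R11", "x", [_line("A", 1, "g", "A", 1.0)], total_weight_g=0), fct
            )
        with pytest.raises(RecipeError, match="no matched"):
            compute_recipe_nutrients(Recipe("R12", "x", [_line("A", 1, "g")]), fct)

    def test_empty_ingredient_list_rejected_at_construction(self):
        with pytest.raises(RecipeError):
            Recipe("R13", "x", [])

    def test_retention_coverage_counts_assigned_lines_over_all_lines(self):
        fct = _fct(_item("A", iron_mg=1), _item("B", iron_mg=1))
        table = RetentionTable(
            factors={"RF": RetentionFactor("RF", "", {"iron_mg": 0.9})}, assignment={"A": "RF"}
        )
        recipe = Recipe(
            "R14", "x", [_line("A", 50, "g", "A", 50.0), _line("B", 50, "g", "B", 50.0)],
        )
        out = compute_recipe_nutrients(recipe, fct, table)
        assert out.retention_coverage == pytest.approx(0.5)


class TestResolveRecipe:
    def _setup(self):
        fct = _fct(_item("A", iron_mg=1))
        mapping = {"salt": [(Source.IFCT2017, "A")]}
        return fct, mapping, MeasureConversionTable()

    def test_abort_policy_raises_on_unmatched_line(self):
        fct, mapping, table = self._setup()
        recipe = Recipe("R15", "x", [_line("salt", 1, "g"), _line("mystery", 5, "g")])
        with pytest.raises(UnmatchedIngredientError, match="R15"):
            resolve_recipe(recipe, mapping, fct, table, on_unmatched="error")

    def test_permissive_policy_excludes_line_and_lowers_coverage(self):
        fct, mapping, table = self._setup()
        recipe = Recipe("R16", "x", [_line("salt", 1, "g"), _line("mystery", 5, "g")])
        resolved = resolve_recipe(recipe, mapping, fct, table, on_unmatched="exclude")
        out = compute_recipe_nutrients(resolved, fct)
        assert out.coverage == pytest.approx(0.5)
        assert out.total_weight_g == pytest.approx(1.0)  # excluded line carries no weight
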