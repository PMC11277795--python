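"""Compute a recipe's nutrient profile from its ingredient lines (stage 2).

Builds a two-ingredient dal recipe by hand — one ingredient measured in
grams, one as a household tablespoon — resolves the measures to grams,
and prints total, per-100 g and per-serving protein and iron.
"""

from nutridbk import (
    CompiledFCT,
    FoodItem,
    IngredientLine,
    MeasureConversionTable,
    NutrientVector,
    Recipe,
    Source,
    compute_recipe_nutrients,
    resolve_recipe,
)

fct = CompiledFCT.from_items(
    [
        FoodItem("LENTIL", "red lentils, raw", Source.IFCT2017,
                 NutrientVector(protein_g=24.0, iron_mg=7.4, energy_kcal=343, energy_kj=1435.1)),
        FoodItem("GHEE", "clarified butter", Source.IFCT2017,
                 NutrientVector(protein_g=0.0, iron_mg=0.0, fat_g=99.8, energy_kcal=897, energy_kj=3753.0)),
    ]
)
mapping = {
    "red lentils": [(Source.IFCT2017, "LENTIL")],
    "ghee": [(Source.IFCT2017, "GHEE")],
}
recipe = Recipe(
    recipe_code="DAL01",
    english_name="simple dal",
    local_name="dal",
    category="main",
    ingredients=[
        IngredientLine("red lentils", 150, "g"),
        IngredientLine("ghee", 1, "tbsp"),  # 15 ml x density 0.91 g/ml
    ],
    total_weight_g=450,  # cooked weight after adding water
    n_servings=3,
)

table = MeasureConversionTable(density_g_per_ml={"GHEE": 0.91})
resolve_recipe(recipe, mapping, fct, table)
out = compute_recipe_nutrients(recipe, fct)

print(f"resolved ghee line: {recipe.ingredients[1].resolved_grams:.2f} g")
for f in ("protein_g", "iron_mg", "energy_kcal"):
    print(
        f"{f:12s} total={out.total[f]:7.2f}  per 100 g={out.per_100g[f]:6.2f}  "
        f"per serving={out.per_serving[f]:6.2f}"
    )
# Totals are the gram-weighted sums of each ingredient's per-100 g values;
# per-100 g divides by the cooked recipe weight, per-serving by n_servings.
print("ingredient line coverage:", out.coverage)
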