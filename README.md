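# nutridbk

Compile multi-source food composition tables (FCTs) into a single raw-food
databank and turn recipes into nutrient profiles, with a built-in
sensitivity analysis for cooking losses.

Dietary assessment needs a table that converts *foods eaten* into
*nutrients consumed*. National FCTs cover raw foods but rarely composite
dishes, and no single table is complete: newer editions supersede older
ones, and some nutrients (carbohydrates, fibre, biotin — especially for
protein foods) must be borrowed from foreign tables. `nutridbk` is aimed
at nutrition researchers and database builders who need this workflow to
be reproducible: every merge decision, borrowed value and unit conversion
is explicit, configured, and recorded with provenance.

## The method

**Stage 1 — compilation.** Source tables are merged under a strict
priority order (newest national edition → older edition → UK FCT → USDA).
A food present in several tables keeps the highest-priority record whole
(no field mixing). Remaining per-nutrient gaps are filled through a
curated code-to-code mapping into a fallback table, and every value
carries a provenance tag naming its source. Energy uses the FAO factor
pair — 1 kcal = 4.184 kJ and 1 kJ = 0.239 kcal — each direction with its
own printed constant (they are deliberately not mutual inverses).

**Stage 2 — recipe calculation.** Each ingredient line is resolved to
grams (household measures via configured ml equivalents and per-food
density), matched to a compiled food through a curated name mapping
(highest-priority source wins), and summed over the 39-nutrient panel:

    total       = Σᵢ vᵢ · gᵢ / 100
    per_100g    = total · 100 / W
    per_serving = total / n_servings

where `vᵢ` is ingredient *i*'s per-100 g nutrient vector, `gᵢ` its
resolved grams, and `W` the total recipe weight (supplied cooked weight,
or else the raw ingredient sum — no yield factor). Missing nutrient
values are explicit nulls, never zeros; a null contributing to a sum
flags that nutrient's result as incomplete.

**Sensitivity analysis.** Cooking losses are modelled by USDA-style
nutrient retention factors: per cooking-method class, a multiplicative
fraction in [0, 1] for each of 17 covered minerals and vitamins. Each
food gets at most one factor set (its most common cooking method);
unassigned foods keep raw values, so the with/without comparison runs
over identical recipes. Per nutrient, the paired comparison reports both
medians, the mean decrease, and a two-sided Wilcoxon signed-rank p-value
(zeros discarded, ties mid-ranked, exact permutation null for n ≤ 25,
normal approximation with continuity correction beyond).

## Worked example

`examples/02_recipe_nutrients.py` builds a two-ingredient dal (150 g red
lentils + 1 tbsp ghee at density 0.91 g/ml, cooked weight 450 g, 3
servings) and prints:

```
resolved ghee line: 13.65 g
protein_g    total=  36.00  per 100 g=  8.00  per serving= 12.00
iron_mg      total=  11.10  per 100 g=  2.47  per serving=  3.70
energy_kcal  total= 636.94  per 100 g=141.54  per serving=212.31
ingredient line coverage: 1.0
```

The tablespoon resolves to 15 ml × 0.91 g/ml = 13.65 g; lentils
contribute 1.5 × 24 g protein and ghee none, so the dish holds 36 g
protein — 8 g per 100 g of cooked dish, 12 g per serving. Coverage 1.0
means every ingredient line matched a compiled food.

`examples/01_compile_databank.py` shows stage-1 merging and a borrowed
value's provenance; `examples/03_retention_sensitivity.py` runs the full
with/without-retention comparison on a generated databank.

The same workflow is scriptable from a shell:

```bash
nutridbk generate-fixtures --seed 1 --out fixture/
nutridbk compile --fct fixture/ --gapfill-mapping fixture/gapfill_mapping.csv --out compiled/
nutridbk calculate --fct compiled/ --recipes fixture/recipes.csv \
    --mapping fixture/ingredient_mapping.csv --permissive --out nutrients/
nutridbk compare-retention --fct compiled/ --recipes fixture/recipes.csv \
    --mapping fixture/ingredient_mapping.csv \
    --retention fixture/retention_factors.csv \
    --retention-assignment fixture/retention_assignment.csv \
    --permissive --out comparison/
```

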