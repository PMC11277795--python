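"""Recipe nutrient calculation: stage 2 of the databank.

A recipe is a list of quantified ingredient lines (grams, millilitres,
or household measures), a total weight, and serving information.  Each
line is resolved to grams, matched through a curated name mapping to a
compiled food item (highest-priority source wins), optionally adjusted
for cooking losses, and the per-100 g nutrient contributions are summed:

    total     = sum_i  v_i * g_i / 100
    per_100g  = total * 100 / W
    per_serving = total / n_servings   (or per_100g * serving_size / 100)

where ``v_i`` is ingredient i's per-100 g nutrient vector (after
retention, when enabled), ``g_i`` its resolved grams, and ``W`` the
total recipe weight — the supplied cooked weight if given, otherwise the
sum of raw ingredient grams (no yield factor is applied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fct import DEFAULT_SOURCE_PRIORITY, CompiledFCT, Source, source_rank
from .nutrients import NUTRIENT_FIELDS, NullPolicy, NutrientVector, nsum, scale
from .retention import RetentionTable, apply_retention, assign_retention

logger = logging.getLogger(__name__)

__all__ = [
    "MeasureConversionTable",
    "IngredientLine",
    "Recipe",
    "RecipeNutrients",
    "RecipeError",
    "UnresolvableUnitError",
    "UnmatchedIngredientError",
    "resolve_grams",
    "match_ingredient",
    "resolve_recipe",
    "compute_recipe_nutrients",
    "compute_all",
    "results_to_frame",
    "load_recipes",
    "load_ingredient_mapping",
]


class RecipeError(ValueError):
    """A recipe violates the computation contract."""


class UnresolvableUnitError(RecipeError):
    """An ingredient line uses a unit absent from the conversion table."""


class UnmatchedIngredientError(RecipeError):
    """An ingredient has no curated mapping into the compiled databank."""


@dataclass(frozen=True)
class MeasureConversionTable:
    """Household-measure and volume conversions to grams.

    Volume units map to millilitres and are then converted to grams with
    a per-food density (g/ml, default 1.0); mass-like measures (sprig)
    map directly to grams.  All values come from configuration — the
    defaults are tbsp = 15 ml, tsp = 5 ml, sprig = 1 g.
    """

    volume_ml: Mapping[str, float] = dc_field(default_factory=lambda: {"tbsp": 15.0, "tsp": 5.0})
    mass_g: Mapping[str, float] = dc_field(default_factory=lambda: {"sprig": 1.0})
    default_density_g_per_ml: float = 1.0
    density_g_per_ml: Mapping[str, float] = dc_field(default_factory=dict)  # per food_code

    def __post_init__(self) -> None:
        for table in (self.volume_ml, self.mass_g):
            bad = {u: v for u, v in table.items() if v <= 0}
            if bad:
                raise RecipeError(f"non-positive measure equivalents: {bad}")
        if self.default_density_g_per_ml <= 0:
            raise RecipeError("default density must be > 0")

    def density(self, food_code: str | None) -> float:
        if food_code is not None and food_code in self.density_g_per_ml:
            return self.density_g_per_ml[food_code]
        return self.default_density_g_per_ml


@dataclass
class IngredientLine:
    """One quantified ingredient of a recipe."""

    raw_name: str
    quantity: float
    unit: str
    matched_code: str | None = None
    resolved_grams: float | None = None

    def __post_init__(self) -> None:
        if self.quantity <= 0:
            raise RecipeError(f"ingredient {self.raw_name!r}: quantity must be > 0")


@dataclass
class Recipe:
    """A composite dish: ingredients plus weight and serving metadata."""

    recipe_code: str
    english_name: str
    ingredients: list[IngredientLine]
    local_name: str = ""
    category: str = ""
    total_weight_g: float | None = None
    n_servings: int | None = None
    serving_size_g: float | None = None

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise RecipeError(f"recipe {self.recipe_code}: no ingredients")
        if self.n_servings is not None and self.n_servings <= 0:
            raise RecipeError(f"recipe {self.recipe_code}: n_servings must be positive")


@dataclass
class RecipeNutrients:
    """Computed nutrient profile of one recipe."""

    recipe_code: str
    total: NutrientVector
    per_100g: NutrientVector
    per_serving: NutrientVector | None
    total_weight_g: float
    retention_applied: bool
    coverage: float  # fraction of ingredient lines matched to a food item
    retention_coverage: float  # fraction of lines with a retention assignment
    per_serving_missing: bool = False


def resolve_grams(
    line: IngredientLine, table: MeasureConversionTable, recipe_code: str = ""
) -> float:
    """Grams of an ingredient line: g passes through, ml and household
    measures convert via millilitres and density, sprig via its gram
    equivalent."""
    unit = line.unit.lower().strip()
    if unit == "g":
        return line.quantity
    if unit == "ml":
        return line.quantity * table.density(line.matched_code)
    if unit in table.volume_ml:
        return line.quantity * table.volume_ml[unit] * table.density(line.matched_code)
    if unit in table.mass_g:
        return line.quantity * table.mass_g[unit]
    where = f" in recipe {recipe_code}" if recipe_code else ""
    raise UnresolvableUnitError(
        f"unit {line.unit!r} for ingredient {line.raw_name!r}{where} "
        "is not in the measure conversion table"
    )


def match_ingredient(
    raw_name: str,
    mapping: Mapping[str, Sequence[tuple[Source, str]]],
    fct: CompiledFCT,
    priority: Sequence[Source] = DEFAULT_SOURCE_PRIORITY,
) -> str:
    """Resolve an ingredient name to a compiled food code.

    The curated mapping lists candidate (source, code) pairs; the
    highest-priority source whose food is present in the databank wins
    (national tables before the UK table before USDA).
    """
    candidates = mapping.get(raw_name)
    if not candidates:
        raise UnmatchedIngredientError(f"no mapping entry for ingredient {raw_name!r}")
    for src, code in sorted(candidates, key=lambda sc: source_rank(sc[0], priority)):
        if code in fct:
            return code
    raise UnmatchedIngredientError(
        f"ingredient {raw_name!r}: no mapped code present in the compiled databank "
        f"(candidates: {[(Source(s).value, c) for s, c in candidates]})"
    )


def resolve_recipe(
    recipe: Recipe,
    mapping: Mapping[str, Sequence[tuple[Source, str]]],
    fct: CompiledFCT,
    table: MeasureConversionTable,
    *,
    on_unmatched: str = "error",
) -> Recipe:
    """Match and gram-resolve every ingredient line in place.

    ``on_unmatched="error"`` aborts on the first unmatchable line (the
    default: silent undercounting is the worse failure);
    ``"exclude"`` leaves the line unmatched so that computation skips it
    and reports reduced coverage.
    """
    if on_unmatched not in ("error", "exclude"):
        raise ValueError(f"unknown on_unmatched policy {on_unmatched!r}")
    for line in recipe.ingredients:
        try:
            line.matched_code = match_ingredient(line.raw_name, mapping, fct)
        except UnmatchedIngredientError as exc:
            if on_unmatched == "error":
                raise UnmatchedIngredientError(f"recipe {recipe.recipe_code}: {exc}") from exc
            logger.warning("recipe %s: excluding line %r (%s)", recipe.recipe_code, line.raw_name, exc)
            line.matched_code = None
        line.resolved_grams = resolve_grams(line, table, recipe.recipe_code)
    return recipe


def compute_recipe_nutrients(
    recipe: Recipe,
    fct: CompiledFCT,
    retention: RetentionTable | None = None,
    *,
    null_policy: NullPolicy | str = NullPolicy.ZERO_FLAG,
) -> RecipeNutrients:
    """Sum ingredient contributions into total, per-100 g and per-serving
    vectors.

    Lines must already be gram-resolved (see :func:`resolve_recipe`);
    unmatched lines are excluded and lower ``coverage``.  When a
    retention table is supplied, each matched food's vector is first
    multiplied by its assigned retention factors (foods without an
    assignment keep raw values).  Per-serving uses ``n_servings`` when
    present, else ``serving_size_g``, else is null and flagged.
    """
    lines = recipe.ingredients
    matched = [ln for ln in lines if ln.matched_code is not None and ln.matched_code in fct]
    if not matched:
        raise RecipeError(f"recipe {recipe.recipe_code}: no matched ingredient lines")
    contributions = []
    n_assigned = 0
    for ln in matched:
        if ln.resolved_grams is None:
            raise RecipeError(
                f"recipe {recipe.recipe_code}: line {ln.raw_name!r} not gram-resolved"
            )
        vec = fct[ln.matched_code].nutrients
        if retention is not None:
            rf = assign_retention(ln.matched_code, retention)
            if rf is not None:
                vec = apply_retention(vec, rf)
                n_assigned += 1
        contributions.append(scale(vec, ln.resolved_grams / 100.0))
    total = nsum(contributions, null_policy)
    total_weight = recipe.total_weight_g
    if total_weight is None:
        total_weight = sum(ln.resolved_grams for ln in matched)
    if total_weight <= 0:
        raise RecipeError(f"recipe {recipe.recipe_code}: non-positive total weight {total_weight}")
    per_100g = scale(total, 100.0 / total_weight)
    per_serving: NutrientVector | None
    missing = False
    if recipe.n_servings is not None:
        per_serving = scale(total, 1.0 / recipe.n_servings)
    elif recipe.serving_size_g is not None:
        per_serving = scale(per_100g, recipe.serving_size_g / 100.0)
    else:
        per_serving = None
        missing = True
        logger.info("recipe %s: no serving information; per-serving values omitted", recipe.recipe_code)
    return RecipeNutrients(
        recipe_code=recipe.recipe_code,
        total=total,
        per_100g=per_100g,
        per_serving=per_serving,
        total_weight_g=total_weight,
        retention_applied=retention is not None,
        coverage=len(matched) / len(lines),
        retention_coverage=(n_assigned / len(lines)) if retention is not None else 0.0,
        per_serving_missing=missing,
    )


def compute_all(
    recipes: Iterable[Recipe],
    fct: CompiledFCT,
    retention: RetentionTable | None = None,
    *,
    null_policy: NullPolicy | str = NullPolicy.ZERO_FLAG,
) -> list[RecipeNutrients]:
    return [compute_recipe_nutrients(r, fct, retention, null_policy=null_policy) for r in recipes]


def results_to_frame(results: Iterable[RecipeNutrients]) -> pd.DataFrame:
    """One row per recipe: per_100g_* and per_serving_* nutrient columns
    plus weight and coverage metadata."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "recipe_code": r.recipe_code,
            "total_weight_g": r.total_weight_g,
            "retention_applied": r.retention_applied,
            "coverage": r.coverage,
            "retention_coverage": r.retention_coverage,
        }
        for f in NUTRIENT_FIELDS:
            row[f"per_100g_{f}"] = r.per_100g[f]
        for f in NUTRIENT_FIELDS:
            row[f"per_serving_{f}"] = None if r.per_serving is None else r.per_serving[f]
        rows.append(row)
    return pd.DataFrame(rows)


def load_recipes(path: str | Path) -> list[Recipe]:
    """Read the long-format recipe CSV (one row per ingredient line).

    Per-recipe columns (``english_name``, ``category``,
    ``total_weight_g``, ``n_servings``, ``serving_size_g``) are taken
    from each recipe's first row.
    """
    df = pd.read_csv(path, dtype={"recipe_code": str})
    if df.empty:
        raise RecipeError(f"{path}: recipe file has no rows")
    recipes: list[Recipe] = []
    for code, grp in df.groupby("recipe_code", sort=False):
        head = grp.iloc[0]

        def _opt(col: str) -> float | None:
            v = head.get(col)
            return None if v is None or pd.isna(v) else float(v)

        n_serv = _opt("n_servings")
        lines = [
            IngredientLine(
                raw_name=str(row["raw_name"]),
                quantity=float(row["quantity"]),
                unit=str(row["unit"]),
            )
            for _, row in grp.iterrows()
        ]
        recipes.append(
            Recipe(
                recipe_code=str(code),
                english_name=str(head.get("english_name", "")),
                local_name=str(head.get("local_name", "") or ""),
                category=str(head.get("category", "") or ""),
                ingredients=lines,
                total_weight_g=_opt("total_weight_g"),
                n_servings=int(n_serv) if n_serv is not None else None,
                serving_size_g=_opt("serving_size_g"),
            )
        )
    return recipes


def load_ingredient_mapping(path: str | Path) -> dict[str, list[tuple[Source, str]]]:
    """Read the curated ingredient-name mapping CSV
    (``raw_name, source, food_code``; several candidate rows per name allowed)."""
    df = pd.read_csv(path, dtype=str)
    mapping: dict[str, list[tuple[Source, str]]] = {}
    for _, row in df.iterrows():
        mapping.setdefault(str(row["raw_name"]), []).append(
            (Source(row["source"]), str(row["food_code"]))
        )
    return mapping
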