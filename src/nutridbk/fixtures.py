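"""Deterministic synthetic fixture generator with an independent oracle.

Emits a complete toy input set for the two-stage pipeline — four source
FCT CSVs with controlled duplication between the two national editions,
a gap-fill mapping, an ingredient-name mapping, a long-format recipe
table, a retention-factor table with assignments, and a pipeline
configuration — plus a ground-truth CSV of the expected per-100 g and
per-serving recipe nutrients.

The ground truth is computed by a deliberately naive, loop-based
summation inside this module that shares no code with the pipeline
(plain dict/float arithmetic, inline conversion constants), so the
generator and the engine cannot share a bug.  The same seed always
reproduces byte-identical files; the manifest records SHA-256 hashes.

Default proportions scale the full databank's shape down about fivefold:
four sources contributing 106/74/29/11 items, ~200 multi-ingredient
recipes, and a 42.62% retention assignment rate.  Fixture values carry
no nutritional realism (no correlation structure among nutrients).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .fct import Source
from .nutrients import NUTRIENT_FIELDS
from .retention import COVERED_FIELDS

__all__ = ["FixtureSpec", "generate_fixture"]

_KJ_PER_KCAL = 4.184  # inline on purpose: the oracle must not import the engine's constants
_KCAL_PER_KJ = 0.239

#: Which energy column each source reports natively.
_SOURCE_ENERGY_UNIT = {
    Source.IFCT2017: "kJ",
    Source.IFCT2004: "kcal",
    Source.UKFCT: "kJ",
    Source.USDA: "kcal",
}

_FILL_FIELDS = ("biotin_ug", "carb_g", "fibre_g")

_CATEGORIES = ("bread", "main", "curry", "dessert")


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and rates of the generated toy databank.

    Defaults are the study conditions at roughly one-fifth scale; the
    retention assignment rate targets the share of recipe ingredient
    lines carrying a retention factor.
    """

    seed: int = 0
    n_items_per_source: Mapping[Source, int] = dc_field(
        default_factory=lambda: {
            Source.IFCT2017: 106,
            Source.IFCT2004: 74,
            Source.UKFCT: 29,
            Source.USDA: 11,
        }
    )
    n_recipes: int = 203
    ingredients_per_recipe: tuple[int, int] = (3, 12)
    missingness_rate: float = 0.15
    retention_assignment_rate: float = 0.4262
    n_overlap_items: int = 15  # foods duplicated across the two national editions
    n_single_ingredient: int = 12  # single-ingredient recipes for factor recovery
    n_retention_codes: int = 6

    def __post_init__(self) -> None:
        for name in ("missingness_rate", "retention_assignment_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.ingredients_per_recipe
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid ingredients_per_recipe range {self.ingredients_per_recipe}")


def _gen_values(rng: np.random.Generator) -> dict[str, float]:
    """One food's nutrient values (all fields non-null; energy coherent)."""
    vals: dict[str, float] = {}
    kcal = round(float(rng.uniform(40, 600)), 1)
    vals["energy_kcal"] = kcal
    vals["energy_kj"] = round(kcal * _KJ_PER_KCAL, 1)
    for f in NUTRIENT_FIELDS:
        if f.startswith("energy"):
            continue
        unit = f.rsplit("_", 1)[1]
        hi = {"g": 80.0, "mg": 500.0, "ug": 300.0}[unit]
        vals[f] = round(float(rng.uniform(0, hi)), 3)
    return vals


def _native_row(values: Mapping[str, float | None], unit: str) -> dict[str, float | None]:
    """Drop the non-native energy column so the loader must convert."""
    out = dict(values)
    out.pop("energy_kcal" if unit == "kJ" else "energy_kj")
    return out


def _loaded_values(native: Mapping[str, float | None], unit: str) -> dict[str, float | None]:
    """What the loader is expected to produce from a native row (naive math)."""
    out = {f: native.get(f) for f in NUTRIENT_FIELDS}
    if unit == "kJ":
        out["energy_kcal"] = None if out["energy_kj"] is None else out["energy_kj"] * _KCAL_PER_KJ
    else:
        out["energy_kj"] = None if out["energy_kcal"] is None else out["energy_kcal"] * _KJ_PER_KCAL
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Any]:
    """Write the full fixture set to ``out_dir`` and return the manifest.

    The manifest lists every file with its SHA-256 hash, the expected
    per-source item counts, the designated parameter-recovery retention
    code with its generating factors, the degenerate recipe codes, and
    the realised retention line coverage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    counts = {Source(s): int(n) for s, n in spec.n_items_per_source.items()}

    # ---- source items -------------------------------------------------------
    # native[src] maps food_code -> row dict as written to that source's CSV
    native: dict[Source, dict[str, dict[str, Any]]] = {}
    for src in (Source.IFCT2017, Source.IFCT2004, Source.UKFCT, Source.USDA):
        unit = _SOURCE_ENERGY_UNIT[src]
        rows: dict[str, dict[str, Any]] = {}
        for i in range(counts.get(src, 0)):
            code = f"{src.value}_{i:03d}"
            vals: dict[str, float | None] = dict(_gen_values(rng))
            if src in (Source.IFCT2017, Source.IFCT2004):
                for f in _FILL_FIELDS:
                    if rng.random() < spec.missingness_rate:
                        vals[f] = None
            rows[code] = {
                "food_code": code,
                "name": f"food {src.value.lower()} {i:03d}",
                "local_names": f"desi {src.value.lower()} {i:03d}",
                **_native_row(vals, unit),
            }
        native[src] = rows

    # duplicated foods: the older edition re-lists some 2017 codes with
    # different values; the merge must keep the 2017 record
    codes_2017 = list(native[Source.IFCT2017])
    overlap_codes = [
        codes_2017[i] for i in rng.choice(len(codes_2017), size=min(spec.n_overlap_items, len(codes_2017)), replace=False)
    ]
    for code in overlap_codes:
        vals: dict[str, float | None] = dict(_gen_values(rng))
        native[Source.IFCT2004][code] = {
            "food_code": code,
            "name": native[Source.IFCT2017][code]["name"],
            "local_names": native[Source.IFCT2017][code]["local_names"],
            **_native_row(vals, "kcal"),
        }

    # ---- expected compiled databank (naive priority merge) ------------------
    compiled: dict[str, dict[str, float | None]] = {}
    item_source: dict[str, Source] = {}
    item_name: dict[str, str] = {}
    for src in (Source.IFCT2017, Source.IFCT2004, Source.UKFCT, Source.USDA):
        unit = _SOURCE_ENERGY_UNIT[src]
        for code, row in native[src].items():
            if code in compiled:
                continue  # higher-priority edition already holds this food
            compiled[code] = _loaded_values(row, unit)
            item_source[code] = src
            item_name[code] = row["name"]

    # ---- gap-fill mapping ----------------------------------------------------
    uk_codes = list(native[Source.UKFCT])
    gap_rows = []
    items_with_gaps = [
        c for c, v in compiled.items() if any(v[f] is None for f in _FILL_FIELDS)
    ]
    unmapped_gap_item = items_with_gaps[0] if items_with_gaps else None  # no-fallback case
    n_gap_filled = 0
    for code in items_with_gaps:
        if code == unmapped_gap_item:
            continue
        fb = uk_codes[int(rng.integers(len(uk_codes)))]
        gap_rows.append({"item_code": code, "fallback_source": Source.UKFCT.value, "fallback_code": fb})
        for f in _FILL_FIELDS:
            if compiled[code][f] is None and compiled[fb][f] is not None:
                compiled[code][f] = compiled[fb][f]
                n_gap_filled += 1

    # ---- retention factors and assignment -----------------------------------
    ret_codes = [f"RF{i + 1:02d}" for i in range(spec.n_retention_codes)]
    descriptions = [
        "legumes, cooked 15-20 minutes, boiled and baked",
        "vegetables, boiled and drained",
        "cereal grains, steamed",
        "leafy greens, sauteed",
        "roots and tubers, fried",
        "dairy, simmered",
    ]
    factors: dict[str, dict[str, float]] = {}
    for i, rc in enumerate(ret_codes):
        facs: dict[str, float] = {}
        for f in COVERED_FIELDS:
            if f in ("calcium_mg", "zinc_mg"):
                lo, hi = 0.75, 1.0
            elif f == "vitc_mg":
                lo, hi = 0.2, 1.0
            else:
                lo, hi = 0.5, 1.0
            facs[f] = round(float(rng.uniform(lo, hi)), 3)
        if i == spec.n_retention_codes - 1:
            # one partial set: two nutrients not covered by this method class
            facs.pop("folate_ug", None)
            facs.pop("carotenoids_ug", None)
        factors[rc] = facs
    recovery_code = ret_codes[0]

    # foods reserved for single-ingredient parameter-recovery recipes are
    # kept out of the general ingredient pool so the realised line
    # coverage stays at the target rate
    pool_2017 = [c for c in codes_2017]
    recovery_foods = [
        pool_2017[i]
        for i in rng.choice(len(pool_2017), size=min(spec.n_single_ingredient, len(pool_2017)), replace=False)
    ]
    general_pool = sorted(set(compiled) - set(recovery_foods))

    # exact-count assignment (not Bernoulli per food): recipe lines sample
    # foods uniformly, so the assigned-food fraction IS the expected line
    # coverage, and fixing the count pins it to the target rate
    assignment: dict[str, str] = {}
    n_assign = int(round(spec.retention_assignment_rate * len(general_pool)))
    assigned_foods = [
        general_pool[i] for i in rng.choice(len(general_pool), size=n_assign, replace=False)
    ]
    for code in assigned_foods:
        assignment[code] = ret_codes[int(rng.integers(len(ret_codes)))]
    for code in recovery_foods:
        assignment[code] = recovery_code
    assignment = dict(sorted(assignment.items()))

    # ---- ingredient name mapping --------------------------------------------
    map_rows = [
        {"raw_name": item_name[c], "source": item_source[c].value, "food_code": c}
        for c in sorted(compiled)
    ]
    # a few names also list a lower-priority candidate: matching must
    # still pick the national-table item
    decoy_names = []
    if uk_codes:
        for c in codes_2017[:5]:
            uk = uk_codes[int(rng.integers(len(uk_codes)))]
            map_rows.append({"raw_name": item_name[c], "source": Source.UKFCT.value, "food_code": uk})
            decoy_names.append(item_name[c])
    name_to_code = {item_name[c]: c for c in compiled}  # priority winner by construction

    # ---- recipes -------------------------------------------------------------
    lo, hi = spec.ingredients_per_recipe
    recipe_rows: list[dict[str, Any]] = []
    recipe_meta: dict[str, dict[str, Any]] = {}
    recipe_lines: dict[str, list[tuple[str, float]]] = {}  # code -> [(food_code, grams)]

    def _line_quantity(unit: str) -> float:
        if unit == "g":
            return round(float(rng.uniform(5, 300)), 1)
        if unit == "ml":
            return round(float(rng.uniform(5, 250)), 1)
        if unit in ("tbsp", "tsp"):
            return float(rng.choice([0.5, 1.0, 1.5, 2.0, 3.0]))
        return float(rng.integers(1, 6))  # sprig

    def _grams(unit: str, qty: float) -> float:
        return {"g": qty, "ml": qty * 1.0, "tbsp": qty * 15.0, "tsp": qty * 5.0, "sprig": qty * 1.0}[unit]

    def _add_recipe(code: str, name: str, category: str, lines: list[tuple[str, str, float]],
                    total_weight: float | None, n_servings: int | None, serving_size: float | None) -> None:
        resolved = []
        for food, unit, qty in lines:
            recipe_rows.append(
                {
                    "recipe_code": code,
                    "english_name": name,
                    "local_name": f"ghar ka {name}",
                    "category": category,
                    "raw_name": item_name.get(food, food),
                    "quantity": qty,
                    "unit": unit,
                    "total_weight_g": total_weight,
                    "n_servings": n_servings,
                    "serving_size_g": serving_size,
                }
            )
            resolved.append((food, _grams(unit, qty)))
        recipe_meta[code] = {
            "total_weight_g": total_weight,
            "n_servings": n_servings,
            "serving_size_g": serving_size,
        }
        recipe_lines[code] = resolved

    units = ("g", "ml", "tbsp", "tsp", "sprig")
    unit_p = (0.55, 0.15, 0.10, 0.10, 0.10)
    for i in range(spec.n_recipes):
        code = f"R{i:04d}"
        k = int(rng.integers(lo, hi + 1))
        foods = [general_pool[j] for j in rng.choice(len(general_pool), size=k, replace=False)]
        lines = []
        for food in foods:
            unit = str(rng.choice(units, p=unit_p))
            lines.append((food, unit, _line_quantity(unit)))
        raw_sum = sum(_grams(u, q) for _, u, q in lines)
        total_weight = round(raw_sum * float(rng.uniform(0.85, 1.25)), 1) if rng.random() < 0.3 else None
        if rng.random() < 0.85:
            n_servings, serving_size = int(rng.integers(1, 9)), None
        else:
            n_servings, serving_size = None, round(float(rng.uniform(50, 250)), 0)
        _add_recipe(code, f"recipe {i:04d}", _CATEGORIES[i % len(_CATEGORIES)], lines,
                    total_weight, n_servings, serving_size)

    for j, food in enumerate(recovery_foods):
        _add_recipe(f"RSINGLE{j:02d}", f"single dish {j:02d}", "main",
                    [(food, "g", round(float(rng.uniform(80, 400)), 1))], None, 2, None)

    # degenerate classes --------------------------------------------------
    ident_food = general_pool[0]
    _add_recipe("RIDENT", "identity dish", "main", [(ident_food, "g", 100.0)], 100.0, 1, None)
    pickle_foods = [general_pool[j] for j in rng.choice(len(general_pool), size=3, replace=False)]
    _add_recipe("RPICKLE", "mango pickle", "pickles and preserves",
                [(f, "g", round(float(rng.uniform(10, 120)), 1)) for f in pickle_foods], None, None, None)
    uk_only = next(c for c in sorted(compiled) if item_source[c] is Source.UKFCT)
    usda_only = next(c for c in sorted(compiled) if item_source[c] is Source.USDA)
    _add_recipe("RUKONLY", "uk fallback dish", "curry",
                [(uk_only, "g", 150.0), (general_pool[1], "g", 50.0)], None, 2, None)
    _add_recipe("RUSDAONLY", "usda fallback dish", "curry",
                [(usda_only, "g", 120.0), (general_pool[2], "g", 80.0)], None, 4, None)
    # error-path recipe: its ingredient has no mapping row
    recipe_rows.append(
        {
            "recipe_code": "RUNMATCHED", "english_name": "mystery dish",
            "local_name": "rahasya", "category": "main",
            "raw_name": "mystery ingredient", "quantity": 50.0, "unit": "g",
            "total_weight_g": None, "n_servings": 2, "serving_size_g": None,
        }
    )

    # ---- naive ground-truth computation --------------------------------------
    truth_rows: list[dict[str, Any]] = []
    n_lines = 0
    n_assigned_lines = 0
    for code, lines in recipe_lines.items():
        meta = recipe_meta[code]
        n_lines += len(lines)
        n_assigned_lines += sum(1 for food, _ in lines if food in assignment)
        for with_retention in (False, True):
            totals: dict[str, float | None] = {f: None for f in NUTRIENT_FIELDS}
            for food, grams in lines:
                vals = compiled[food]
                for f in NUTRIENT_FIELDS:
                    v = vals[f]
                    if v is None:
                        continue
                    if with_retention and food in assignment:
                        fac = factors[assignment[food]].get(f)
                        if fac is not None:
                            v = v * fac
                    contrib = v * (grams / 100.0)
                    totals[f] = contrib if totals[f] is None else totals[f] + contrib
            tw = meta["total_weight_g"]
            if tw is None:
                tw = sum(g for _, g in lines)
            per100 = {f: (None if v is None else v * (100.0 / tw)) for f, v in totals.items()}
            if meta["n_servings"] is not None:
                per_serv = {f: (None if v is None else v / meta["n_servings"]) for f, v in totals.items()}
            elif meta["serving_size_g"] is not None:
                per_serv = {
                    f: (None if v is None else v * (meta["serving_size_g"] / 100.0))
                    for f, v in per100.items()
                }
            else:
                per_serv = {f: None for f in NUTRIENT_FIELDS}
            row: dict[str, Any] = {
                "recipe_code": code,
                "retention": int(with_retention),
                "total_weight_g": tw,
            }
            row.update({f"per_100g_{f}": per100[f] for f in NUTRIENT_FIELDS})
            row.update({f"per_serving_{f}": per_serv[f] for f in NUTRIENT_FIELDS})
            truth_rows.append(row)

    # ---- write files ----------------------------------------------------------
    fct_files = {}
    for src in (Source.IFCT2017, Source.IFCT2004, Source.UKFCT, Source.USDA):
        unit = _SOURCE_ENERGY_UNIT[src]
        energy_col = "energy_kj" if unit == "kJ" else "energy_kcal"
        cols = ["food_code", "name", "local_names", energy_col] + [
            f for f in NUTRIENT_FIELDS if f != energy_col and not f.startswith("energy")
        ]
        df = pd.DataFrame(list(native[src].values()), columns=cols)
        fname = f"fct_{src.value.lower()}.csv"
        df.to_csv(out / fname, index=False)
        fct_files[src.value] = fname

    pd.DataFrame(gap_rows, columns=["item_code", "fallback_source", "fallback_code"]).to_csv(
        out / "gapfill_mapping.csv", index=False
    )
    pd.DataFrame(map_rows, columns=["raw_name", "source", "food_code"]).to_csv(
        out / "ingredient_mapping.csv", index=False
    )
    recipe_cols = [
        "recipe_code", "english_name", "local_name", "category",
        "raw_name", "quantity", "unit", "total_weight_g", "n_servings", "serving_size_g",
    ]
    pd.DataFrame(recipe_rows, columns=recipe_cols).to_csv(out / "recipes.csv", index=False)

    ret_rows = []
    for rc in ret_codes:
        row = {"retention_code": rc, "description": descriptions[ret_codes.index(rc) % len(descriptions)]}
        row.update({f: factors[rc].get(f) for f in COVERED_FIELDS})
        ret_rows.append(row)
    pd.DataFrame(ret_rows, columns=["retention_code", "description", *COVERED_FIELDS]).to_csv(
        out / "retention_factors.csv", index=False
    )
    pd.DataFrame(sorted(assignment.items()), columns=["food_code", "retention_code"]).to_csv(
        out / "retention_assignment.csv", index=False
    )

    truth_cols = ["recipe_code", "retention", "total_weight_g"] + [
        f"per_100g_{f}" for f in NUTRIENT_FIELDS
    ] + [f"per_serving_{f}" for f in NUTRIENT_FIELDS]
    pd.DataFrame(truth_rows, columns=truth_cols).to_csv(out / "ground_truth.csv", index=False)

    PipelineConfig().to_yaml(out / "config.yaml")

    files = sorted(
        [*fct_files.values(), "gapfill_mapping.csv", "ingredient_mapping.csv", "recipes.csv",
         "retention_factors.csv", "retention_assignment.csv", "ground_truth.csv", "config.yaml"]
    )
    manifest: dict[str, Any] = {
        "seed": spec.seed,
        "rng": "numpy default_rng (PCG64)",
        "files": {f: _sha256(out / f) for f in files},
        "fct_files": fct_files,
        "expected_source_counts": {s.value: int(n) for s, n in counts.items()},
        "expected_total_items": int(sum(counts.values())),
        "n_overlap_items": len(overlap_codes),
        "overlap_codes": sorted(overlap_codes),
        "n_gap_filled_values": n_gap_filled,
        "unmapped_gap_item": unmapped_gap_item,
        "recovery": {
            "retention_code": recovery_code,
            "factors": factors[recovery_code],
            "recipes": [f"RSINGLE{j:02d}" for j in range(len(recovery_foods))],
            "foods": recovery_foods,
        },
        "degenerate_recipes": {
            "identity": "RIDENT",
            "no_serving_info": "RPICKLE",
            "uk_only_ingredient": "RUKONLY",
            "usda_only_ingredient": "RUSDAONLY",
            "unmatched_ingredient": "RUNMATCHED",
        },
        "identity_food": ident_food,
        "decoy_mapped_names": decoy_names,
        "n_ingredient_lines": n_lines,
        "realised_retention_line_coverage": (n_assigned_lines / n_lines) if n_lines else 0.0,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
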