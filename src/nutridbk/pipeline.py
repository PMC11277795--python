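"""Two-stage pipeline orchestration and CSV artifact writing.

Stage 1 compiles the source FCTs into the raw-food databank; stage 2
resolves and computes recipe nutrient profiles, optionally twice
(without and with retention factors) followed by the paired comparison.
Every run echoes its effective configuration into the output directory.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import PipelineConfig
from .fct import (
    CompiledFCT,
    GapFillRecord,
    MergeReport,
    Source,
    compile_fct,
    load_fct,
    provenance_summary,
    write_compiled,
)
from .recipes import (
    Recipe,
    compute_all,
    load_ingredient_mapping,
    load_recipes,
    resolve_recipe,
    results_to_frame,
)
from .retention import RetentionTable, load_retention_table
from .stats import retention_range_report, summarize_differences

logger = logging.getLogger(__name__)

__all__ = [
    "load_gapfill_mapping",
    "run_compile",
    "run_calculate",
    "run_compare",
    "run_full_pipeline",
]

#: Energy unit each well-known source declares natively; synthetic or
#: unknown layouts should pass explicit units instead.
DEFAULT_SOURCE_ENERGY_UNITS: Mapping[Source, str] = {
    Source.IFCT2017: "kJ",
    Source.IFCT2004: "kcal",
    Source.UKFCT: "kJ",
    Source.USDA: "kcal",
    Source.SYNTHETIC: "kcal",
}


def load_gapfill_mapping(path: str | Path) -> dict[str, tuple[Source, str]]:
    """Read the curated gap-fill mapping CSV
    (``item_code, fallback_source, fallback_code``)."""
    df = pd.read_csv(path, dtype=str)
    return {
        str(r["item_code"]): (Source(r["fallback_source"]), str(r["fallback_code"]))
        for _, r in df.iterrows()
    }


def run_compile(
    config: PipelineConfig,
    fct_paths: Mapping[Source, str | Path],
    gapfill_mapping_path: str | Path | None = None,
    out_dir: str | Path | None = None,
    *,
    energy_units: Mapping[Source, str] | None = None,
) -> tuple[CompiledFCT, list[MergeReport], list[GapFillRecord]]:
    """Stage 1: load every source table in priority order, merge, gap-fill.

    Writes ``compiled_fct.csv``, ``provenance.csv``, ``merge_report.csv``
    and the echoed configuration when ``out_dir`` is given.
    """
    units = dict(DEFAULT_SOURCE_ENERGY_UNITS)
    if energy_units:
        units.update({Source(s): u for s, u in energy_units.items()})
    tables = []
    for src in config.source_priority:
        if src not in fct_paths:
            continue
        path = Path(fct_paths[src])
        if not path.exists():
            raise FileNotFoundError(f"source table for {src.value} not found: {path}")
        items = load_fct(path, src, units[src], energy=config.energy, energy_rtol=config.energy_rtol)
        logger.info("loaded %d items from %s (%s)", len(items), path, src.value)
        tables.append((src, items))
    mapping = load_gapfill_mapping(gapfill_mapping_path) if gapfill_mapping_path else None
    fct, reports, records = compile_fct(
        tables, match_key=config.match_key, fill_fields=config.fill_fields, gapfill_mapping=mapping
    )
    counts, total = provenance_summary(fct)
    logger.info(
        "compiled %d items: %s", total, {s.value: n for s, n in sorted(counts.items(), key=lambda kv: kv[0].value)}
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_compiled(fct, out)
        pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
            out / "merge_report.csv", index=False
        )
        pd.DataFrame(
            [
                {
                    "food_code": r.food_code,
                    "nutrient_field": r.field,
                    "action": r.action,
                    "fill_source": r.fill_source.value if r.fill_source else None,
                    "fallback_code": r.fallback_code,
                }
                for r in records
            ],
            columns=["food_code", "nutrient_field", "action", "fill_source", "fallback_code"],
        ).to_csv(out / "gapfill_report.csv", index=False)
        config.to_yaml(out / "config_used.yaml")
    return fct, reports, records


def _resolve_all(
    config: PipelineConfig,
    recipes: list[Recipe],
    mapping_path: str | Path,
    fct: CompiledFCT,
) -> list[Recipe]:
    mapping = load_ingredient_mapping(mapping_path)
    return [
        resolve_recipe(r, mapping, fct, config.measures, on_unmatched=config.on_unmatched)
        for r in recipes
    ]


def run_calculate(
    config: PipelineConfig,
    fct: CompiledFCT,
    recipes_path: str | Path,
    mapping_path: str | Path,
    retention: RetentionTable | None = None,
    out_dir: str | Path | None = None,
    out_name: str = "recipe_nutrients.csv",
) -> pd.DataFrame:
    """Stage 2: resolve, match and compute every recipe; returns the
    one-row-per-recipe nutrient table."""
    recipes = load_recipes(recipes_path)
    recipes = _resolve_all(config, recipes, mapping_path, fct)
    if config.on_unmatched == "exclude":
        computable = []
        for r in recipes:
            if any(ln.matched_code is not None for ln in r.ingredients):
                computable.append(r)
            else:
                logger.warning("recipe %s: no matchable ingredients; dropped from output", r.recipe_code)
        recipes = computable
    results = compute_all(recipes, fct, retention, null_policy=config.null_policy)
    frame = results_to_frame(results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / out_name, index=False)
        config.to_yaml(out / "config_used.yaml")
    return frame


def run_compare(
    config: PipelineConfig,
    fct: CompiledFCT,
    recipes_path: str | Path,
    mapping_path: str | Path,
    retention: RetentionTable,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Compute both arms and the per-nutrient paired comparison.

    Returns (without, with, comparison); writes the three tables plus a
    per-recipe delta table when ``out_dir`` is given.
    """
    without = run_calculate(config, fct, recipes_path, mapping_path, None)
    with_ = run_calculate(config, fct, recipes_path, mapping_path, retention)
    comparison = summarize_differences(without, with_)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        without.to_csv(out / "recipe_nutrients_without_retention.csv", index=False)
        with_.to_csv(out / "recipe_nutrients_with_retention.csv", index=False)
        comparison.to_csv(out / "retention_comparison.csv", index=False)
        delta = without.set_index("recipe_code").filter(like="per_100g_") - with_.set_index(
            "recipe_code"
        ).filter(like="per_100g_")
        delta.to_csv(out / "per_recipe_delta.csv")
        config.to_yaml(out / "config_used.yaml")
    return without, with_, comparison


def run_full_pipeline(
    config: PipelineConfig,
    fct_paths: Mapping[Source, str | Path],
    recipes_path: str | Path,
    mapping_path: str | Path,
    out_dir: str | Path,
    gapfill_mapping_path: str | Path | None = None,
    retention_factors_path: str | Path | None = None,
    retention_assignment_path: str | Path | None = None,
) -> dict[str, object]:
    """Compile, match, calculate (both arms when retention inputs are
    given) and compare; returns the in-memory artifacts."""
    out = Path(out_dir)
    fct, reports, records = run_compile(config, fct_paths, gapfill_mapping_path, out)
    artifacts: dict[str, object] = {"fct": fct, "merge_reports": reports, "gapfill_records": records}
    if retention_factors_path is not None:
        retention = load_retention_table(retention_factors_path, retention_assignment_path)
        without, with_, comparison = run_compare(
            config, fct, recipes_path, mapping_path, retention, out
        )
        artifacts.update(
            {
                "without": without,
                "with": with_,
                "comparison": comparison,
                "retention_ranges": retention_range_report(fct, retention),
            }
        )
    else:
        artifacts["without"] = run_calculate(
            config, fct, recipes_path, mapping_path, None, out
        )
    return artifacts
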