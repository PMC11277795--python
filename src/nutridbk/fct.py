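"""Food composition table (FCT) compilation: stage 1 of the databank.

Source tables (two national FCT editions plus foreign fallback tables)
are loaded from CSV, merged under a strict source-priority order — for a
food present in several tables the highest-priority table's record is
kept whole, with no field-level mixing — and remaining per-nutrient gaps
are filled from a curated code-to-code mapping into a fallback table.
Every value carries provenance: which source supplied it.
"""

from __future__ import annotations

import logging
import string
import warnings
from collections import Counter
from dataclasses import dataclass, field as dc_field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .nutrients import (
    DEFAULT_ENERGY,
    DEFAULT_ENERGY_RTOL,
    NUTRIENT_FIELDS,
    EnergyConversion,
    NutrientValidationError,
    NutrientVector,
    kcal_to_kj,
    kj_to_kcal,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "DEFAULT_SOURCE_PRIORITY",
    "SourceTag",
    "FoodItem",
    "CompiledFCT",
    "MergeReport",
    "GapFillRecord",
    "FCTValidationError",
    "DEFAULT_FILL_FIELDS",
    "source_rank",
    "normalize_name",
    "load_fct",
    "merge_fcts",
    "gap_fill",
    "provenance_summary",
    "compile_fct",
    "write_compiled",
    "read_compiled",
]


class Source(str, Enum):
    """Identity of a contributing food composition table."""

    IFCT2017 = "IFCT2017"
    IFCT2004 = "IFCT2004"
    UKFCT = "UKFCT"
    USDA = "USDA"
    SYNTHETIC = "SYNTHETIC"


#: Default priority order, highest first: the newer national edition wins
#: over the older one, which wins over the UK table, then USDA.
DEFAULT_SOURCE_PRIORITY: tuple[Source, ...] = (
    Source.IFCT2017,
    Source.IFCT2004,
    Source.UKFCT,
    Source.USDA,
    Source.SYNTHETIC,
)


def source_rank(source: Source, priority: Sequence[Source] = DEFAULT_SOURCE_PRIORITY) -> int:
    """1-based priority rank of a source (1 = most authoritative)."""
    return list(priority).index(Source(source)) + 1


@dataclass(frozen=True)
class SourceTag:
    """A source together with its priority rank within a compilation."""

    code: Source
    priority_rank: int

    @classmethod
    def of(cls, source: Source, priority: Sequence[Source] = DEFAULT_SOURCE_PRIORITY) -> "SourceTag":
        return cls(Source(source), source_rank(source, priority))


class FCTValidationError(ValueError):
    """An input table violates the FCT loading contract."""


@dataclass(frozen=True)
class FoodItem:
    """A raw food: code, names, source, per-100 g nutrients and provenance.

    ``provenance`` maps every non-null nutrient field to the source whose
    table supplied that value (differing from ``source`` only through
    gap-filling).
    """

    food_code: str
    name: str
    source: Source
    nutrients: NutrientVector
    local_names: tuple[str, ...] = ()
    provenance: Mapping[str, Source] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        prov = dict(self.provenance)
        for f in self.nutrients.nonnull_fields:
            prov.setdefault(f, self.source)
        object.__setattr__(self, "provenance", prov)


_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def normalize_name(name: str) -> str:
    """Lowercase, strip punctuation and collapse whitespace (for name matching)."""
    return " ".join(name.lower().translate(_PUNCT_TABLE).split())


#: Nutrients gap-filled from the secondary source by default: the fields
#: most often missing for protein foods in the national tables.
DEFAULT_FILL_FIELDS: frozenset[str] = frozenset({"carb_g", "fibre_g", "biotin_ug"})

_META_COLUMNS = ("food_code", "name", "local_names")


def load_fct(
    path: str | Path,
    source: Source,
    energy_unit: str,
    *,
    energy: EnergyConversion = DEFAULT_ENERGY,
    energy_rtol: float = DEFAULT_ENERGY_RTOL,
) -> list[FoodItem]:
    """Load one source FCT from CSV.

    The file has ``food_code``, ``name``, optional ``local_names``
    (pipe-separated) and any subset of the canonical nutrient columns.
    ``energy_unit`` ("kJ" or "kcal") declares which energy column the
    source reports natively; the other representation is filled in with
    the FAO factor for that direction.  Unknown columns are ignored with
    a warning; a negative nutrient or duplicate ``food_code`` is an error
    naming the offending row.
    """
    unit = energy_unit.lower()
    if unit not in ("kj", "kcal"):
        raise FCTValidationError(f"energy_unit must be 'kJ' or 'kcal', got {energy_unit!r}")
    try:
        df = pd.read_csv(path, dtype={"food_code": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    for required in ("food_code", "name"):
        if required not in df.columns:
            raise FCTValidationError(f"{path}: missing required column {required!r}")
    declared_col = "energy_kj" if unit == "kj" else "energy_kcal"
    if declared_col not in df.columns:
        raise FCTValidationError(
            f"{path}: declared energy unit {energy_unit} but column {declared_col!r} absent"
        )
    known = set(NUTRIENT_FIELDS) | set(_META_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    dupes = df["food_code"][df["food_code"].duplicated()].unique().tolist()
    if dupes:
        raise FCTValidationError(f"{path}: duplicate food_code values {dupes}")

    nutrient_cols = [c for c in df.columns if c in NUTRIENT_FIELDS]
    bad: list[str] = []
    for idx, row in df.iterrows():
        for c in nutrient_cols:
            v = row[c]
            if pd.notna(v) and v < 0:
                bad.append(f"row {idx} (food_code={row['food_code']}): {c}={v}")
    if bad:
        raise FCTValidationError(f"{path}: negative nutrient values: " + "; ".join(bad))

    items: list[FoodItem] = []
    src = Source(source)
    for _, row in df.iterrows():
        values = {c: (None if pd.isna(row[c]) else float(row[c])) for c in nutrient_cols}
        kj, kcal = values.get("energy_kj"), values.get("energy_kcal")
        if kj is None and kcal is not None:
            values["energy_kj"] = kcal_to_kj(kcal, energy)
        elif kcal is None and kj is not None:
            values["energy_kcal"] = kj_to_kcal(kj, energy)
        local = row.get("local_names")
        local_names = tuple(s for s in str(local).split("|") if s) if pd.notna(local) else ()
        try:
            vec = NutrientVector(energy_rtol=energy_rtol, **values)
        except NutrientValidationError as exc:
            raise FCTValidationError(f"{path}: food_code={row['food_code']}: {exc}") from exc
        items.append(
            FoodItem(
                food_code=str(row["food_code"]),
                name=str(row["name"]),
                local_names=local_names,
                source=src,
                nutrients=vec,
            )
        )
    return items


@dataclass
class MergeReport:
    """Duplicates dropped while merging two source collections."""

    match_key: str
    dropped: list[tuple[str, str, str]] = dc_field(default_factory=list)  # (key, dropped_code, kept_code)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["match_key_value", "dropped_code", "kept_code"])


def merge_fcts(
    primary: Iterable[FoodItem],
    older: Iterable[FoodItem],
    match_key: str = "food_code",
) -> tuple[list[FoodItem], MergeReport]:
    """Union of two item collections with the primary edition winning.

    For any food present in both (matched on ``food_code`` or on
    ``normalized_name``), the primary item is kept in full — values are
    never mixed across editions at this step.  The report lists every
    dropped duplicate.
    """
    if match_key not in ("food_code", "normalized_name"):
        raise ValueError(f"unknown match_key {match_key!r}")
    keyfn: Callable[[FoodItem], str]
    if match_key == "food_code":
        keyfn = lambda it: it.food_code  # noqa: E731
    else:
        keyfn = lambda it: normalize_name(it.name)  # noqa: E731
    primary = list(primary)
    older = list(older)
    primary_keys = {keyfn(it): it for it in primary}
    report = MergeReport(match_key=match_key)
    out = list(primary)
    for it in older:
        k = keyfn(it)
        if k in primary_keys:
            report.dropped.append((k, it.food_code, primary_keys[k].food_code))
        else:
            out.append(it)
            primary_keys[k] = it
    return out, report


@dataclass(frozen=True)
class GapFillRecord:
    """Outcome of one gap-fill attempt on one nutrient field."""

    food_code: str
    field: str
    action: str  # "filled" | "unresolved" | "no_match"
    fill_source: Source | None = None
    fallback_code: str | None = None


def gap_fill(
    item: FoodItem,
    fallback: Mapping[str, FoodItem],
    fill_fields: Iterable[str] = DEFAULT_FILL_FIELDS,
    mapping: Mapping[str, str] | None = None,
) -> tuple[FoodItem, list[GapFillRecord]]:
    """Fill null fields of ``item`` from its curated fallback food.

    ``mapping`` gives the fallback key for each item code (no fuzzy
    matching); ``fallback`` maps those keys to items.  Only fields in
    ``fill_fields`` that are null on the item and non-null on the fallback
    are copied; provenance for a copied field is set to the fallback's
    source.  An item with gaps but no mapping entry is returned unchanged
    with a "no fallback match" record.
    """
    mapping = mapping or {}
    fill_fields = set(fill_fields)
    gaps = [f for f in fill_fields if item.nutrients[f] is None]
    if not gaps:
        return item, []
    fb_key = mapping.get(item.food_code)
    fb_item = fallback.get(fb_key) if fb_key is not None else None
    if fb_item is None:
        logger.info("no fallback match for %s (gaps: %s)", item.food_code, gaps)
        return item, [GapFillRecord(item.food_code, f, "no_match") for f in gaps]
    records: list[GapFillRecord] = []
    changes: dict[str, float] = {}
    prov = dict(item.provenance)
    for f in gaps:
        v = fb_item.nutrients[f]
        if v is None:
            records.append(GapFillRecord(item.food_code, f, "unresolved", fb_item.source, fb_item.food_code))
        else:
            changes[f] = v
            prov[f] = fb_item.source
            records.append(GapFillRecord(item.food_code, f, "filled", fb_item.source, fb_item.food_code))
            logger.info(
                "gap-filled %s.%s = %s from %s:%s",
                item.food_code, f, v, fb_item.source.value, fb_item.food_code,
            )
    if not changes:
        return item, records
    filled = FoodItem(
        food_code=item.food_code,
        name=item.name,
        local_names=item.local_names,
        source=item.source,
        nutrients=item.nutrients.replace(**changes),
        provenance=prov,
    )
    return filled, records


@dataclass
class CompiledFCT:
    """The merged, gap-filled databank of raw food items."""

    items: dict[str, FoodItem] = dc_field(default_factory=dict)

    @classmethod
    def from_items(cls, items: Iterable[FoodItem]) -> "CompiledFCT":
        d: dict[str, FoodItem] = {}
        for it in items:
            if it.food_code in d:
                raise FCTValidationError(f"duplicate food_code in compiled databank: {it.food_code}")
            d[it.food_code] = it
        return cls(items=d)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, code: str) -> bool:
        return code in self.items

    def __getitem__(self, code: str) -> FoodItem:
        return self.items[code]

    def get(self, code: str) -> FoodItem | None:
        return self.items.get(code)

    @property
    def source_counts(self) -> dict[Source, int]:
        """Per-source item counts, recomputed on every access (never stale)."""
        return dict(Counter(it.source for it in self.items.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items.values():
            row: dict[str, object] = {
                "food_code": it.food_code,
                "name": it.name,
                "local_names": "|".join(it.local_names),
                "source": it.source.value,
            }
            row.update(it.nutrients.as_dict())
            rows.append(row)
        cols = list(_META_COLUMNS) + ["source"] + list(NUTRIENT_FIELDS)
        return pd.DataFrame(rows, columns=cols)

    def provenance_frame(self) -> pd.DataFrame:
        rows = [
            {"food_code": it.food_code, "nutrient_field": f, "source": s.value}
            for it in self.items.values()
            for f, s in sorted(it.provenance.items())
        ]
        return pd.DataFrame(rows, columns=["food_code", "nutrient_field", "source"])


def provenance_summary(fct: CompiledFCT) -> tuple[dict[Source, int], int]:
    """Per-source item counts (by item-level source) and their total."""
    counts = fct.source_counts
    return counts, sum(counts.values())


def compile_fct(
    tables: Sequence[tuple[Source, Sequence[FoodItem]]],
    *,
    match_key: str = "food_code",
    fill_fields: Iterable[str] = DEFAULT_FILL_FIELDS,
    gapfill_mapping: Mapping[str, tuple[Source, str]] | None = None,
    fallback_pool: Mapping[tuple[Source, str], FoodItem] | None = None,
) -> tuple[CompiledFCT, list[MergeReport], list[GapFillRecord]]:
    """Run stage 1: priority merge of all source tables, then gap-fill.

    ``tables`` is ordered highest priority first.  Foods only present in
    a fallback table become first-class items of that source, which keeps
    per-source counts additive.  ``gapfill_mapping`` maps an item code to
    the curated (source, code) fallback food; the fallback pool defaults
    to all items of all non-first tables.
    """
    merged: list[FoodItem] = []
    reports: list[MergeReport] = []
    for _, items in tables:
        merged, rep = merge_fcts(merged, items, match_key=match_key)
        reports.append(rep)
    if fallback_pool is None:
        fallback_pool = {
            (src, it.food_code): it for src, items in tables[1:] for it in items
        }
    mapping = {
        code: (Source(src), fb_code) for code, (src, fb_code) in (gapfill_mapping or {}).items()
    }
    flat_fallback = {f"{s.value}:{c}": it for (s, c), it in fallback_pool.items()}
    flat_mapping = {code: f"{s.value}:{c}" for code, (s, c) in mapping.items()}
    records: list[GapFillRecord] = []
    filled_items: list[FoodItem] = []
    for it in merged:
        filled, recs = gap_fill(it, flat_fallback, fill_fields, flat_mapping)
        filled_items.append(filled)
        records.extend(recs)
    return CompiledFCT.from_items(filled_items), reports, records


def write_compiled(fct: CompiledFCT, out_dir: str | Path) -> dict[str, Path]:
    """Write the compiled databank and its provenance table as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compiled": out / "compiled_fct.csv",
        "provenance": out / "provenance.csv",
    }
    fct.to_frame().to_csv(paths["compiled"], index=False)
    fct.provenance_frame().to_csv(paths["provenance"], index=False)
    return paths


def read_compiled(in_dir: str | Path) -> CompiledFCT:
    """Reload a compiled databank written by :func:`write_compiled` (lossless)."""
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "compiled_fct.csv", dtype={"food_code": str})
    prov_df = pd.read_csv(in_dir / "provenance.csv", dtype={"food_code": str})
    prov_by_code: dict[str, dict[str, Source]] = {}
    for _, row in prov_df.iterrows():
        prov_by_code.setdefault(row["food_code"], {})[row["nutrient_field"]] = Source(row["source"])
    items = []
    for _, row in df.iterrows():
        values = {c: (None if pd.isna(row[c]) else float(row[c])) for c in NUTRIENT_FIELDS}
        local = row.get("local_names")
        items.append(
            FoodItem(
                food_code=str(row["food_code"]),
                name=str(row["name"]),
                local_names=tuple(s for s in str(local).split("|") if s) if pd.notna(local) else (),
                source=Source(row["source"]),
                nutrients=NutrientVector(energy_rtol=float("inf"), **values),
                provenance=prov_by_code.get(str(row["food_code"]), {}),
            )
        )
    return CompiledFCT.from_items(items)
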