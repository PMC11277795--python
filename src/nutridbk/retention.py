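"""Nutrient retention factors: cooking losses applied to raw foods.

A retention factor set gives, for one cooking-method class (e.g.
"legumes, cooked 15-20 minutes, boiled and baked"), the fraction of each
covered nutrient remaining after cooking.  Each raw food is assigned at
most one factor set — the most common cooking method for that food — and
the factors multiply the food's raw per-100 g values before recipe
summation.  Only 17 minerals and vitamins are covered; energy,
macronutrients and the other panel fields are never touched, and a food
with no assignment keeps its raw values (implicit factor 1.0), so
with/without-retention comparisons run over identical recipe sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .fct import Source  # noqa: F401  (re-exported context for assignment files)
from .nutrients import NutrientVector

logger = logging.getLogger(__name__)

__all__ = [
    "COVERED_FIELDS",
    "RetentionFactor",
    "RetentionTable",
    "RetentionConfigError",
    "assign_retention",
    "apply_retention",
    "load_retention_table",
    "write_retention_table",
]

#: The 17 nutrients with published retention factors; all other panel
#: fields pass through cooking unchanged in this model.
COVERED_FIELDS: tuple[str, ...] = (
    "calcium_mg",
    "iron_mg",
    "magnesium_mg",
    "phosphorus_mg",
    "potassium_mg",
    "sodium_mg",
    "zinc_mg",
    "copper_mg",
    "vitc_mg",
    "thiamine_mg",
    "riboflavin_mg",
    "niacin_mg",
    "folicacid_ug",
    "vitb6_mg",
    "folate_ug",
    "vita_ug",
    "carotenoids_ug",
)

_COVERED_SET = frozenset(COVERED_FIELDS)


class RetentionConfigError(ValueError):
    """A retention table or assignment violates its contract."""


@dataclass(frozen=True)
class RetentionFactor:
    """Multiplicative retention fractions for one cooking-method class.

    ``factors`` maps covered nutrient fields to fractions in [0, 1]; a
    field absent from the map is treated as fully retained.
    """

    retention_code: str
    description: str
    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = set(self.factors) - _COVERED_SET
        if bad:
            raise RetentionConfigError(
                f"{self.retention_code}: factors for non-covered nutrients {sorted(bad)}"
            )
        out_of_range = {f: v for f, v in self.factors.items() if not (0.0 <= v <= 1.0)}
        if out_of_range:
            raise RetentionConfigError(
                f"{self.retention_code}: factors outside [0, 1]: {out_of_range}"
            )
        object.__setattr__(self, "factors", dict(self.factors))


@dataclass
class RetentionTable:
    """All factor sets plus the food -> factor-set assignment (a function)."""

    factors: dict[str, RetentionFactor] = dc_field(default_factory=dict)
    assignment: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {c for c in self.assignment.values() if c not in self.factors}
        if unknown:
            raise RetentionConfigError(
                f"assignment references unknown retention codes: {sorted(unknown)}"
            )


def assign_retention(food_code: str, table: RetentionTable) -> RetentionFactor | None:
    """The factor set assigned to a food, or ``None`` if it has no assignment."""
    code = table.assignment.get(food_code)
    return table.factors[code] if code is not None else None


def apply_retention(v: NutrientVector, rf: RetentionFactor) -> NutrientVector:
    """Multiply covered, non-null nutrients by their retention fraction.

    Nutrients outside the covered set — and null fields — are returned
    bit-identical.
    """
    changes = {
        f: v[f] * fac for f, fac in rf.factors.items() if v[f] is not None
    }
    return v.replace(**changes) if changes else v


def load_retention_table(
    factors_path: str | Path, assignment_path: str | Path | None = None
) -> RetentionTable:
    """Load factor sets and the optional food assignment from CSV.

    The factors file has ``retention_code``, ``description`` and one
    column per covered nutrient (fractions; blank = not covered by that
    set).  The assignment file has ``food_code``, ``retention_code``; an
    assignment to a code absent from the factors file is a load-time
    error.
    """
    df = pd.read_csv(factors_path, dtype={"retention_code": str})
    factors: dict[str, RetentionFactor] = {}
    for _, row in df.iterrows():
        code = str(row["retention_code"])
        if code in factors:
            raise RetentionConfigError(f"duplicate retention_code {code}")
        facs = {
            f: float(row[f]) for f in COVERED_FIELDS if f in df.columns and pd.notna(row[f])
        }
        factors[code] = RetentionFactor(code, str(row.get("description", "")), facs)
    assignment: dict[str, str] = {}
    if assignment_path is not None:
        adf = pd.read_csv(assignment_path, dtype=str)
        for _, row in adf.iterrows():
            food, code = str(row["food_code"]), str(row["retention_code"])
            if food in assignment and assignment[food] != code:
                raise RetentionConfigError(
                    f"food {food} assigned to multiple retention codes"
                )
            assignment[food] = code
            logger.debug("retention assignment %s -> %s", food, code)
    return RetentionTable(factors=factors, assignment=assignment)


def write_retention_table(table: RetentionTable, factors_path: str | Path, assignment_path: str | Path) -> None:
    """Write a retention table back to the two-CSV interchange format."""
    rows = []
    for rf in table.factors.values():
        row: dict[str, object] = {"retention_code": rf.retention_code, "description": rf.description}
        row.update({f: rf.factors.get(f) for f in COVERED_FIELDS})
        rows.append(row)
    pd.DataFrame(rows, columns=["retention_code", "description", *COVERED_FIELDS]).to_csv(
        factors_path, index=False
    )
    pd.DataFrame(
        sorted(table.assignment.items()), columns=["food_code", "retention_code"]
    ).to_csv(assignment_path, index=False)
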