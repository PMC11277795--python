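"""Nutrient panel, energy unit conversion and vector arithmetic.

The databank expresses every food and recipe as a fixed 39-nutrient
profile per 100 g edible portion: energy in both kJ and kcal,
macronutrients in grams, minerals and most vitamins in milligrams, and
trace nutrients in micrograms.  Missing values are explicit (``None``),
never zero — a table that did not analyse biotin for a food is a
different statement from one that measured none — and the distinction is
preserved through all arithmetic.

Energy is converted with the FAO factor pair 1 kcal = 4.184 kJ and
1 kJ = 0.239 kcal.  The two printed factors are deliberately *not*
mutual inverses (1/4.184 ≈ 0.23901); each direction uses its own factor
and the library never chains both on the same value.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping

__all__ = [
    "NUTRIENT_FIELDS",
    "FIELD_UNITS",
    "EnergyConversion",
    "DEFAULT_ENERGY",
    "NullPolicy",
    "NutrientVector",
    "NutrientValidationError",
    "kcal_to_kj",
    "kj_to_kcal",
    "scale",
    "add",
    "nsum",
]

#: Canonical column names (``<name>_<unit>``) of the 39-nutrient panel,
#: in databank column order.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kj",
    "energy_kcal",
    "carb_g",
    "protein_g",
    "fat_g",
    "freesugar_g",
    "fibre_g",
    "sfa_mg",
    "mufa_mg",
    "pufa_mg",
    "cholesterol_mg",
    "calcium_mg",
    "phosphorus_mg",
    "magnesium_mg",
    "sodium_mg",
    "potassium_mg",
    "iron_mg",
    "copper_mg",
    "selenium_ug",
    "chromium_mg",
    "manganese_mg",
    "molybdenum_mg",
    "zinc_mg",
    "vita_ug",
    "vite_mg",
    "vitd2_ug",
    "vitd3_ug",
    "vitk1_ug",
    "vitk2_ug",
    "folate_ug",
    "thiamine_mg",
    "riboflavin_mg",
    "niacin_mg",
    "pantothenic_mg",
    "vitb6_mg",
    "biotin_ug",
    "folicacid_ug",
    "vitc_mg",
    "carotenoids_ug",
)

_FIELD_SET = frozenset(NUTRIENT_FIELDS)

#: Unit of each field, derived from the canonical suffix.
FIELD_UNITS: Mapping[str, str] = {
    f: ("kJ" if f == "energy_kj" else "kcal" if f == "energy_kcal" else f.rsplit("_", 1)[1])
    for f in NUTRIENT_FIELDS
}


class NutrientValidationError(ValueError):
    """A nutrient value or operation argument violates the panel contract."""


@dataclass(frozen=True)
class EnergyConversion:
    """The FAO energy factor pair.

    ``kj_per_kcal`` and ``kcal_per_kj`` are independent printed constants,
    not inverses of each other.
    """

    kj_per_kcal: float = 4.184
    kcal_per_kj: float = 0.239

    def __post_init__(self) -> None:
        if self.kj_per_kcal <= 0 or self.kcal_per_kj <= 0:
            raise NutrientValidationError("energy conversion factors must be > 0")


DEFAULT_ENERGY = EnergyConversion()

#: Relative tolerance for the kJ/kcal coherence check on a vector.  2%
#: absorbs the non-inverse factor pair plus source rounding.
DEFAULT_ENERGY_RTOL = 0.02


class NullPolicy(str, Enum):
    """How :func:`add` treats missing operands.

    ``ZERO_FLAG``  — a null operand contributes 0 and the result field is
    flagged incomplete (default; used for recipe summation).
    ``PROPAGATE``  — any null operand yields a null result field.
    """

    ZERO_FLAG = "treat-null-as-zero-with-flag"
    PROPAGATE = "propagate-null"


class NutrientVector:
    """An immutable 39-field nutrient profile (per 100 g, or a scaled total).

    Parameters
    ----------
    incomplete:
        Field names whose value is known to under-count because a null
        operand was zeroed during summation.
    energy_rtol:
        Relative tolerance for the kJ = kcal x 4.184 coherence check when
        both energy fields are present.
    **values:
        Canonical field name -> non-negative value, or ``None``/omitted
        for missing.
    """

    __slots__ = ("_values", "incomplete")

    def __init__(
        self,
        incomplete: Iterable[str] = (),
        energy_rtol: float = DEFAULT_ENERGY_RTOL,
        energy: EnergyConversion = DEFAULT_ENERGY,
        **values: float | None,
    ) -> None:
        unknown = set(values) - _FIELD_SET
        if unknown:
            raise NutrientValidationError(f"unknown nutrient fields: {sorted(unknown)}")
        vals: dict[str, float | None] = {f: None for f in NUTRIENT_FIELDS}
        for f, v in values.items():
            if v is None:
                continue
            v = float(v)
            if v != v:  # NaN means missing in tabular input
                continue
            if v < 0:
                raise NutrientValidationError(f"negative value for {f}: {v}")
            vals[f] = v
        kj, kcal = vals["energy_kj"], vals["energy_kcal"]
        if kj is not None and kcal is not None:
            expected = kcal * energy.kj_per_kcal
            if abs(kj - expected) > energy_rtol * max(abs(expected), 1e-12):
                raise NutrientValidationError(
                    f"incoherent energy pair: {kj} kJ vs {kcal} kcal "
                    f"(expected ~{expected:.3f} kJ)"
                )
        bad_flags = set(incomplete) - _FIELD_SET
        if bad_flags:
            raise NutrientValidationError(f"unknown incomplete flags: {sorted(bad_flags)}")
        object.__setattr__(self, "_values", vals)
        object.__setattr__(self, "incomplete", frozenset(incomplete))

    # -- mapping-style access -------------------------------------------------
    def __getitem__(self, item: str) -> float | None:
        return self._values[item]

    def get(self, item: str, default: float | None = None) -> float | None:
        v = self._values[item]
        return default if v is None else v

    def items(self) -> Iterator[tuple[str, float | None]]:
        return iter(self._values.items())

    def as_dict(self, drop_null: bool = False) -> dict[str, float | None]:
        if drop_null:
            return {f: v for f, v in self._values.items() if v is not None}
        return dict(self._values)

    @property
    def nonnull_fields(self) -> tuple[str, ...]:
        return tuple(f for f, v in self._values.items() if v is not None)

    def replace(self, **changes: float | None) -> "NutrientVector":
        vals = self.as_dict()
        vals.update(changes)
        return NutrientVector(incomplete=self.incomplete, **vals)

    def with_flags(self, flags: Iterable[str]) -> "NutrientVector":
        return NutrientVector(incomplete=self.incomplete | set(flags), **self.as_dict())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return self._values == other._values and self.incomplete == other.incomplete

    def __hash__(self) -> int:
        return hash((tuple(self._values.items()), self.incomplete))

    def __repr__(self) -> str:
        body = ", ".join(f"{f}={v:g}" for f, v in self._values.items() if v is not None)
        flags = f", incomplete={sorted(self.incomplete)}" if self.incomplete else ""
        return f"NutrientVector({body}{flags})"


def kcal_to_kj(e: float, energy: EnergyConversion = DEFAULT_ENERGY) -> float:
    """Convert kilocalories to kilojoules with the FAO factor (4.184)."""
    if e is None:
        raise NutrientValidationError("energy value is null")
    if e < 0:
        raise NutrientValidationError(f"negative energy: {e} kcal")
    return e * energy.kj_per_kcal


def kj_to_kcal(e: float, energy: EnergyConversion = DEFAULT_ENERGY) -> float:
    """Convert kilojoules to kilocalories with the FAO factor (0.239)."""
    if e is None:
        raise NutrientValidationError("energy value is null")
    if e < 0:
        raise NutrientValidationError(f"negative energy: {e} kJ")
    return e * energy.kcal_per_kj


def scale(v: NutrientVector, f: float) -> NutrientVector:
    """Multiply every non-null field by ``f`` (null fields stay null)."""
    if f < 0:
        raise NutrientValidationError(f"negative scale factor: {f}")
    vals = {k: (None if x is None else x * f) for k, x in v.items()}
    # scaling can break the 2% kJ/kcal coherence only via rounding; keep
    # the check disabled here by scaling both energies identically
    return NutrientVector(incomplete=v.incomplete, energy_rtol=float("inf"), **vals)


def add(
    a: NutrientVector,
    b: NutrientVector,
    null_policy: NullPolicy | str = NullPolicy.ZERO_FLAG,
) -> NutrientVector:
    """Fieldwise sum of two vectors.

    Under ``ZERO_FLAG`` (default) a null operand contributes 0 and the
    field is flagged incomplete; if both operands are null the field stays
    null (and is flagged).  Under ``PROPAGATE`` any null operand nulls the
    result field.
    """
    policy = NullPolicy(null_policy)
    vals: dict[str, float | None] = {}
    flags = set(a.incomplete) | set(b.incomplete)
    for f in NUTRIENT_FIELDS:
        x, y = a[f], b[f]
        if policy is NullPolicy.PROPAGATE:
            vals[f] = None if (x is None or y is None) else x + y
        else:
            if x is None and y is None:
                vals[f] = None
                flags.add(f)
            elif x is None or y is None:
                vals[f] = x if y is None else y
                flags.add(f)
            else:
                vals[f] = x + y
    return NutrientVector(incomplete=flags, energy_rtol=float("inf"), **vals)


def nsum(
    vectors: Iterable[NutrientVector],
    null_policy: NullPolicy | str = NullPolicy.ZERO_FLAG,
) -> NutrientVector:
    """Sum a sequence of vectors under ``null_policy`` (empty sum -> all-null)."""
    total: NutrientVector | None = None
    for v in vectors:
        total = v if total is None else add(total, v, null_policy)
    return total if total is not None else NutrientVector()
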