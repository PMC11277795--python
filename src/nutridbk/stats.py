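"""Paired with/without-retention comparison statistics.

For each covered nutrient, per-100 g values computed without and with
retention factors form paired samples over recipes.  The module reports
per-arm medians, the mean paired difference (without − with, which is
non-negative by construction since retention factors are ≤ 1), and a
two-sided Wilcoxon signed-rank p-value.

The signed-rank test drops zero differences (Wilcoxon's original rule),
mid-ranks ties, and uses the exact permutation null for small effective
n — computed by a generating-function convolution over the 2^n sign
assignments — switching to the normal approximation with continuity
correction (and tie-corrected variance, via scipy) for larger samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fct import CompiledFCT
from .retention import COVERED_FIELDS, RetentionTable

__all__ = [
    "EXACT_N_MAX",
    "PairedNutrientSample",
    "ComparisonSummary",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "summarize_differences",
    "retention_range_report",
]

#: Largest effective sample size for which the exact permutation null is
#: enumerated; beyond this the normal approximation is used.
EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedNutrientSample:
    """Paired per-100 g values of one nutrient over recipes."""

    nutrient: str
    without: tuple[float, ...]
    with_: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.without) != len(self.with_):
            raise ValueError(
                f"{self.nutrient}: arms have different lengths "
                f"({len(self.without)} vs {len(self.with_)})"
            )


@dataclass(frozen=True)
class ComparisonSummary:
    """One nutrient's with/without-retention comparison."""

    nutrient: str
    median_without: float
    median_with: float
    mean_difference: float  # without − with
    p_value: float
    n: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    p_value: float
    n: int  # effective n after zero handling
    method: str  # "exact" | "approx" | "degenerate"
    degenerate: bool = False  # no nonzero pairs


def _exact_signed_rank_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for the signed-rank statistic of nonzero ``diffs``.

    Enumerates the null distribution of W+ (each difference's sign
    equally likely) by convolving the rank generating polynomial; ranks
    are mid-ranks of |d|, doubled so tied half-ranks stay integral.
    Returns (W+, p).
    """
    ranks = sps.rankdata(np.abs(diffs))
    dbl = np.rint(2 * ranks).astype(np.int64)  # 2x mid-ranks are integers
    w_plus_dbl = int(dbl[diffs > 0].sum())
    total = dbl.sum()
    # counts[s] = number of sign assignments with doubled W+ == s
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in dbl:
        counts[r:] = counts[r:] + counts[:-r]  # RHS evaluated first: overlap-safe
    n_assign = counts.sum()  # == 2^n, exact in int64 for n <= 62
    p_le = counts[: w_plus_dbl + 1].sum() / n_assign
    p_ge = counts[w_plus_dbl:].sum() / n_assign
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(dbl[diffs > 0].sum()) / 2.0, p


def wilcoxon_signed_rank(
    without: Sequence[float] | PairedNutrientSample,
    with_: Sequence[float] | None = None,
    *,
    zero_policy: str = "discard",
    mode: str = "auto",
    exact_n_max: int = EXACT_N_MAX,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Parameters
    ----------
    without, with_:
        The two arms (or a :class:`PairedNutrientSample` alone).
    zero_policy:
        ``"discard"`` (default) drops zero differences before ranking;
        ``"pratt"`` keeps them in the ranking (normal approximation only).
    mode:
        ``"exact"``, ``"normal-approx"``, or ``"auto"`` (exact when the
        effective n is at most ``exact_n_max``).

    All differences zero is reported as a degenerate result with p = 1
    rather than an error.
    """
    if isinstance(without, PairedNutrientSample):
        d = np.asarray(without.without, dtype=float) - np.asarray(without.with_, dtype=float)
    elif with_ is not None:
        x = np.asarray(without, dtype=float)
        y = np.asarray(with_, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"paired arms differ in length: {x.shape} vs {y.shape}")
        d = x - y
    else:
        d = np.asarray(without, dtype=float)
    if d.size == 0:
        raise ValueError("no pairs supplied")
    if zero_policy not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if mode not in ("auto", "exact", "normal-approx"):
        raise ValueError(f"unknown mode {mode!r}")

    nonzero = d[d != 0]
    n_eff = int(nonzero.size)
    if n_eff == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n=0, method="degenerate", degenerate=True)

    use_exact = mode == "exact" or (mode == "auto" and n_eff <= exact_n_max)
    if zero_policy == "pratt":
        use_exact = False  # exact enumeration implemented for the classic rule only
    if use_exact:
        w_plus, p = _exact_signed_rank_p(nonzero)
        return WilcoxonResult(statistic=w_plus, p_value=p, n=n_eff, method="exact")
    zm = "wilcox" if zero_policy == "discard" else "pratt"
    sample = nonzero if zero_policy == "discard" else d
    res = sps.wilcoxon(
        sample, zero_method=zm, correction=True, alternative="two-sided", method="approx"
    )
    ranks = sps.rankdata(np.abs(nonzero if zero_policy == "discard" else d))
    if zero_policy == "pratt":
        w_plus = float(ranks[d > 0].sum())
    else:
        w_plus = float(ranks[nonzero > 0].sum())
    return WilcoxonResult(statistic=w_plus, p_value=float(res.pvalue), n=n_eff, method="approx")


def _per100g_matrix(table: pd.DataFrame, nutrients: Sequence[str]) -> pd.DataFrame:
    """Accept recipe tables keyed either by raw field names or by the
    ``per_100g_<field>`` CSV columns; return a recipe x nutrient frame."""
    df = table
    if "recipe_code" in df.columns:
        df = df.set_index("recipe_code")
    cols = {}
    for f in nutrients:
        if f in df.columns:
            cols[f] = df[f]
        elif f"per_100g_{f}" in df.columns:
            cols[f] = df[f"per_100g_{f}"]
        else:
            raise KeyError(f"nutrient column {f!r} (or per_100g_{f}) not found")
    return pd.DataFrame(cols)


def summarize_differences(
    without: pd.DataFrame,
    with_: pd.DataFrame,
    nutrients: Sequence[str] = COVERED_FIELDS,
    *,
    bonferroni: bool = False,
    mode: str = "auto",
) -> pd.DataFrame:
    """Per-nutrient medians, mean paired difference and signed-rank p-value.

    Both tables must cover the same recipes (joined on ``recipe_code``);
    a mismatch is an error listing the difference.  Medians are computed
    over recipes with a non-null value for the nutrient.  With
    ``bonferroni=True`` p-values are multiplied by the number of
    nutrients tested (capped at 1); off by default.
    """
    a = _per100g_matrix(without, nutrients)
    b = _per100g_matrix(with_, nutrients)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            "recipe sets differ between arms: "
            f"only in without-arm {list(only_a[:10])}, only in with-arm {list(only_b[:10])}"
        )
    b = b.loc[a.index]
    rows = []
    for f in nutrients:
        x, y = a[f], b[f]
        paired = x.notna() & y.notna()
        n = int(paired.sum())
        if n == 0:
            rows.append(ComparisonSummary(f, float("nan"), float("nan"), float("nan"), float("nan"), 0))
            continue
        res = wilcoxon_signed_rank(x[paired].to_numpy(), y[paired].to_numpy(), mode=mode)
        p = res.p_value
        if bonferroni:
            p = min(1.0, p * len(nutrients))
        rows.append(
            ComparisonSummary(
                nutrient=f,
                median_without=float(x[x.notna()].median()),
                median_with=float(y[y.notna()].median()),
                mean_difference=float((x[paired] - y[paired]).mean()),
                p_value=p,
                n=n,
            )
        )
    return pd.DataFrame(
        [
            {
                "nutrient": r.nutrient,
                "median_without": r.median_without,
                "median_with": r.median_with,
                "mean_diff": r.mean_difference,
                "p_value": r.p_value,
                "n": r.n,
            }
            for r in rows
        ]
    )


def retention_range_report(
    fct: CompiledFCT, table: RetentionTable
) -> dict[str, tuple[float, float]]:
    """Min and max retention factor per covered nutrient over assigned foods.

    Foods without an assignment do not contribute; an empty assignment
    yields an empty report.
    """
    report: dict[str, tuple[float, float]] = {}
    for food_code, ret_code in table.assignment.items():
        if len(fct) and food_code not in fct:
            continue
        rf = table.factors[ret_code]
        for f, v in rf.factors.items():
            lo, hi = report.get(f, (v, v))
            report[f] = (min(lo, v), max(hi, v))
    return report
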