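"""Descriptive and inferential group comparison.

Mirrors the original SAS analysis plan: quantitative variables are described
by (n, mean, SD, median, Q1, Q3, min, max, missing) and compared by one-way
ANOVA; qualitative variables by counts and percentages over non-missing
values and compared by Pearson's chi-squared test without continuity
correction.  Each test yields an overall p-value across all three practice
groups plus pairwise p-values of every other group against the conventional
(CM) reference — the pairwise ANOVA p is the two-group ANOVA, identical to
the pooled-variance two-sided t-test (F = t^2).  Raw p-values are reported
per variable; no multiplicity correction.  Significance is conventionally
read at 5 %.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

ALPHA = 0.05


class TestKind(str, enum.Enum):
    chi_squared = "chi_squared"
    anova = "anova"


@dataclass
class ComparisonResult:
    variable: str
    test: TestKind
    statistic: float
    overall_p: float
    pairwise_p: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.overall_p, *self.pairwise_p.values()):
            if not (0.0 <= p <= 1.0 or math.isnan(p)):
                raise ValidationError(f"p-value out of [0, 1]: {p}")


@dataclass
class QuantitativeSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n_missing: int


@dataclass
class QualitativeSummary:
    counts: dict[str, int]
    percentages: dict[str, float]  # over non-missing, sum to 100
    n_missing: int


@dataclass
class GroupSummary:
    group: str
    n: int
    quantitative: dict[str, QuantitativeSummary] = field(default_factory=dict)
    qualitative: dict[str, QualitativeSummary] = field(default_factory=dict)


def summarize_quantitative(values: pd.Series) -> QuantitativeSummary:
    x = pd.to_numeric(values, errors="coerce")
    n_missing = int(x.isna().sum())
    x = x.dropna()
    if len(x) == 0:
        nan = float("nan")
        return QuantitativeSummary(0, nan, nan, nan, nan, nan, nan, nan, n_missing)
    sd = float(x.std(ddof=1)) if len(x) > 1 else float("nan")
    return QuantitativeSummary(
        n=len(x), mean=float(x.mean()), sd=sd, median=float(x.median()),
        q1=float(x.quantile(0.25)), q3=float(x.quantile(0.75)),
        min=float(x.min()), max=float(x.max()), n_missing=n_missing)


def summarize_qualitative(values: pd.Series) -> QualitativeSummary:
    x = values[~values.isna()]
    counts = x.value_counts().sort_index()
    total = int(counts.sum())
    pct = {str(k): 100.0 * v / total for k, v in counts.items()} if total else {}
    return QualitativeSummary(
        counts={str(k): int(v) for k, v in counts.items()},
        percentages=pct,
        n_missing=int(values.isna().sum()))


def describe(df: pd.DataFrame, group_col: str = "practice_group",
             quantitative: tuple[str, ...] = (),
             qualitative: tuple[str, ...] = ()) -> list[GroupSummary]:
    """Per-group summaries in the style of the published descriptive tables.

    Empty groups yield summaries full of missing descriptors, never an error.
    """
    out = []
    for g, sub in df.groupby(group_col, sort=False):
        summary = GroupSummary(group=str(g), n=len(sub))
        for var in quantitative:
            summary.quantitative[var] = summarize_quantitative(sub[var])
        for var in qualitative:
            summary.qualitative[var] = summarize_qualitative(sub[var])
        out.append(summary)
    return out


def percentage(yes: int, no: int, decimals: int = 1) -> float:
    """A published-table percentage: yes / (yes + no) on non-missing counts."""
    if yes + no == 0:
        raise ValidationError("empty denominator")
    return round(100.0 * yes / (yes + no), decimals)


def chi_squared_test(table, variable: str = "",
                     group_labels: tuple[str, ...] | None = None,
                     ref: str = "CM") -> ComparisonResult:
    """Pearson chi-squared without continuity correction on an r x c table.

    Rows are outcome levels, columns are groups.  When ``group_labels`` are
    given, pairwise p-values test each non-reference group's column pair
    against the reference column.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValidationError("negative count in contingency table")
    for axis, name in ((1, "row"), (0, "column")):
        sums = t.sum(axis=axis)
        if (sums == 0).any():
            idx = int(np.where(sums == 0)[0][0])
            raise ValidationError(f"degenerate {name} {idx}: all counts zero")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    pairwise = {}
    if group_labels is not None:
        if len(group_labels) != t.shape[1]:
            raise ValidationError("group_labels must match table columns")
        ref_i = group_labels.index(ref)
        for j, g in enumerate(group_labels):
            if g == ref:
                continue
            sub = t[:, [ref_i, j]]
            _, pp, _, _ = stats.chi2_contingency(sub, correction=False)
            pairwise[f"{g}-vs-{ref}"] = float(pp)
    return ComparisonResult(variable=variable, test=TestKind.chi_squared,
                            statistic=float(stat), overall_p=float(p),
                            pairwise_p=pairwise)


def anova_costs(groups: dict[str, np.ndarray], ref: str = "CM",
                variable: str = "", log_scale: bool = False) -> ComparisonResult:
    """One-way ANOVA across groups plus two-group ANOVAs against ``ref``.

    ``log_scale`` compares log1p-transformed costs (off by default; the
    published analysis works on raw means despite the right skew).
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = {}
    for g, x in groups.items():
        a = np.asarray(x, dtype=float)
        a = a[~np.isnan(a)]
        if len(a) < 2:
            raise ValidationError(f"group {g}: fewer than 2 observations")
        arrays[g] = np.log1p(a) if log_scale else a
    if ref not in arrays:
        raise ValidationError(f"reference group {ref!r} not present")
    fstat, p = stats.f_oneway(*arrays.values())
    if all(np.allclose(a, next(iter(arrays.values()))[0]) for a in arrays.values()):
        fstat, p = 0.0, 1.0  # identical constant groups: no variance at all
    pairwise = {}
    for g, a in arrays.items():
        if g == ref:
            continue
        _, pp = stats.f_oneway(arrays[ref], a)
        pairwise[f"{g}-vs-{ref}"] = float(pp)
    return ComparisonResult(variable=variable, test=TestKind.anova,
                            statistic=float(fstat), overall_p=float(p),
                            pairwise_p=pairwise)


def headline_ratio(mean_a: float, mean_b: float,
                   decimals: int | None = None) -> float:
    """Percent saving of ``mean_a`` relative to ``mean_b``:
    100 x (mean_b - mean_a) / mean_b."""
    if mean_b <= 0:
        raise ValidationError("reference mean must be > 0")
    r = 100.0 * (mean_b - mean_a) / mean_b
    return round(r, decimals) if decimals is not None else r
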