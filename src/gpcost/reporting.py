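"""Published-style report tables over a costed cohort.

Three analogues of the original descriptive tables are produced, each as a
tidy numeric frame plus formatted cells (``n (%)`` for qualitative rows,
``mean [SD]`` for quantitative ones) with an overall p-value across the three
practice groups and pairwise p-values versus the conventional (CM) reference:

* non-medicinal prescriptions (sick-leave, imaging, lab tests, ...) — counts
  and chi-squared tests;
* prescription composition — homeopathic-only / conventional-only / mixed
  shares and drugs-per-prescription means overall and per reimbursement tier;
* the nine-cell cost grid (Social Security / remaining / health expenditure
  x consultation / prescription / total) — per-visit means compared by
  ANOVA.  Visits to not-under-agreement GPs have no countable consultation
  fee: they are excluded from consultation and total cost rows but retained
  in prescription rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compare import ComparisonResult, anova_costs, chi_squared_test, headline_ratio
from .model import NONMEDICINAL_FLAGS

GROUP_ORDER = ("CM", "Mx", "Ho")
REF_GROUP = "CM"

#: cost-table rows: label -> (breakdown column, excludes NUA visits)
COST_ROWS = {
    "ss": ("total_ss", True),
    "ss_consultation": ("consultation_ss", True),
    "ss_prescription": ("prescription_ss", False),
    "remaining": ("total_remaining", True),
    "remaining_consultation": ("consultation_remaining", True),
    "remaining_prescription": ("prescription_remaining", False),
    "expenditure": ("health_expenditure", True),
    "expenditure_consultation": ("consultation_total", True),
    "expenditure_prescription": ("prescription_total", False),
}


def fmt_n_pct(n: int, pct: float) -> str:
    return f"{n} ({pct:.1f})"


def fmt_mean_sd(mean: float, sd: float, decimals: int = 2) -> str:
    return f"{mean:.{decimals}f} [{sd:.{decimals}f}]"


def _groups_in(df: pd.DataFrame) -> list[str]:
    present = df["practice_group"].unique().tolist()
    return [g for g in GROUP_ORDER if g in present] + [
        g for g in present if g not in GROUP_ORDER]


def _p_cols(row: dict, result: ComparisonResult, groups: list[str]) -> None:
    row["p_overall"] = result.overall_p
    for g in groups:
        if g != REF_GROUP:
            row[f"p_{g}_vs_{REF_GROUP}"] = result.pairwise_p.get(
                f"{g}-vs-{REF_GROUP}", np.nan)


def nonmedicinal_table(visits: pd.DataFrame) -> pd.DataFrame:
    """Counts, percentages and chi-squared p-values for each flag."""
    groups = _groups_in(visits)
    rows = []
    for flag in NONMEDICINAL_FLAGS:
        yes = {g: int(visits.loc[visits["practice_group"] == g, flag]
                      .astype(bool).sum()) for g in groups}
        tot = {g: int((visits["practice_group"] == g).sum()) for g in groups}
        table = [[yes[g] for g in groups], [tot[g] - yes[g] for g in groups]]
        row = {"variable": flag}
        for g in groups:
            pct = 100.0 * yes[g] / tot[g] if tot[g] else np.nan
            row[g] = fmt_n_pct(yes[g], pct)
            row[f"{g}_pct"] = pct
        try:
            result = chi_squared_test(table, variable=flag,
                                      group_labels=tuple(groups), ref=REF_GROUP)
            _p_cols(row, result, groups)
        except Exception:
            row["p_overall"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def prescription_table(visits: pd.DataFrame, drugs: pd.DataFrame) -> pd.DataFrame:
    """Prescription composition and per-tier drug counts by group."""
    groups = _groups_in(visits)
    v = visits[["visit_id", "practice_group"]].copy()
    d = drugs.merge(v, on="visit_id", how="left")
    per_visit = (
        d.groupby("visit_id")
        .agg(n_lines=("visit_id", "size"),
             n_homeo=("is_homeopathic", lambda s: int(s.astype(bool).sum())),
             n_t0=("tier", lambda s: int((s.astype(float) == 0.0).sum())),
             n_t35=("tier", lambda s: int((s.astype(float) == 0.35).sum())),
             n_t65=("tier", lambda s: int((s.astype(float) == 0.65).sum())))
        .reindex(v["visit_id"], fill_value=0)
    )
    per_visit["practice_group"] = v.set_index("visit_id")["practice_group"]
    rows = []

    # composition among visits with at least one drug line
    has_rx = per_visit[per_visit["n_lines"] > 0]
    kinds = {
        "homeopathic_only": has_rx["n_homeo"] == has_rx["n_lines"],
        "conventional_only": has_rx["n_homeo"] == 0,
        "mixed": (has_rx["n_homeo"] > 0) & (has_rx["n_homeo"] < has_rx["n_lines"]),
    }
    for label, mask in kinds.items():
        row = {"variable": label}
        table = [[], []]
        for g in groups:
            in_g = has_rx["practice_group"] == g
            yes, tot = int((mask & in_g).sum()), int(in_g.sum())
            table[0].append(yes)
            table[1].append(tot - yes)
            pct = 100.0 * yes / tot if tot else np.nan
            row[g] = fmt_n_pct(yes, pct)
            row[f"{g}_pct"] = pct
        try:
            result = chi_squared_test(table, variable=label,
                                      group_labels=tuple(groups), ref=REF_GROUP)
            _p_cols(row, result, groups)
        except Exception:
            row["p_overall"] = np.nan
        rows.append(row)

    counts = {"drugs_per_rx": "n_lines", "drugs_nonreimbursable": "n_t0",
              "drugs_tier35": "n_t35", "drugs_tier65": "n_t65"}
    for label, col in counts.items():
        row = {"variable": label}
        by_group = {}
        for g in groups:
            x = per_visit.loc[per_visit["practice_group"] == g, col].to_numpy(float)
            by_group[g] = x
            row[g] = fmt_mean_sd(x.mean(), x.std(ddof=1), 1)
            row[f"{g}_mean"] = float(x.mean())
        result = anova_costs(by_group, ref=REF_GROUP, variable=label)
        _p_cols(row, result, groups)
        rows.append(row)
    return pd.DataFrame(rows)


def cost_table(visits: pd.DataFrame, breakdowns: pd.DataFrame) -> pd.DataFrame:
    """The nine-cell payer x component grid of per-visit cost means (EUR)."""
    groups = _groups_in(visits)
    merged = breakdowns.merge(visits[["visit_id", "practice_group"]],
                              on="visit_id", how="left")
    rows = []
    for label, (col, costed_only) in COST_ROWS.items():
        sub = merged[merged["consultation_costed"].astype(bool)] if costed_only else merged
        row = {"variable": label}
        by_group = {}
        for g in groups:
            eur = sub.loc[sub["practice_group"] == g, col].to_numpy(float) / 100.0
            by_group[g] = eur
            row[g] = fmt_mean_sd(eur.mean(), eur.std(ddof=1), 2)
            row[f"{g}_mean"] = float(eur.mean())
        result = anova_costs(by_group, ref=REF_GROUP, variable=label)
        _p_cols(row, result, groups)
        rows.append(row)
    return pd.DataFrame(rows)


def markdown_summary(table1: pd.DataFrame, table2: pd.DataFrame,
                     table4: pd.DataFrame, seed=None) -> str:
    """A compact human-readable report of the three tables and the headline
    expenditure saving of the homeopathic vs conventional group."""

    def md(df: pd.DataFrame) -> str:
        cols = [c for c in df.columns
                if not c.endswith(("_pct", "_mean")) or c == "p_overall"]
        show = df[cols].copy()
        for c in show.columns:
            if c.startswith("p_"):
                show[c] = show[c].map(
                    lambda p: "" if pd.isna(p) else f"{p:.4f}")
        header = "| " + " | ".join(show.columns) + " |"
        sep = "|" + "|".join(["---"] * len(show.columns)) + "|"
        body = ["| " + " | ".join(str(x) for x in rec) + " |"
                for rec in show.itertuples(index=False)]
        return "\n".join([header, sep, *body])

    lines = ["# Cohort cost report", ""]
    if seed is not None:
        lines += [f"Seed: {seed}", ""]
    lines += ["## Non-medicinal prescriptions", "", md(table1), "",
              "## Prescription composition", "", md(table2), "",
              "## Costs by payer perspective (EUR per visit)", "", md(table4), ""]
    t4 = table4.set_index("variable")
    if {"CM_mean", "Ho_mean"} <= set(t4.columns):
        ho = t4.loc["expenditure", "Ho_mean"]
        cm = t4.loc["expenditure", "CM_mean"]
        saving = headline_ratio(ho, cm)
        lines += [f"Health expenditure per visit: Ho {ho:.2f} EUR vs "
                  f"CM {cm:.2f} EUR — a {saving:.0f} % saving.", ""]
    return "\n".join(lines)
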