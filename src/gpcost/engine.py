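"""Deterministic cost attribution under the 2008 French tariff rules.

For every visit the engine fills the nine-cell grid of
:class:`~gpcost.model.CostBreakdown`:

* **Consultation** — the charged amount is the sector tariff (22 EUR sector 1,
  32 EUR sector 2).  Social Security reimburses its statutory share of the
  22 EUR *contractual base* only: 70 % normally, 100 % when the patient has a
  long-duration disease (DLD).  The 1 EUR adult lump sum is netted off the SS
  share (floored at zero), so it lands on the patient side, as does the whole
  sector-2 excess.  Not-under-agreement (NUA) consultations cannot be costed:
  all three consultation cells are zero and ``consultation_costed`` is False.
* **Prescription** — per drug line, total = unit price x boxes; SS reimburses
  tier x total (tier forced to 100 % for DLD-related lines), rounded half-up
  to the cent, minus the 0.25 EUR per-box franchise, floored at zero within
  the line.  Unreimbursed (tier 0) lines carry no franchise.
* **Total** — component-wise sum; SS + remaining = health expenditure.

Scalar functions operate on one visit; :func:`cost_frames` is the vectorized
equivalent over the two-table layout and is cent-identical to the scalar path.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import CostBreakdown, DrugLine, PatientVisit, Sector, TariffSchedule
from .money import share_cents, to_cents


class Split(NamedTuple):
    """A Social-Security / remaining / total decomposition, in cents."""

    ss: int
    remaining: int
    total: int


class ConsultationCost(NamedTuple):
    ss: int
    remaining: int
    total: int
    costed: bool


def consultation_cost(visit: PatientVisit, tariff: TariffSchedule) -> ConsultationCost:
    """Cost of the consultation itself, by payer."""
    if visit.gp.sector is Sector.NUA:
        return ConsultationCost(0, 0, 0, False)
    total = (tariff.tariff_s2_cents if visit.gp.sector is Sector.S2
             else tariff.tariff_s1_cents)
    if visit.has_dld:
        ss = tariff.base_cents
    else:
        ss = share_cents(tariff.base_cents, tariff.ss_consultation_share)
    if visit.age > tariff.adult_age_threshold:
        ss -= tariff.lump_sum_cents
    ss = min(max(ss, 0), total)
    return ConsultationCost(ss, total - ss, total, True)


def drug_line_split(line: DrugLine, tariff: TariffSchedule, *,
                    minor: bool = False) -> Split:
    """Payer split for one prescribed medicine.

    ``minor`` matters only when the tariff's child franchise exemption is
    switched on.
    """
    total = line.total_cents
    rate = 1.0 if line.dld_related else line.tier
    if rate == 0.0:
        return Split(0, total, total)
    reimbursed = share_cents(total, rate)
    franchise = tariff.franchise_cents * line.n_boxes
    if minor and tariff.franchise_exempt_children:
        franchise = 0
    ss = max(0, reimbursed - franchise)
    return Split(ss, total - ss, total)


def prescription_cost(visit: PatientVisit, tariff: TariffSchedule) -> Split:
    """Component-wise sum of the visit's drug-line splits."""
    minor = visit.age <= tariff.adult_age_threshold
    ss = total = 0
    for line in visit.drug_lines:
        s = drug_line_split(line, tariff, minor=minor)
        ss += s.ss
        total += s.total
    return Split(ss, total - ss, total)


def total_management_cost(visit: PatientVisit, tariff: TariffSchedule) -> CostBreakdown:
    """Assemble the full nine-cell breakdown for one visit."""
    cons = consultation_cost(visit, tariff)
    rx = prescription_cost(visit, tariff)
    c = int(cons.costed)
    return CostBreakdown(
        visit_id=visit.visit_id,
        consultation_ss=cons.ss,
        consultation_remaining=cons.remaining,
        consultation_total=cons.total,
        prescription_ss=rx.ss,
        prescription_remaining=rx.remaining,
        prescription_total=rx.total,
        total_ss=c * cons.ss + rx.ss,
        total_remaining=c * cons.remaining + rx.remaining,
        health_expenditure=c * cons.total + rx.total,
        consultation_costed=cons.costed,
    )


def cost_visits(visits: list[PatientVisit], tariff: TariffSchedule | None = None
                ) -> list[CostBreakdown]:
    tariff = tariff or TariffSchedule()
    return [total_management_cost(v, tariff) for v in visits]


# ---------------------------------------------------------------------------
# vectorized path over the two-table layout

def _price_cents(series: pd.Series) -> np.ndarray:
    return np.rint(series.astype(float).to_numpy() * 100).astype(np.int64)


def cost_frames(visits_df: pd.DataFrame, drugs_df: pd.DataFrame,
                tariff: TariffSchedule | None = None) -> pd.DataFrame:
    """Vectorized engine: cent-valued breakdown frame, one row per visit.

    Row order follows ``visits_df``.  Produces exactly the numbers of the
    scalar path (the per-line half-up rounding and zero floor are applied
    identically).
    """
    tariff = tariff or TariffSchedule()
    n = len(visits_df)
    sector = visits_df["sector"].astype(str).to_numpy()
    age = visits_df["age"].to_numpy(dtype=np.int64)
    dld = visits_df["has_dld"].astype(bool).to_numpy()

    costed = sector != Sector.NUA.value
    cons_total = np.where(sector == Sector.S2.value,
                          tariff.tariff_s2_cents, tariff.tariff_s1_cents)
    cons_total = np.where(costed, cons_total, 0).astype(np.int64)
    ss_nondld = share_cents(tariff.base_cents, tariff.ss_consultation_share)
    cons_ss = np.where(dld, tariff.base_cents, ss_nondld).astype(np.int64)
    cons_ss -= (age > tariff.adult_age_threshold) * tariff.lump_sum_cents
    cons_ss = np.clip(cons_ss, 0, cons_total)
    cons_rem = cons_total - cons_ss

    rx = pd.DataFrame(
        {"prescription_ss": np.zeros(n, dtype=np.int64),
         "prescription_total": np.zeros(n, dtype=np.int64)},
        index=visits_df["visit_id"].astype(str),
    )
    if drugs_df is not None and len(drugs_df):
        price = _price_cents(drugs_df["unit_price"])
        boxes = drugs_df["n_boxes"].to_numpy(dtype=np.int64)
        total = price * boxes
        tier_bp = np.rint(drugs_df["tier"].astype(float).to_numpy() * 10000).astype(np.int64)
        rate_bp = np.where(drugs_df["dld_related"].astype(bool).to_numpy(), 10000, tier_bp)
        reimbursed = (total * rate_bp + 5000) // 10000
        franchise = tariff.franchise_cents * boxes
        if tariff.franchise_exempt_children:
            adult_by_visit = pd.Series(age > tariff.adult_age_threshold,
                                       index=rx.index)
            # duplicated visit_ids would make the lookup ambiguous
            adult_by_visit = adult_by_visit[~adult_by_visit.index.duplicated()]
            is_adult = adult_by_visit.reindex(
                drugs_df["visit_id"].astype(str)).fillna(True).to_numpy(dtype=bool)
            franchise = np.where(is_adult, franchise, 0)
        line_ss = np.where(rate_bp == 0, 0,
                           np.maximum(0, reimbursed - franchise))
        per_visit = (
            pd.DataFrame({"visit_id": drugs_df["visit_id"].astype(str),
                          "prescription_ss": line_ss,
                          "prescription_total": total})
            .groupby("visit_id")[["prescription_ss", "prescription_total"]]
            .sum()
        )
        rx.update(per_visit)
        rx = rx.astype(np.int64)

    rx_ss = rx["prescription_ss"].to_numpy()
    rx_total = rx["prescription_total"].to_numpy()
    rx_rem = rx_total - rx_ss
    c = costed.astype(np.int64)
    out = pd.DataFrame({
        "visit_id": visits_df["visit_id"].astype(str).to_numpy(),
        "consultation_ss": cons_ss,
        "consultation_remaining": cons_rem,
        "consultation_total": cons_total,
        "prescription_ss": rx_ss,
        "prescription_remaining": rx_rem,
        "prescription_total": rx_total,
        "total_ss": c * cons_ss + rx_ss,
        "total_remaining": c * cons_rem + rx_rem,
        "health_expenditure": c * cons_total + rx_total,
        "consultation_costed": costed,
    })
    return out


def breakdowns_from_frame(df: pd.DataFrame) -> list[CostBreakdown]:
    return [
        CostBreakdown(
            visit_id=str(rec["visit_id"]),
            **{f: int(rec[f]) for f in CostBreakdown.MONEY_FIELDS},
            consultation_costed=bool(rec["consultation_costed"]),
        )
        for rec in df.to_dict("records")
    ]
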