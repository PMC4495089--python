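"""CSV and YAML plumbing.

Two-file tabular layout: ``visits.csv`` (one row per consultation, with the
GP's group/sector, patient context and non-medicinal prescription flags) and
``druglines.csv`` (one row per prescribed medicine, joined on ``visit_id``).
The tariff schedule travels as YAML mirroring :class:`~gpcost.model.TariffSchedule`.

Readers validate every domain invariant and report schema problems by column
name and row-level problems by row number.  Unknown columns in ``visits.csv``
(gender, professional group, quality-of-life scores, ...) are carried through
untyped.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pydantic
import yaml

from .errors import SchemaError, ValidationError
from .model import (
    NONMEDICINAL_FLAGS,
    CostBreakdown,
    DrugLine,
    GeneralPractitioner,
    PatientVisit,
    PracticeGroup,
    Sector,
    TariffSchedule,
)
from .money import fmt_euros, to_cents

VISIT_COLUMNS = (
    "visit_id", "practice_group", "sector", "age",
    "has_dld", "has_supplementary_insurance",
    "sick_leave", "sick_leave_days",
    "radiology", "ct_scan", "mri", "lab_test",
    "nursing", "physiotherapy", "specialist_referral",
)
DRUGLINE_COLUMNS = (
    "visit_id", "unit_price", "n_boxes", "tier",
    "dld_related", "is_homeopathic", "drug_class",
)
BREAKDOWN_COLUMNS = CostBreakdown.MONEY_FIELDS + ("consultation_costed",)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


def _as_bool(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValidationError(f"column {column}: not a boolean: {value!r}", row=row)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def read_visit_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"visit_id": str})
    _require_columns(df, VISIT_COLUMNS, Path(path).name)
    return df


def read_drugline_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"visit_id": str, "drug_class": str})
    _require_columns(df, DRUGLINE_COLUMNS, Path(path).name)
    return df


def visits_from_frames(
    visits_df: pd.DataFrame,
    drugs_df: pd.DataFrame | None = None,
    tariff: TariffSchedule | None = None,
) -> list[PatientVisit]:
    """Build validated :class:`PatientVisit` objects from the two tables.

    Row order of both tables is preserved; drug lines attach to their visit in
    file order.  ``tariff`` (default 2008 schedule) supplies the admissible
    reimbursement tiers.
    """
    tariff = tariff or TariffSchedule()
    lines_by_visit: dict[str, list[DrugLine]] = {}
    if drugs_df is not None and len(drugs_df):
        for row_no, rec in enumerate(drugs_df.to_dict("records")):
            cls = rec.get("drug_class")
            if cls is not None and (pd.isna(cls) or str(cls) == ""):
                cls = None
            try:
                line = DrugLine(
                    unit_price=rec["unit_price"],
                    n_boxes=int(rec["n_boxes"]),
                    tier=float(rec["tier"]),
                    dld_related=_as_bool(rec["dld_related"], "dld_related", row_no),
                    is_homeopathic=_as_bool(rec["is_homeopathic"], "is_homeopathic", row_no),
                    drug_class=None if cls is None else str(cls),
                )
            except ValidationError as exc:
                raise ValidationError(str(exc), row=row_no) from None
            if line.tier not in set(tariff.drug_tiers):
                raise ValidationError(
                    f"tier {line.tier} not in {sorted(tariff.drug_tiers)}", row=row_no)
            lines_by_visit.setdefault(str(rec["visit_id"]), []).append(line)

    visits: list[PatientVisit] = []
    known = set(VISIT_COLUMNS) | {"gp_id"}
    for row_no, rec in enumerate(visits_df.to_dict("records")):
        vid = str(rec["visit_id"])
        try:
            group = PracticeGroup(str(rec["practice_group"]))
            sector = Sector(str(rec["sector"]))
        except ValueError as exc:
            raise ValidationError(str(exc), row=row_no) from None
        flags = {f for f in NONMEDICINAL_FLAGS if _as_bool(rec[f], f, row_no)}
        gp = GeneralPractitioner(
            gp_id=str(rec.get("gp_id", f"gp_{vid}")),
            practice_group=group,
            sector=sector,
        )
        try:
            visit = PatientVisit(
                visit_id=vid,
                gp=gp,
                age=int(rec["age"]),
                has_dld=_as_bool(rec["has_dld"], "has_dld", row_no),
                has_supplementary_insurance=_as_bool(
                    rec["has_supplementary_insurance"], "has_supplementary_insurance", row_no),
                drug_lines=lines_by_visit.get(vid, []),
                nonmedicinal=flags,
                sick_leave_days=int(rec["sick_leave_days"]),
                extra={k: v for k, v in rec.items() if k not in known},
            )
            visit.validate_against(tariff)
        except ValidationError as exc:
            raise ValidationError(str(exc), row=row_no) from None
        visits.append(visit)

    orphan = set(lines_by_visit) - {v.visit_id for v in visits}
    if orphan:
        raise ValidationError(
            f"drug lines reference unknown visit_id(s): {sorted(orphan)[:5]}")
    return visits


def read_visits(
    visits_path: str | Path,
    druglines_path: str | Path | None = None,
    tariff: TariffSchedule | None = None,
) -> list[PatientVisit]:
    """Read and validate the two-file cohort layout."""
    vdf = read_visit_frame(visits_path)
    ddf = read_drugline_frame(druglines_path) if druglines_path else None
    return visits_from_frames(vdf, ddf, tariff)


def frames_from_visits(visits: list[PatientVisit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`visits_from_frames` (extras included, order kept)."""
    vrows, drows = [], []
    for v in visits:
        row = {
            "visit_id": v.visit_id,
            "practice_group": v.gp.practice_group.value,
            "sector": v.gp.sector.value,
            "age": v.age,
            "has_dld": int(v.has_dld),
            "has_supplementary_insurance": int(v.has_supplementary_insurance),
            "sick_leave_days": v.sick_leave_days,
        }
        for f in NONMEDICINAL_FLAGS:
            row[f] = int(f in v.nonmedicinal)
        row.update(v.extra)
        vrows.append(row)
        for line in v.drug_lines:
            drows.append({
                "visit_id": v.visit_id,
                "unit_price": f"{line.unit_price:.2f}",
                "n_boxes": line.n_boxes,
                "tier": line.tier,
                "dld_related": int(line.dld_related),
                "is_homeopathic": int(line.is_homeopathic),
                "drug_class": line.drug_class or "",
            })
    cols = list(VISIT_COLUMNS)
    extra_cols = [c for c in (vrows[0] if vrows else {}) if c not in cols]
    vdf = pd.DataFrame(vrows, columns=cols + extra_cols)
    ddf = pd.DataFrame(drows, columns=list(DRUGLINE_COLUMNS))
    return vdf, ddf


def write_breakdowns(breakdowns, path: str | Path) -> None:
    """Write one CSV row per visit, money cells formatted to the cent.

    Accepts a list of :class:`CostBreakdown` or the engine's cent-valued
    frame; reading the file back round-trips every field exactly.
    """
    if isinstance(breakdowns, pd.DataFrame):
        df = breakdowns.copy()
    else:
        df = pd.DataFrame(
            [{"visit_id": b.visit_id,
              **{f: getattr(b, f) for f in CostBreakdown.MONEY_FIELDS},
              "consultation_costed": b.consultation_costed}
             for b in breakdowns],
            columns=["visit_id", *BREAKDOWN_COLUMNS],
        )
    out = pd.DataFrame({"visit_id": df["visit_id"].astype(str)})
    for f in CostBreakdown.MONEY_FIELDS:
        out[f] = [fmt_euros(int(c)) for c in df[f]]
    out["consultation_costed"] = df["consultation_costed"].astype(bool).astype(int)
    out.to_csv(path, index=False)


def read_breakdowns(path: str | Path) -> list[CostBreakdown]:
    df = pd.read_csv(path, dtype={"visit_id": str})
    _require_columns(df, ("visit_id", *BREAKDOWN_COLUMNS), Path(path).name)
    return [
        CostBreakdown(
            visit_id=str(rec["visit_id"]),
            **{f: to_cents(str(rec[f])) for f in CostBreakdown.MONEY_FIELDS},
            consultation_costed=bool(int(rec["consultation_costed"])),
        )
        for rec in df.to_dict("records")
    ]


def load_tariff(path: str | Path) -> TariffSchedule:
    """Load a tariff schedule from YAML; bad keys raise a schema error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{Path(path).name}: expected a mapping of tariff fields")
    unknown = set(raw) - set(TariffSchedule.model_fields)
    if unknown:
        raise SchemaError(
            f"{Path(path).name}: unknown tariff key(s) {', '.join(sorted(unknown))}")
    try:
        return TariffSchedule(**{k: str(v) if isinstance(v, float) and
                                 k.startswith(("consultation", "contractual", "adult_lump", "franchise_per"))
                                 else v for k, v in raw.items()})
    except pydantic.ValidationError as exc:
        bad = ", ".join(str(e["loc"][0]) for e in exc.errors() if e["loc"])
        raise SchemaError(f"{Path(path).name}: invalid value for {bad or 'tariff'}") from exc


def save_tariff(tariff: TariffSchedule, path: str | Path) -> None:
    data = tariff.model_dump()
    for k, v in data.items():
        if hasattr(v, "quantize"):
            data[k] = float(v)
        elif isinstance(v, tuple):
            data[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
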