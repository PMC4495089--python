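"""Domain types for the 2008 French general-practice costing model.

The unit of analysis is one consultation (visit) with a general practitioner
(GP).  Each visit carries the GP's practice group (conventional CM, mixed Mx,
homeopathic Ho) and contract sector, the patient context that drives cost
attribution (age, long-duration-disease status, supplementary insurance), the
prescribed drug lines, and the non-medicinal prescription flags that are
described but never costed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal

from pydantic import BaseModel, Field, model_validator

from .errors import ValidationError
from .money import to_cents, to_euros

DRUG_TIERS = (0.00, 0.35, 0.65, 1.00)

NONMEDICINAL_FLAGS = (
    "sick_leave",
    "radiology",
    "ct_scan",
    "mri",
    "lab_test",
    "nursing",
    "physiotherapy",
    "specialist_referral",
)


class PracticeGroup(str, enum.Enum):
    """GP prescribing-practice group: conventional, mixed, homeopathic."""

    CM = "CM"
    Mx = "Mx"
    Ho = "Ho"


class Sector(str, enum.Enum):
    """GP contract sector.

    S1 charges the statutory tariff, S2 sets free fees (reimbursed on the
    contractual base), NUA ("not under agreement") GPs are outside the
    statutory contract: their consultation fee is not reimbursed and cannot
    be costed, though their prescriptions are.
    """

    S1 = "S1"
    S2 = "S2"
    NUA = "NUA"


class TariffSchedule(BaseModel):
    """All monetary parameters of the 2008 costing model.

    Defaults are the 2008 statutory values: 22 EUR sector-1 consultation,
    32 EUR sector-2, Social Security (SS) pays 70 % of the 22 EUR contractual
    base (100 % for long-duration-disease care), a 1 EUR per-consultation
    lump sum for adults (age strictly above ``adult_age_threshold``) and a
    0.25 EUR per-box franchise on reimbursed medicines, both charged to the
    patient side by netting against the SS share.
    """

    consultation_tariff_sector1: Decimal = Decimal("22.00")
    consultation_tariff_sector2: Decimal = Decimal("32.00")
    contractual_base: Decimal = Decimal("22.00")
    ss_consultation_share: float = Field(0.70, ge=0.0, le=1.0)
    adult_lump_sum: Decimal = Decimal("1.00")
    adult_age_threshold: int = 18
    franchise_per_box: Decimal = Decimal("0.25")
    drug_tiers: tuple[float, ...] = DRUG_TIERS
    # French law exempts minors from the per-box franchise; the source model
    # applies it unconditionally, so the exemption ships as an opt-in switch.
    franchise_exempt_children: bool = False

    @model_validator(mode="after")
    def _check(self) -> "TariffSchedule":
        for name in ("consultation_tariff_sector1", "consultation_tariff_sector2",
                     "contractual_base", "adult_lump_sum", "franchise_per_box"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.consultation_tariff_sector2 < self.consultation_tariff_sector1:
            raise ValueError("sector-2 tariff must be >= sector-1 tariff")
        if not all(0.0 <= t <= 1.0 for t in self.drug_tiers):
            raise ValueError("drug tiers must lie in [0, 1]")
        return self

    # cent views used by the engine
    @property
    def tariff_s1_cents(self) -> int:
        return to_cents(self.consultation_tariff_sector1)

    @property
    def tariff_s2_cents(self) -> int:
        return to_cents(self.consultation_tariff_sector2)

    @property
    def base_cents(self) -> int:
        return to_cents(self.contractual_base)

    @property
    def lump_sum_cents(self) -> int:
        return to_cents(self.adult_lump_sum)

    @property
    def franchise_cents(self) -> int:
        return to_cents(self.franchise_per_box)


@dataclass(frozen=True)
class GeneralPractitioner:
    gp_id: str
    practice_group: PracticeGroup
    sector: Sector


@dataclass
class DrugLine:
    """One prescribed medicine: unit price per box, box count, statutory tier.

    ``dld_related`` marks medicines tied to the patient's long-duration
    disease, which Social Security covers at 100 % regardless of tier.
    """

    unit_price: Decimal
    n_boxes: int
    tier: float
    dld_related: bool = False
    is_homeopathic: bool = False
    drug_class: str | None = None

    def __post_init__(self) -> None:
        self.unit_price = to_euros(to_cents(self.unit_price))
        if self.unit_price < 0:
            raise ValidationError("unit_price must be >= 0")
        if self.n_boxes < 1:
            raise ValidationError("n_boxes must be >= 1")

    @property
    def total_cents(self) -> int:
        return to_cents(self.unit_price) * self.n_boxes


@dataclass
class PatientVisit:
    visit_id: str
    gp: GeneralPractitioner
    age: int
    has_dld: bool
    has_supplementary_insurance: bool
    drug_lines: list[DrugLine] = field(default_factory=list)
    nonmedicinal: set[str] = field(default_factory=set)
    sick_leave_days: int = 0
    extra: dict = field(default_factory=dict)  # pass-through columns, untyped

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError("age must be >= 0")
        if self.sick_leave_days < 0:
            raise ValidationError("sick_leave_days must be >= 0")
        if self.sick_leave_days > 0 and "sick_leave" not in self.nonmedicinal:
            raise ValidationError(
                "sick_leave_days > 0 requires the sick_leave flag")
        unknown = self.nonmedicinal - set(NONMEDICINAL_FLAGS)
        if unknown:
            raise ValidationError(f"unknown non-medicinal flags: {sorted(unknown)}")

    def validate_against(self, tariff: TariffSchedule) -> None:
        """Check tier membership and the DLD/line consistency invariant."""
        tiers = set(tariff.drug_tiers)
        for i, line in enumerate(self.drug_lines):
            if line.tier not in tiers:
                raise ValidationError(
                    f"drug line {i}: tier {line.tier} not in {sorted(tiers)}")
            if line.dld_related and not self.has_dld:
                raise ValidationError(
                    f"drug line {i}: dld_related on a visit without DLD status")


@dataclass
class CostBreakdown:
    """The nine-cell payer-by-component cost grid for one visit, in cents.

    Rows: consultation, prescription, total (= their sum when the
    consultation could be costed).  Columns: Social Security share, remaining
    cost (patient and/or supplementary insurer, not separable), and their sum
    -- the health expenditure.  ``consultation_costed`` is False for visits
    to a not-under-agreement GP, whose fee cannot be counted.
    """

    visit_id: str
    consultation_ss: int
    consultation_remaining: int
    consultation_total: int
    prescription_ss: int
    prescription_remaining: int
    prescription_total: int
    total_ss: int
    total_remaining: int
    health_expenditure: int
    consultation_costed: bool

    MONEY_FIELDS = (
        "consultation_ss", "consultation_remaining", "consultation_total",
        "prescription_ss", "prescription_remaining", "prescription_total",
        "total_ss", "total_remaining", "health_expenditure",
    )

    def __post_init__(self) -> None:
        for name in self.MONEY_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for row in ("consultation", "prescription"):
            ss = getattr(self, f"{row}_ss")
            rem = getattr(self, f"{row}_remaining")
            if ss + rem != getattr(self, f"{row}_total"):
                raise ValidationError(f"{row}: ss + remaining != total")
        if self.total_ss + self.total_remaining != self.health_expenditure:
            raise ValidationError("total: ss + remaining != health expenditure")
        cons = int(self.consultation_costed)
        for col, tot in (("ss", self.total_ss),
                         ("remaining", self.total_remaining)):
            expected = (cons * getattr(self, f"consultation_{col}")
                        + getattr(self, f"prescription_{col}"))
            if tot != expected:
                raise ValidationError(f"total_{col} != consultation + prescription")
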