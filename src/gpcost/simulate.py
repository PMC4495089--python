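"""Seeded synthetic cohort with the marginal structure of the EPI3 survey.

No patient-level data accompany the published evaluation, so every
downstream stage (costing, group comparison, reporting) is exercised on a
synthetic cohort whose *marginals* match the published tables: per-group
sizes, sector mix, long-duration-disease (DLD) prevalence, non-medicinal
prescription rates, and per-reimbursement-tier drug counts.  Joint structure
the tables never report (DLD x drug count, price laws, ...) is modelled with
simple conventional choices and documented in the methods note.

Drug counts are generated per reimbursement tier as independent negative
binomials matched to the published per-tier (mean, SD) — the published
headline drugs-per-prescription moments are then an emergent property (the
implied mean is the sum of per-tier means), checked by
:func:`validate_fidelity`, not a constraint.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import epi3
from .errors import SchemaError
from .model import NONMEDICINAL_FLAGS

logger = logging.getLogger(__name__)

TIER_LEVELS = {"nonreimbursable": 0.0, "tier35": 0.35, "tier65": 0.65}

#: per-line probability of a therapeutic-class tag (descriptive only);
#: Ho-GPs prescribe fewer analgesics/NSAIDs, antibiotics and psychotropics.
DEFAULT_CLASS_PROBS = {
    "CM": {"N02": 0.10, "M01": 0.08, "R01": 0.03, "J01": 0.04,
           "N05B": 0.03, "N05C": 0.015, "N06A": 0.03},
    "Mx": {"N02": 0.09, "M01": 0.07, "R01": 0.027, "J01": 0.035,
           "N05B": 0.024, "N05C": 0.012, "N06A": 0.024},
    "Ho": {"N02": 0.05, "M01": 0.04, "R01": 0.01, "J01": 0.02,
           "N05B": 0.016, "N05C": 0.009, "N06A": 0.015},
}

DEFAULT_NONMEDICINAL_RATES = {
    flag: {g: yes / (yes + no) for g, (yes, no) in by_group.items()}
    for flag, by_group in epi3.NONMEDICINAL_COUNTS.items()
}

#: per-line homeopathic probabilities chosen so the homeopathic-only /
#: conventional-only / mixed prescription split lands near the published one
DEFAULT_HOMEO_PROB = {"CM": 0.002, "Mx": 0.03, "Ho": 0.45}


class CohortConfig(BaseModel):
    """Generator parameters; defaults are the published EPI3 marginals."""

    group_sizes: dict[str, int] = Field(default_factory=lambda: dict(epi3.GROUP_SIZES))
    sector2_share: dict[str, float] = Field(default_factory=lambda: dict(epi3.SECTOR2_SHARE))
    nua_share: dict[str, float] = Field(default_factory=lambda: dict(epi3.NUA_SHARE))
    dld_prevalence: dict[str, float] = Field(default_factory=lambda: dict(epi3.DLD_PREVALENCE))
    adult_share: float = 0.85
    supplementary_share: dict[str, float] = Field(
        default_factory=lambda: {"CM": 0.94, "Mx": 0.95, "Ho": 0.97})
    drugs_per_rx: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(epi3.DRUGS_PER_RX))
    tier_counts: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=lambda: {t: dict(v) for t, v in epi3.TIER_COUNTS.items()})
    price_median: float = 5.0          # EUR per box, log-normal median
    price_sigma: float = 0.8           # log-scale SD
    p_dld_related: float = 0.5         # per line, DLD patients only
    p_homeopathic: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_HOMEO_PROB))
    nonmedicinal_rates: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {f: dict(v) for f, v in DEFAULT_NONMEDICINAL_RATES.items()})
    sick_leave_days_mean: dict[str, float] = Field(
        default_factory=lambda: dict(epi3.SICK_LEAVE_DAYS_MEAN))
    drug_class_probs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CLASS_PROBS.items()})
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        for name in ("sector2_share", "nua_share", "dld_prevalence",
                     "supplementary_share", "p_homeopathic"):
            if any(not 0 <= p <= 1 for p in getattr(self, name).values()):
                raise ValueError(f"{name} fractions must lie in [0, 1]")
        if not 0 <= self.adult_share <= 1:
            raise ValueError("adult_share must lie in [0, 1]")
        for tier, by_group in self.tier_counts.items():
            if any(m < 0 or s < 0 for m, s in by_group.values()):
                raise ValueError(f"tier_counts[{tier}]: means and SDs must be >= 0")
        for g in self.group_sizes:
            if self.sector2_share.get(g, 0) + self.nua_share.get(g, 0) > 1:
                raise ValueError(f"{g}: sector-2 + NUA share exceeds 1")
        return self

    @property
    def groups(self) -> list[str]:
        return list(self.group_sizes)

    def implied_drugs_per_rx(self, group: str) -> float:
        """Mean drugs per prescription implied by the per-tier means."""
        return sum(self.tier_counts[t][group][0] for t in self.tier_counts)

    def implied_drugs_per_rx_sd(self, group: str) -> float:
        return math.sqrt(sum(self.tier_counts[t][group][1] ** 2
                             for t in self.tier_counts))


def _draw_counts(mean: float, sd: float, n: int, rng: np.random.Generator,
                 label: str = "") -> np.ndarray:
    """Negative-binomial counts matched to (mean, sd); Poisson fallback when
    the variance is not over-dispersed (sd^2 <= mean)."""
    if n == 0 or mean <= 0:
        return np.zeros(n, dtype=np.int64)
    var = sd * sd
    if var > mean:
        r = mean * mean / (var - mean)
        p = mean / var
        return rng.negative_binomial(r, p, size=n)
    logger.info("%s: sd^2 <= mean (%.3g <= %.3g), falling back to Poisson",
                label or "count draw", var, mean)
    return rng.poisson(mean, size=n)


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic cohort; returns (visits, drug lines) frames.

    Deterministic for a fixed config and seed (``seed`` overrides
    ``config.seed``).  Realized group sizes equal the configured sizes
    exactly; all patient-level attributes are drawn independently at the
    configured per-group rates.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    vframes, dframes = [], []
    for g in config.groups:
        n = config.group_sizes[g]
        if n == 0:
            continue
        s2 = config.sector2_share.get(g, 0.0)
        nua = config.nua_share.get(g, 0.0)
        sector = rng.choice(np.array(["S1", "S2", "NUA"]), size=n,
                            p=[1 - s2 - nua, s2, nua])
        has_dld = rng.random(n) < config.dld_prevalence.get(g, 0.0)
        adult = rng.random(n) < config.adult_share
        age = np.where(adult, rng.integers(19, 91, size=n),
                       rng.integers(0, 19, size=n))
        suppl = rng.random(n) < config.supplementary_share.get(g, 1.0)

        flags = {}
        for f in NONMEDICINAL_FLAGS:
            rate = config.nonmedicinal_rates.get(f, {}).get(g, 0.0)
            flags[f] = rng.random(n) < rate
        days_mean = config.sick_leave_days_mean.get(g, 0.0)
        sick_days = np.where(
            flags["sick_leave"],
            1 + rng.poisson(max(days_mean - 1, 0.0), size=n), 0)

        visit_ids = np.array([f"{g}-{i:05d}" for i in range(n)])
        vframes.append(pd.DataFrame({
            "visit_id": visit_ids,
            "practice_group": g,
            "sector": sector,
            "age": age.astype(np.int64),
            "has_dld": has_dld.astype(int),
            "has_supplementary_insurance": suppl.astype(int),
            "sick_leave": flags["sick_leave"].astype(int),
            "sick_leave_days": sick_days.astype(np.int64),
            **{f: flags[f].astype(int) for f in NONMEDICINAL_FLAGS if f != "sick_leave"},
        }))

        for tier_name, tier in TIER_LEVELS.items():
            mean, sd = config.tier_counts[tier_name][g]
            counts = _draw_counts(mean, sd, n, rng, f"{g}/{tier_name}")
            owner = np.repeat(np.arange(n), counts)
            m = len(owner)
            if m == 0:
                continue
            price = rng.lognormal(math.log(config.price_median),
                                  config.price_sigma, size=m)
            price_cents = np.maximum(1, np.rint(price * 100)).astype(np.int64)
            dld_rel = (rng.random(m) < config.p_dld_related) & has_dld[owner]
            homeo = rng.random(m) < config.p_homeopathic.get(g, 0.0)
            cls_probs = config.drug_class_probs.get(g, {})
            classes = list(cls_probs) + [""]
            p = np.array(list(cls_probs.values()) + [0.0])
            p[-1] = 1.0 - p[:-1].sum()
            drug_class = rng.choice(np.array(classes), size=m, p=p)
            dframes.append(pd.DataFrame({
                "visit_id": visit_ids[owner],
                "unit_price": [f"{c / 100:.2f}" for c in price_cents],
                "n_boxes": rng.integers(1, 4, size=m).astype(np.int64),
                "tier": tier,
                "dld_related": dld_rel.astype(int),
                "is_homeopathic": homeo.astype(int),
                "drug_class": drug_class,
            }))

    vcols = ["visit_id", "practice_group", "sector", "age", "has_dld",
             "has_supplementary_insurance", "sick_leave", "sick_leave_days",
             *(f for f in NONMEDICINAL_FLAGS if f != "sick_leave")]
    dcols = ["visit_id", "unit_price", "n_boxes", "tier", "dld_related",
             "is_homeopathic", "drug_class"]
    visits = (pd.concat(vframes, ignore_index=True)[vcols]
              if vframes else pd.DataFrame(columns=vcols))
    if dframes:
        drugs = pd.concat(dframes, ignore_index=True)[dcols]
        drugs = drugs.sort_values("visit_id", kind="stable").reset_index(drop=True)
    else:
        drugs = pd.DataFrame(columns=dcols)
    return visits, drugs


def _z(realized: float, target: float, se: float) -> float:
    if se == 0:
        return 0.0 if realized == target else math.inf
    return (realized - target) / se


def validate_fidelity(visits: pd.DataFrame, drugs: pd.DataFrame,
                      config: CohortConfig | None = None,
                      flag_at: float = 4.0) -> pd.DataFrame:
    """Compare realized marginals with the generator's targets.

    One row per (group, metric): target, realized, binomial / mean standard
    error at the realized group size, z-score and a flag for |z| above
    ``flag_at``.  The drugs-per-prescription target is the value implied by
    the per-tier means (see module docstring).  Empty cohort -> empty report.
    """
    config = config or CohortConfig()
    cols = ["group", "metric", "target", "realized", "se", "z", "flagged"]
    if len(visits) == 0:
        return pd.DataFrame(columns=cols)
    rows = []

    def add(group, metric, target, realized, se):
        z = _z(realized, target, se)
        rows.append({"group": group, "metric": metric, "target": target,
                     "realized": realized, "se": se, "z": z,
                     "flagged": abs(z) > flag_at})

    for g, vg in visits.groupby("practice_group", sort=False):
        n = len(vg)

        def rate(metric, target, realized_count):
            se = math.sqrt(target * (1 - target) / n) if 0 < target < 1 else 0.0
            add(g, metric, target, realized_count / n, se)

        rate("sector2_share", config.sector2_share.get(g, 0.0),
             (vg["sector"] == "S2").sum())
        rate("nua_share", config.nua_share.get(g, 0.0),
             (vg["sector"] == "NUA").sum())
        rate("dld_prevalence", config.dld_prevalence.get(g, 0.0),
             vg["has_dld"].astype(bool).sum())
        rate("adult_share", config.adult_share, (vg["age"] > 18).sum())
        rate("supplementary_share", config.supplementary_share.get(g, 1.0),
             vg["has_supplementary_insurance"].astype(bool).sum())
        for f in NONMEDICINAL_FLAGS:
            rate(f, config.nonmedicinal_rates.get(f, {}).get(g, 0.0),
                 vg[f].astype(bool).sum())

        dg = drugs[drugs["visit_id"].isin(vg["visit_id"])] if len(drugs) else drugs
        per_visit = (dg.groupby("visit_id").size().reindex(vg["visit_id"], fill_value=0)
                     if len(dg) else pd.Series(0, index=vg["visit_id"]))
        add(g, "drugs_per_rx", config.implied_drugs_per_rx(g),
            float(per_visit.mean()),
            config.implied_drugs_per_rx_sd(g) / math.sqrt(n))
        for tier_name, tier in TIER_LEVELS.items():
            mean, sd = config.tier_counts[tier_name][g]
            cnt = ((dg["tier"].astype(float) == tier).groupby(dg["visit_id"]).sum()
                   .reindex(vg["visit_id"], fill_value=0)
                   if len(dg) else pd.Series(0, index=vg["visit_id"]))
            add(g, f"drugs_{tier_name}", mean, float(cnt.mean()),
                sd / math.sqrt(n))

        sl = vg[vg["sick_leave"].astype(bool)]
        if len(sl):
            m = config.sick_leave_days_mean.get(g, 0.0)
            se = math.sqrt(max(m - 1, 0.0) / len(sl))
            add(g, "sick_leave_days_mean", m, float(sl["sick_leave_days"].mean()), se)
    return pd.DataFrame(rows, columns=cols)


def load_cohort_config(path) -> CohortConfig:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping of cohort-config fields")
    unknown = set(raw) - set(CohortConfig.model_fields)
    if unknown:
        raise SchemaError(f"{path}: unknown cohort key(s) {', '.join(sorted(unknown))}")
    import pydantic
    try:
        return CohortConfig(**raw)
    except pydantic.ValidationError as exc:
        bad = ", ".join(str(e["loc"][0]) for e in exc.errors() if e["loc"])
        raise SchemaError(f"{path}: invalid value for {bad or 'cohort config'}") from exc
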