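import numpy as np
import pandas as pd
import pytest

from gpcost.model import TariffSchedule

SECTORS = ("S1", "S2", "NUA")
GROUPS = ("CM", "Mx", "Ho")
TIERS = (0.0, 0.35, 0.65, 1.0)

VISITS_FIXTURE = """\
visit_id,practice_group,sector,age,has_dld,has_supplementary_insurance,sick_leave,sick_leave_days,radiology,ct_scan,mri,lab_test,nursing,physiotherapy,specialist_referral
v1,CM,S1,40,0,1,0,0,0,0,0,0,0,0,0
v2,Ho,S2,10,1,1,1,5,0,0,0,0,0,0,0
v3,Mx,NUA,30,0,0,0,0,0,0,0,1,0,0,0
"""

DRUGLINES_FIXTURE = """\
visit_id,unit_price,n_boxes,tier,dld_related,is_homeopathic,drug_class
v1,10.00,1,0.65,0,0,N02
v1,3.33,2,0.35,0,0,
v2,7.50,1,0.65,1,1,
v2,2.40,3,0.00,0,1,
v3,20.00,1,0.35,0,0,J01
"""

#: hand-computed expected breakdowns (EUR) for the fixture above:
#: v1 adult S1 non-DLD: consultation 14.40/7.60/22.00; lines 6.25 + 1.83
#:   (0.35 x 6.66 = 2.331 -> 2.33, minus 2 x 0.25)
#: v2 child S2 DLD: consultation 22.00/10.00/32.00 (no lump sum); line 1 at
#:   100 % (DLD-related) 7.50 - 0.25 = 7.25; line 2 tier 0 -> 0/7.20
#: v3 NUA: consultation not costed; 0.35 x 20 - 0.25 = 6.75
FIXTURE_EXPECTED = {
    "v1": {"consultation_ss": "14.40", "consultation_remaining": "7.60",
           "consultation_total": "22.00", "prescription_ss": "8.08",
           "prescription_remaining": "8.58", "prescription_total": "16.66",
           "total_ss": "22.48", "total_remaining": "16.18",
           "health_expenditure": "38.66", "consultation_costed": True},
    "v2": {"consultation_ss": "22.00", "consultation_remaining": "10.00",
           "consultation_total": "32.00", "prescription_ss": "7.25",
           "prescription_remaining": "7.45", "prescription_total": "14.70",
           "total_ss": "29.25", "total_remaining": "17.45",
           "health_expenditure": "46.70", "consultation_costed": True},
    "v3": {"consultation_ss": "0.00", "consultation_remaining": "0.00",
           "consultation_total": "0.00", "prescription_ss": "6.75",
           "prescription_remaining": "13.25", "prescription_total": "20.00",
           "total_ss": "6.75", "total_remaining": "13.25",
           "health_expenditure": "20.00", "consultation_costed": False},
}


@pytest.fixture
def tariff():
    return TariffSchedule()


@pytest.fixture
def fixture_files(tmp_path):
    vpath = tmp_path / "visits.csv"
    dpath = tmp_path / "druglines.csv"
    vpath.write_text(VISITS_FIXTURE)
    dpath.write_text(DRUGLINES_FIXTURE)
    return vpath, dpath


def random_cohort_dicts(seed: int, n: int):
    """Random visits/lines as plain dicts, independent of the generator
    module, spanning every sector, tier and patient condition."""
    rng = np.random.default_rng(seed)
    visits, lines = [], []
    for i in range(n):
        vid = f"r{i:06d}"
        has_dld = bool(rng.random() < 0.3)
        visits.append({
            "visit_id": vid,
            "practice_group": GROUPS[rng.integers(3)],
            "sector": SECTORS[rng.integers(3)],
            "age": int(rng.integers(0, 96)),
            "has_dld": has_dld,
            "has_supplementary_insurance": bool(rng.integers(2)),
        })
        for _ in range(int(rng.integers(0, 6))):
            lines.append({
                "visit_id": vid,
                "unit_price": f"{rng.integers(1, 15001) / 100:.2f}",
                "n_boxes": int(rng.integers(1, 6)),
                "tier": float(TIERS[rng.integers(4)]),
                "dld_related": bool(has_dld and rng.random() < 0.4),
                "is_homeopathic": bool(rng.random() < 0.2),
            })
    return visits, lines


def cohort_dicts_to_frames(visits, lines):
    vdf = pd.DataFrame(visits)
    for f in ("sick_leave", "radiology", "ct_scan", "mri", "lab_test",
              "nursing", "physiotherapy", "specialist_referral"):
        vdf[f] = 0
    vdf["sick_leave_days"] = 0
    vdf["has_dld"] = vdf["has_dld"].astype(int)
    vdf["has_supplementary_insurance"] = vdf["has_supplementary_insurance"].astype(int)
    if lines:
        ddf = pd.DataFrame(lines)
        ddf["dld_related"] = ddf["dld_related"].astype(int)
        ddf["is_homeopathic"] = ddf["is_homeopathic"].astype(int)
        ddf["drug_class"] = ""
    else:
        ddf = pd.DataFrame(columns=["visit_id", "unit_price", "n_boxes", "tier",
                                    "dld_related", "is_homeopathic", "drug_class"])
    return vdf, ddf
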