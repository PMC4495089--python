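"""Published marginals of the EPI3 cross-sectional economic evaluation.

The EPI3 La-Ser survey compared French GPs by prescribing practice:
conventional-only (CM), mixed (Mx) and homeopathic (Ho).  The patient-level
data are not public, but the published descriptive tables fix the marginal
structure that the synthetic cohort emulates and that the reporting stage is
checked against: group sizes, sector mix, long-duration-disease (DLD)
prevalence, non-medicinal prescription rates, prescription composition and
the headline per-visit cost means.

All counts and rates here are published values, used as generator targets and
as inputs to the recomputation of derivable statistics (percentages,
chi-squared tests, cost ratios).  Monetary values are 2008 euros.
"""

GROUPS = ("CM", "Mx", "Ho")

GROUP_SIZES = {"CM": 1691, "Mx": 3187, "Ho": 1501}

#: yes/no counts per non-medicinal prescription flag (denominators differ
#: across flags because of missing data).
NONMEDICINAL_COUNTS = {
    "sick_leave": {"CM": (175, 1389), "Mx": (336, 2783), "Ho": (112, 1297)},
    "radiology": {"CM": (104, 1463), "Mx": (183, 2937), "Ho": (79, 1328)},
    "ct_scan": {"CM": (16, 1538), "Mx": (28, 3093), "Ho": (7, 1392)},
    "mri": {"CM": (16, 1535), "Mx": (28, 3087), "Ho": (8, 1390)},
    "lab_test": {"CM": (247, 1322), "Mx": (390, 2736), "Ho": (195, 1209)},
    "nursing": {"CM": (14, 1539), "Mx": (29, 3086), "Ho": (7, 1393)},
    "physiotherapy": {"CM": (97, 1461), "Mx": (180, 2939), "Ho": (106, 1294)},
    "specialist_referral": {"CM": (191, 1354), "Mx": (311, 2792), "Ho": (133, 1261)},
}

SECTOR2_SHARE = {"CM": 0.069, "Mx": 0.049, "Ho": 0.493}
NUA_SHARE = {"CM": 0.0, "Mx": 0.005, "Ho": 0.02}
DLD_PREVALENCE = {"CM": 0.295, "Mx": 0.28, "Ho": 0.187}

#: mean [SD] drugs per prescription (headline) and per reimbursement tier
DRUGS_PER_RX = {"CM": (3.1, 2.1), "Mx": (2.8, 1.9), "Ho": (3.5, 2.2)}
TIER_COUNTS = {  # (mean, sd) per prescription
    "nonreimbursable": {"CM": (0.2, 0.4), "Mx": (0.2, 0.5), "Ho": (0.3, 0.6)},
    "tier35": {"CM": (0.7, 0.9), "Mx": (0.8, 1.1), "Ho": (2.0, 1.9)},
    "tier65": {"CM": (2.2, 1.9), "Mx": (1.9, 1.6), "Ho": (1.1, 1.5)},
}

SICK_LEAVE_DAYS_MEAN = {"CM": 11.0, "Mx": 13.0, "Ho": 12.0}

#: published per-visit cost means (EUR), by payer perspective and component
COST_MEANS = {
    "ss": {"CM": 65.25, "Mx": 60.51, "Ho": 42.00},
    "ss_consultation": {"CM": 16.49, "Mx": 16.21, "Ho": 15.81},
    "ss_prescription": {"CM": 48.68, "Mx": 43.87, "Ho": 25.62},
    "remaining": {"CM": 21.35, "Mx": 21.08, "Ho": 26.89},
    "remaining_consultation": {"CM": 6.19, "Mx": 6.27, "Ho": 11.20},
    "remaining_prescription": {"CM": 15.24, "Mx": 15.28, "Ho": 15.87},
    "expenditure": {"CM": 86.63, "Mx": 81.60, "Ho": 68.93},
    "expenditure_consultation": {"CM": 22.68, "Mx": 22.49, "Ho": 27.08},
    "expenditure_prescription": {"CM": 63.72, "Mx": 59.03, "Ho": 41.67},
}

#: share of prescriptions that are homeopathic-only / conventional-only / mixed
PRESCRIPTION_TYPE_SHARE = {
    "homeopathic_only": {"CM": 0.001, "Mx": 0.018, "Ho": 0.249},
    "conventional_only": {"CM": 0.911, "Mx": 0.834, "Ho": 0.289},
    "mixed": {"CM": 0.005, "Mx": 0.057, "Ho": 0.320},
}
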