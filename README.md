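# gpcost

Micro-costing of French general-practice care by payer perspective, built
around the EPI3 cross-sectional comparison of three prescribing practices:
conventional-only GPs (CM), mixed practices (Mx) and homeopathic GPs (Ho).
The package is for health economists and pharmacoepidemiologists who want to
(re)run a multi-payer cost decomposition of GP consultations and drug
prescriptions under the 2008 French tariff rules — and, because the original
patient-level data are not public, to do so on synthetic cohorts that match
the published marginal structure.

## The costing model

For each visit the engine fills a 3 × 3 grid — components (consultation,
prescription, total) by payers (Social Security *SS*, remaining cost *R* to
the patient and/or supplementary insurer, health expenditure *E = SS + R*):

**Consultation.** The charged fee is the sector tariff, `T = 22 €` (sector 1)
or `32 €` (sector 2). Social Security reimburses on the contractual base
`B = 22 €` only:

```
SS_cons = clip( s·B − 1€·[age > 18], 0, T )        s = 0.70, or 1.00 with DLD
R_cons  = T − SS_cons
```

where DLD (*affection longue durée*) is the long-duration-disease status that
grants 100 % statutory coverage of related care, and the 1 € adult lump sum
(*participation forfaitaire*) is netted off the SS share. The whole sector-2
excess (`T − B = 10 €`) falls on the patient side. Consultations with GPs
"not under agreement" (NUA) are not reimbursed and cannot be costed: they are
flagged and excluded from consultation-cost means, while their prescriptions
are costed normally.

**Prescription.** Per drug line with unit price `p`, `n` boxes and statutory
reimbursement tier `t ∈ {0, 0.35, 0.65, 1}` (forced to 1 for DLD-related
medicines):

```
total   = p·n
SS_line = max(0, round(t·p·n) − 0.25€·n)    if t > 0, else 0
```

with the 0.25 € per-box franchise (*franchise médicale*) charged to the
patient side and the reimbursement rounded half-up to the cent once per line.
All arithmetic is exact integer cents; `SS + R = total` holds to the cent in
every cell.

## Worked example

```python
from gpcost import (TariffSchedule, GeneralPractitioner, PatientVisit,
                    DrugLine, PracticeGroup, Sector, total_management_cost)

tariff = TariffSchedule()          # 2008 statutory defaults
gp = GeneralPractitioner("g1", PracticeGroup.CM, Sector.S1)
visit = PatientVisit("v1", gp, age=40, has_dld=False,
                     has_supplementary_insurance=True,
                     drug_lines=[DrugLine("10.00", 1, 0.65)])
b = total_management_cost(visit, tariff)
print(b.total_ss, b.total_remaining, b.health_expenditure)  # cents
```

prints `2065 1135 3200`: Social Security pays 14.40 € of the 22 € consultation
(70 % of 22 € minus the 1 € lump sum) plus 6.25 € of the 10 € medicine (65 %
minus one 0.25 € franchise); the remaining 11.35 € falls to the patient and/or
supplementary insurer; health expenditure is 32.00 €.

The full analysis chain runs from four scripts (or `gpcost pipeline`):

```bash
python analysis/01_simulate_cohort.py --seed 1   # 6379-visit synthetic cohort
python analysis/02_cost_visits.py                # cost every visit
python analysis/03_compare_groups.py             # tables + ANOVA/chi-squared
python analysis/04_published_checks.py           # recompute printed numbers
```

With seed 1 the cohort realizes all 54 configured marginals within 1.9 SE,
and the comparison stage prints the sector-mix signature of the published
consultation costs —

```
total consultation  CM 22.75 vs Ho 26.89 EUR
SS consultation     CM 16.58 vs Ho 15.75 EUR
```

— homeopathic GPs sit in the free-fee sector 2 far more often (49.3 % vs
6.9 %), so their consultations cost more in total yet slightly *less* to
Social Security (fewer DLD patients at 100 % coverage). The published-number
checks print, among others, the sick-leave chi-squared `p = 0.0051` and the
headline 20 % health-expenditure saving (68.93 € vs 86.63 €).

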