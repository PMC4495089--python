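# Methods

## The costing model

The unit of analysis is one consultation with a general practitioner,
together with the medicines prescribed at that consultation. Costs are
attributed under the 2008 French tariff rules from three perspectives:
Social Security (the compulsory statutory insurer), the *remaining* cost
(patient out-of-pocket pooled with supplementary-insurance payments — the
two cannot be separated because supplementary contracts vary per patient),
and their sum, the health expenditure. Hospital admissions, home visits and
the monetary value of sick leave are outside the model; sick leave is
described in physical units only.

Consultation attribution: the charged fee is the sector tariff (22 € sector
1, 32 € sector 2). Social Security reimburses its share of the 22 €
*contractual base*, not of the charged fee — 70 % normally, 100 % for
patients with a long-duration disease (DLD) — so the sector-2 excess falls
entirely on the patient side. The 1 € per-consultation lump sum for patients
strictly older than 18 is netted off the Social-Security share (floored at
zero); it applies to DLD patients too, since the rule conditions only on
age. Consultations with "not under agreement" (NUA) GPs are not reimbursed
at all and cannot be priced; such visits carry a `consultation_costed =
False` flag, contribute zero to consultation costs, are excluded from
consultation-cost and total-cost group comparisons, and keep their
prescriptions costed normally.

Prescription attribution: per line, total = unit price × boxes; the
statutory reimbursement is tier × total with tier ∈ {0, 35, 65, 100} %,
forced to 100 % for DLD-related lines (DLD coverage applies to medicines
related to the pathology, hence a per-line flag rather than a per-visit
rule). The 0.25 € per-box franchise is subtracted from the reimbursement,
and the result floored at zero *within the line* (after summing across the
line's boxes, before summing across lines) — deterministic and
order-independent. Tier-0 lines carry no franchise. French law exempts
minors from the franchise; the model applies it unconditionally by default,
with the exemption available as the tariff switch
`franchise_exempt_children` (off by default to match the source rules).

### Numerical conventions

All money is integer euro-cents. The single fractional-cent operation —
tier × line total (e.g. 35 % of 3.33 €) — is rounded half-up to the cent,
once per line. Rounding per line rather than per box matters: half-up per
box then summing can differ by a cent from half-up on the line total; the
per-line convention is fixed here and shared by the scalar and vectorized
engine paths, which are cent-identical by construction (and verified
against a straight-line Decimal reference in the tests). The
Social-Security consultation share is clipped into `[0, charged fee]`; with
the 2008 defaults the clip never binds.

## The synthetic cohort

No patient-level data accompany the published evaluation, so the generator
draws cohorts whose *marginals* match the published tables, with published
defaults: group sizes 1691 (CM) / 3187 (Mx) / 1501 (Ho); sector-2 shares
6.9 / 4.9 / 49.3 %; NUA shares 0 / 0.5 / 2 %; DLD prevalence 29.5 % (CM) and
18.7 % (Ho); non-medicinal prescription rates recomputed from the published
yes/no counts; sick-leave durations 11 / 13 / 12 days (drawn as 1 + Poisson
so the flagged visits always have ≥ 1 day).

Drug counts are drawn per reimbursement tier as independent negative
binomials matched to the published per-tier (mean, SD) — non-reimbursable
0.2/0.2/0.3, 35 %-tier 0.7/0.8/2.0, 65 %-tier 2.2/1.9/1.1 — with a Poisson
fallback (logged) when SD² ≤ mean. The published headline drugs-per-
prescription moments (3.1 [2.1] / 2.8 [1.9] / 3.5 [2.2]) are deliberately
*not* imposed jointly with the per-tier moments: both sets cannot hold at
once (the per-tier means sum to 3.1 / 2.9 / 3.4), so the per-tier values are
treated as the generative truth and the headline as an emergent fidelity
quantity. The fidelity report therefore scores realized drugs-per-
prescription against the implied mean (sum of per-tier means, SD by
independence); the group ordering Ho > CM > Mx matches the published one
either way. No 100 %-tier lines are generated by default — the published
tier table lists none — but the tier remains admissible in data read from
files, and DLD-related lines exercise the 100 % reimbursement path.

Quantities the tables never report are modelled once, conventionally, and
not revisited:

* **Unit prices** — log-normal, median 5 €, σ = 0.8 (a realistic 2008
  ambulatory price scale; engine correctness never depends on the price
  law). Boxes per line uniform on {1, 2, 3}.
* **Age** — a child/adult two-point mixture (adult share 0.85, adult ages
  uniform 19–90, child 0–18), since the costing rules only use the
  >18-years threshold.
* **DLD-relatedness** — Bernoulli(0.5) per line, DLD patients only.
* **Supplementary insurance** — 94 / 95 / 97 % (CM/Mx/Ho); the population
  rate is about 96 % and the homeopathic group is reported as more often
  insured. Descriptive only; it never enters cost attribution.
* **Homeopathic lines** — per-line Bernoulli (0.002 / 0.03 / 0.45) chosen
  so the homeopathic-only / conventional-only / mixed prescription split
  approximates the published one; descriptive only.
* **Therapeutic-class tags** — a small per-line categorical over the ATC
  codes of the published drug-class table, with lower probabilities in the
  Ho group (fewer analgesics/NSAIDs, antibiotics, psychotropics);
  descriptive only.

All attributes are drawn independently within patient. The generator
therefore does **not** reproduce joint structure the tables never report
(DLD × drug count, price × tier, severity effects), nor the published
per-visit cost *levels*, which depend on the real price distribution: a
passing marginal-fidelity or ordering test says the pipeline recovers what
it was configured to produce, not that the synthetic costs equal the
published means. The published cost table enters only through two
structural facts the engine must — and does — induce from the sector and
DLD mixes alone: total consultation cost higher for Ho than CM, and
Social-Security consultation cost slightly lower for Ho.

## Group comparison

Quantitative variables: n, mean, SD, median, Q1, Q3, min, max, missing
count; compared by one-way homoscedastic ANOVA on raw euros, as in the
original analysis, despite the right skew (a `log_scale` option exists, off
by default). The overall p compares all three groups; each other group is
then contrasted with CM by a two-group ANOVA, identical to the pooled
two-sided t-test (F = t²). Qualitative variables: counts and percentages
over non-missing values, compared by Pearson's chi-squared without
continuity correction (the r×c default of the original SAS analysis). Raw
p-values per variable, no multiplicity correction, conventional 5 %
threshold. Degenerate inputs fail loudly: zero chi-squared marginals and
groups with fewer than two observations raise errors naming the offender;
empty groups in descriptives yield missing descriptors, not errors.

## Problem sizes and calibration

The default pipeline runs the full 6 379-visit cohort (≈ 20 000 drug lines)
in about two seconds end to end. The ANOVA type-I calibration uses 1 000
null cohorts of 300 visits per group: with the skewed cost distribution the
F-test is conservative at small n (rejection ≈ 3.5 % at 150/group) and
reaches nominal 5 % behaviour from about 300/group (5.2 % at 300, 4.5 % at
600 over 1 000 replicates), so 300 is the smallest size at which calibration
is a property of the test rather than of the skew. Property suites run on
10 000 generated visits; oracle-equivalence checks on 1 000 random visits
spanning every sector, tier and patient condition.

## Known limitations

* Remaining cost pools patient out-of-pocket and supplementary-insurance
  payments; contract heterogeneity is not modelled.
* Drug prices arrive pre-resolved per line; there is no drug-name → price
  lookup, and the log-normal synthetic price law is a placeholder for a
  price database the package does not ship.
* The sector-2 tariff is the flat 32 € convention of the costing model, not
  an empirical fee-overrun distribution.
* No regression adjustment for the group imbalances (age, gender, DLD) —
  the comparison stage mirrors the original descriptive design, so group
  contrasts carry the same selection-bias caveats.
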