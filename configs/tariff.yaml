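consultation_tariff_sector1: 22.0
consultation_tariff_sector2: 32.0
contractual_base: 22.0
ss_consultation_share: 0.7
adult_lump_sum: 1.0
adult_age_threshold: 18
franchise_per_box: 0.25
drug_tiers:
- 0.0
- 0.35
- 0.65
- 1.0
franchise_exempt_children: false
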