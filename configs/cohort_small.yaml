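# A reduced cohort for quick runs; all unspecified fields keep the
# published EPI3 marginals as defaults (see gpcost.simulate.CohortConfig).
group_sizes: {CM: 300, Mx: 300, Ho: 300}
seed: 1
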