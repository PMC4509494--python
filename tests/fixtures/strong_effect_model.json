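{
  "name": "strong_effect",
  "table": [
    [
      0.02338196782641227,
      0.02338196782641227,
      0.02338196782641227
    ],
    [
      0.02338196782641227,
      0.21043771043771042,
      0.21043771043771042
    ],
    [
      0.02338196782641227,
      0.21043771043771042,
      0.21043771043771042
    ]
  ],
  "mafs": [
    0.4,
    0.4
  ],
  "prevalence": 0.1,
  "_comment": "Synthetic calibrated penetrance model (not a published table): both-minor-allele threshold archetype, shape baseline 1 / elevated 9, MAF 0.4 per causal SNP, prevalence 0.10."
}
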