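study: eldosouky_lep
source: "Eldosouky et al., LEP G2548A (rs7799039) in obese vs non-obese children"
status: partial
units: ng/ml
genotypes: [GG, A_carrier]
conditions: [obese, non_obese]
genotype_differences:        # GG minus A_carrier, within condition
  obese: 4.5
  non_obese: -0.7
condition_means:
  obese: 33.9
  non_obese: 14.5
notes: "Within-genotype condition differences not printed."
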