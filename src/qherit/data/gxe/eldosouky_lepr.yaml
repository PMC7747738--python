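study: eldosouky_lepr
source: "Eldosouky et al., LEPR Gln223Arg (rs1137101) in obese vs non-obese children"
status: partial
units: ng/ml
genotypes: [G_carrier, AA]
conditions: [obese, non_obese]
genotype_differences:        # G_carrier minus AA, within condition
  obese: 3.0
  non_obese: -0.1
condition_means:
  obese: 33.9
  non_obese: 14.5
notes: >
  Within-genotype condition differences were not printed, so the identity is
  under-determined; genotype effects significant in obese (P<=0.004) but not
  non-obese children (P>0.54).
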