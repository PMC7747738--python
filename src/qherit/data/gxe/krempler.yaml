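study: krempler
source: "Krempler et al., IRS-1 codon 972 variant in obese vs non-obese subjects"
status: partial
units: ng/ml
genotypes: [wild_type, variant_carrier]
conditions: [obese, non_obese]
genotype_differences:        # wild_type minus variant_carrier, within condition
  obese: {value: 11.1, se: 2.9}
  non_obese: {value: -0.8, se: 1.7}
condition_means:
  obese: {value: 36.7, se: 1.5}
  non_obese: {value: 8.7, se: 0.5}
notes: >
  The within-genotype obese-minus-non-obese differences were not printed
  (P_interaction = 0.0004), so the consistency identity is under-determined.
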