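study: meirhaeghe1998
source: "Meirhaeghe et al., PPARgamma exon 6 C/T polymorphism in obese vs non-obese subjects"
status: full
units: ng/ml
genotypes: [T_carrier, CC]
conditions: [obese, non_obese]
condition_differences:       # obese minus non-obese, within genotype
  T_carrier: {value: 23.2, se: 3.1}
  CC: {value: 15.4, se: 1.7}
genotype_differences:        # T_carrier minus CC, within condition
  obese: {value: 6.7, se: 3.4}
  non_obese: {value: -1.1, se: 0.8}
condition_means:
  obese: {value: 30.3, se: 1.4}
  non_obese: {value: 12.6, se: 0.4}
notes: "P_interaction < 0.03 as published."
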