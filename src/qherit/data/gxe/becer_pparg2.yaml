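study: becer_pparg2
source: "Becer et al., PPARgamma2 Pro12Ala (rs1801282) in obese vs non-obese subjects"
status: partial
units: ng/ml
genotypes: [AlaAla, Pro_carrier]
conditions: [obese, non_obese]
condition_differences:       # obese minus non-obese, within genotype
  AlaAla: {value: 16.8, se: 2.2}
  Pro_carrier: {value: 11.7, se: 0.8}
notes: "P_interaction = 0.03; genotype differences within condition not printed."
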