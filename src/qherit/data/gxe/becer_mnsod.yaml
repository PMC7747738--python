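study: becer_mnsod
source: "Becer et al., MnSOD Ala16Val (rs4880) in obese vs non-obese subjects"
status: partial
units: ng/ml
genotypes: [ValVal, AlaAla, AlaVal]
conditions: [obese, non_obese]
condition_differences:       # obese minus non-obese, within genotype
  AlaVal: {value: 16.8, se: 1.6}
  ValVal: {value: 19.5, se: 1.3}
  AlaAla: {value: 11.8, se: 1.5}
notes: >
  Published p-values: AlaVal vs AlaAla P=0.02, ValVal vs AlaAla P=0.0001.
  Genotype differences within condition were not printed.
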