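study: becer_lepr
source: "Becer et al., LEPR Q223R (rs1137101) in obese vs non-obese subjects"
status: partial
units: ng/ml
genotypes: [R_carrier, QQ]
conditions: [obese, non_obese]
condition_differences:       # obese minus non-obese, within genotype
  R_carrier: {value: 18.2, se: 1.8}
  QQ: {value: 12.3, se: 2.0}
notes: >
  Genotype differences within condition and exact condition means were not
  printed (obese means described only as nearly three-fold higher);
  P_interaction = 0.05 as published.
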