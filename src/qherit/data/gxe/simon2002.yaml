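study: simon2002
source: "Simon et al., PPARgamma2 Pro12Ala polymorphism in obese vs non-obese T2DM patients"
status: full
units: ng/ml
genotypes: [Pro12Ala, Pro12Pro]
conditions: [obese, non_obese]
condition_differences:       # obese minus non-obese, within genotype
  Pro12Ala: {value: 40.3, se: 10.7}
  Pro12Pro: {value: 7.2, se: 2.2}
genotype_differences:        # Pro12Ala minus Pro12Pro, within condition
  obese: {value: 28.4, se: 10.7}
  non_obese: {value: -4.7, se: 2.5}
condition_means:
  obese: {value: 23.8, se: 1.9}
  non_obese: {value: 13.9, se: 1.1}
notes: "P_interaction = 0.002 as published."
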