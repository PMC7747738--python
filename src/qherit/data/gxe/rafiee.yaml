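study: rafiee
source: "Rafiee et al., APOB Ins/Del polymorphism by carbohydrate intake"
status: full
units: ng/ml
genotypes: [Del_carrier, InsIns]
conditions: [low_carb, high_carb]
condition_differences:       # low-carbohydrate minus high-carbohydrate, within genotype
  Del_carrier: {value: 9.6, se: 1.4}
  InsIns: {value: -0.8, se: 1.3}
genotype_differences:        # Del_carrier minus InsIns, within condition
  low_carb: {value: 7.6, se: 1.1}
  high_carb: {value: -2.8, se: 1.6}
condition_means:
  low_carb: {value: 27.5, se: 0.6}
  high_carb: {value: 24.9, se: 0.8}
notes: "P_interaction = 0.01 as published; high intake defined as >= 54% of energy."
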