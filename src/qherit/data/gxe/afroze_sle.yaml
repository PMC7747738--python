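study: afroze_sle
source: "Afroze et al., LEPR 223A/G in systemic lupus erythematosus patients vs controls"
status: partial
units: ng/ml
genotypes: [G_carrier, AA]
conditions: [sle, control]
genotype_differences:        # G_carrier minus AA, within condition
  sle: {value: 9.2}
condition_means:
  sle: {value: 23.9, se: 1.95}
  control: {value: 14.8, se: 1.04}
notes: >
  SLE genotype difference derived from printed cell means 25.6 +/- 1.2 vs
  16.4 +/- 2.2 ng/ml; the control genotype difference was described as absent
  but not printed, so the identity is under-determined.
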