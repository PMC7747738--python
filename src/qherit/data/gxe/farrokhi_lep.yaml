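study: farrokhi_lep
source: "Farrokhi et al., LEP rs7799039 in multiple sclerosis patients vs matched controls"
status: full
units: ng/ml
genotypes: [GG, AA]
conditions: [ms, control]
condition_differences:       # MS minus control, within genotype
  GG: {value: 8.30, se: 0.69}
  AA: {value: 5.49, se: 0.67}
genotype_differences:        # GG minus AA, within condition
  ms: {value: 7.81, se: 0.66}
  control: {value: 5.00, se: 0.69}
condition_means:
  ms: {value: 15.70, se: 0.28}
  control: {value: 8.39, se: 0.27}
notes: "AG heterozygote MS-minus-control difference 5.14 +/- 0.69 also published."
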