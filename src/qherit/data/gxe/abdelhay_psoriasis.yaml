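study: abdelhay_psoriasis
source: "Abdel Hay et al., LEP G-2548A in psoriasis patients vs healthy controls"
status: partial
units: ng/ml
genotypes: [GG, AA, GA]
conditions: [psoriasis, control]
condition_differences:       # psoriasis minus control, within genotype
  GG: {value: 24.4, se: 1.1}
  GA: {value: 16.3, se: 1.3}
  AA: {value: 12.0, se: 2.1}
condition_means:
  psoriasis: {value: 33.0, se: 0.7}
  control: {value: 14.7, se: 0.34}
notes: "Genotype differences within condition not printed."
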