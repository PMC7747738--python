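study: farrokhi_lepr
source: "Farrokhi et al., LEPR 223A/G in multiple sclerosis patients vs matched controls"
status: partial
units: ng/ml
genotypes: [AA, AG, GG]
conditions: [ms, control]
condition_means:
  ms: {value: 15.70, se: 0.28}
  control: {value: 8.39, se: 0.27}
notes: >
  Only pairwise p-values for the genotype contrasts between MS and control
  differences were published (AA vs AG P=0.005, AA vs GG P=3.7e-5,
  AG vs GG P=0.05); no numeric cell means or differences are printed, so
  the interaction identity cannot be evaluated.
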