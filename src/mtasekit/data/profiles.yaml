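# Shipped MTase specificity profiles.
# Flank weights are multiplicative preferences in [0,1]; a profile with all
# weights 1 is a pure dinucleotide specificity.  The quadruple-mutant
# profile encodes a qualitative activity ordering, not measured constants.
wild_type_CG:
  core: [CG]
  efficiency: 1.0
quadruple_mutant_CC:
  core: [CC]
  flank5_weights: {G: 1.0, C: 1.0, T: 1.0, A: 0.4}
  flank3_weights: {A: 1.0, C: 0.6, G: 0.05, T: 0.05}
  efficiency: 1.0
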