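compartments:
  Nn: {description: neuron nucleus, volume: 0.033}
  Nc: {description: neuron cytosol, volume: 0.33}
  Nm: {description: neuron mitochondrion, volume: 0.0855}
  An: {description: astrocyte nucleus, volume: 0.019}
  Ac: {description: astrocyte cytosol, volume: 0.19}
  Am: {description: astrocyte mitochondrion, volume: 0.0475}
  e: {description: extracellular space, volume: 0.2}
  b: {description: capillary blood, volume: 0.095}
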