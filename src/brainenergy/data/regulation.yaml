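genes: [GLUT, MCT, HK, PFK, GAPDH, PK, LDH]
cells:
  neuron: {cytosol: Nc, nucleus: Nn}
  astrocyte: {cytosol: Ac, nucleus: An}
params:
  basal_transcription: {value: 0.01, unit: mM/min}
  v_transcription: {value: 0.04, unit: mM/min}
  k_transcription: {value: 1.0, unit: mM}
  k_export: {value: 0.2, unit: 1/min}
  k_mrna_decay_nucleus: {value: 0.05, unit: 1/min}
  k_mrna_decay_cytosol: {value: 0.05, unit: 1/min}
  k_translation: {value: 0.1, unit: 1/min}
  k_protein_decay: {value: 0.02, unit: 1/min}
hif:
  k_synthesis: {value: 1.0, unit: 1/min}
  k_degradation: {value: 10.0, unit: 1/(mM^2*min)}
  k_translocation: {value: 0.1, unit: 1/min}
  k_nuclear_decay: {value: 0.1, unit: 1/min}
  phase_concentration: {value: 0.1, unit: mM}
o2_reference: 7.0
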