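variant: anlsh
reactions: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 16, 18, 19, 20, 21, 22, 23, 24, 25, 26, 28,
  30, 32, 34, 36, 38, 40, 42, 44, 46, 48, 50, 51, 52, 53, 54, 55, 56, 58, 60, 62, 64, 66, 68, 70, 71,
  73, 75, 77, 79, 81, 83, 85, 87, 89, 91, 93, 94]
options:
  neuron_glucose_uptake: false
  neuron_glucose_reactions: [15, 17]
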