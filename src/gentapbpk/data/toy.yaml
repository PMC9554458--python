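# Fast CI-scale configuration (n = 100).
seed: 7
populations:
  - {label: preterm, n: 100}
regimens:
  - {name: extended-q48h, dose_per_kg: 6.0, interval: 48.0}
reference_mic: 1.0
validation: {n_simulated: 100}
synthetic: {group: preterm, n_preterm: 10, n_missing: 0}
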