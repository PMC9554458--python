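# Preterm neonates: conventional vs extended-interval dosing evaluation.
seed: 20220928
populations:
  - {label: preterm, n: 1000, vd_policy: fixed}
regimens:
  - {name: conventional-q24h, dose_per_kg: 4.0, interval: 24.0}
  - {name: extended-q48h, dose_per_kg: 6.0, interval: 48.0}
reference_mic: 1.0
synthetic: {group: preterm, n_preterm: 31, n_missing: 2}
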