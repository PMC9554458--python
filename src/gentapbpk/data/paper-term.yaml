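# Term neonates: conventional vs extended-interval dosing evaluation.
seed: 20220928
populations:
  - {label: term, n: 1000, vd_policy: fixed}
regimens:
  - {name: conventional-q24h, dose_per_kg: 4.0, interval: 24.0}
  - {name: extended-q36h, dose_per_kg: 6.0, interval: 36.0}
reference_mic: 1.0
estimation: {initial_gfr: 1.72}
synthetic: {group: term, n_term: 16, n_missing: 1}
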