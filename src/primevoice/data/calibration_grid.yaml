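# Example local grid around the shipped defaults (parameter-recovery check).
values:
  w_inhib: [0.4, 0.5, 0.6]
  w_cross: [0.5, 0.6, 0.7]
n_participants: 10
n_reps: 3
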