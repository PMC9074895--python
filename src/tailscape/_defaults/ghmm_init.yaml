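# Packaged initializations for GHMM training.
#
# Emission means/variances and initial-state probabilities follow the
# published three-state splinted-ligation model; the numeric transition
# entries are configuration defaults for a left-to-right topology (rows are
# from-states).  Structural zeros encode the allowed moves
# 1->{1,2}, 2->{2,3}, 3->{3} (and the analogous five-state chain) and are
# preserved through training.
three_state:
  state_names: [initiation, polyA, non_polyA]
  polya_state: 1
  startprob: [0.998, 0.001, 0.001]
  transmat:
    - [0.99, 0.01, 0.0]
    - [0.0, 0.99, 0.01]
    - [0.0, 0.0, 1.0]
  means: [100.0, 1.0, -1.0]
  variances: [1.0, 0.25, 0.25]

five_state:
  state_names: [initiation, polyA, polyA_transition, non_polyA_transition, non_polyA]
  polya_state: 1
  startprob: [0.996, 0.001, 0.001, 0.001, 0.001]
  transmat:
    - [0.99, 0.01, 0.0, 0.0, 0.0]
    - [0.0, 0.99, 0.01, 0.0, 0.0]
    - [0.0, 0.0, 0.8, 0.2, 0.0]
    - [0.0, 0.0, 0.0, 0.8, 0.2]
    - [0.0, 0.0, 0.0, 0.0, 1.0]
  means: [100.0, 1.0, 0.5, -0.5, -1.0]
  variances: [1.0, 0.25, 0.25, 0.25, 0.25]
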