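# Column-role map for cohorts written by `dtr-ramp simulate`.
stages:
  - features: [Z1, Z2, Z3, Z4, Z5, Z6, Z7, Z8, Z9, Z10, Z11, Z12, X11, X21, X31]
    treatment: A1
    propensity: p1
  - features: [Z1, Z2, Z3, Z4, Z5, Z6, Z7, Z8, Z9, Z10, Z11, Z12, X12, X22, X32, A1]
    treatment: A2
    propensity: p2
    unpenalized: [A1]
reward: Y
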