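# Baseline parameterization used for the trait sweeps.
traits:
  pi: 0.5
  kappa: 1.0e-4
  lam: 0.505
  alpha: 1.0e-8
  delta: 0.05
  beta: 100.0
community:
  r: 0.9
  mu: -4.0e-10
nutrient:
  k: 1.125
  yield: 5.0e-9
  R0: 11.25
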