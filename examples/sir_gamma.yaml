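# SIR with Gamma-distributed susceptibility (mean 1, variance 1/p = 1).
# Same R0 = 2 as the homogeneous benchmark; attack rate drops to 50%.
model:
  preset: sir
  params: {beta: 0.0005, alpha: 0.25, N: 1000}
  trait: {type: gamma, p: 1.0, c_mode: constant}
seed: {mode: eigen, w0: 1.0e-6}
solver: {t_end: 200}
output: {form: both, prefix: sir_gamma}
verify: {h: 0.01, t_end: 200}
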