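# SIR benchmark: R0 = N beta / alpha = 2
model:
  preset: sir
  params: {beta: 0.0005, alpha: 0.25, N: 1000}
seed: {mode: eigen, w0: 1.0e-6}
solver: {t_end: 200}
output: {form: both, prefix: sir}
verify: {h: 0.01, t_end: 200}
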