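# One scenario cell for `nichebias scenario examples/scenario.yaml`:
# marginal generalist species under Gaussian effort, target-group
# background with the near-flat group.
species:
  mu0: -4.0
  sigma0: 1.5
effort: GS
method: TGOB
tg_shape: FLAT
n: 20000
seed: 20200520
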