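# Two-pollinator scenario in the style of a hummingbird/hawkmoth system:
# one pollinator strongly prefers the focal plant, the other strongly
# avoids it, with equal community visit shares. Synthetic illustration.
f: 0.5
pollinators:
  - id: bird
    rho: 0.8
    kappa: 0.0
    phi: 0.5
  - id: moth
    rho: -0.8
    kappa: 0.0
    phi: 0.5
simulation:
  n_bouts: 200
  bout_length: 20
  seed: 7
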