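# One-pollinator scenario in the style of a butterfly-on-two-morphs study:
# a single pollinator with moderate preference and constancy for the focal
# plant, observed where the focal morph makes up a quarter of the community.
# All numbers are synthetic illustrations, not field estimates.
f: 0.25
pollinators:
  - id: butterfly
    rho: 0.3
    kappa: 0.5
    phi: 1.0
simulation:
  n_bouts: 12
  bout_length: 8
  seed: 101
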