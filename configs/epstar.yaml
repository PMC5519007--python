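# EP*: the ecological parameter combination under which menopause and the
# longest post-reproductive lifespan evolve. Sigmoid slopes (gamma1, sigma1)
# are implementation defaults; see docs/methods.md.
simulation:
  initial_population: 1000
  duration: 10000
  initial_endowment: 200.0
  ecological:
    alpha: 0.91
    beta: 0.47
    gamma1: 0.1
    gamma2: 157.0
    delta: 0.87
    sigma1: 0.1
    sigma2: 27.0
    resource_pool: 20000.0
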