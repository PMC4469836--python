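# Reversal learning under tryptophan depletion (deterministic
# reward/punishment prediction).  Striatal gains: table6; GPi: table3.
experiment: reversal
gains_striatal: table6
gains_gpi: table3
etas: [0.01, 0.01, 0.01]
n_agents: 100
conditions:
  balanced: {alpha_d1: 1.0, alpha_d2: 5.0, alpha_d1d2: 1.0}
  depleted: {alpha_d1: 1.0, alpha_d2: 2.25, alpha_d1d2: 1.0}
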