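# Risk-sensitivity experiment (safe vs risky juice targets).
# Striatal plasticity gains: table5; GPi selection gains: table3.
experiment: risk
gains_striatal: table5
gains_gpi: table3
etas: [0.3, 0.1, 0.1]
r_b: 159.83
trials_per_state: 50
n_agents: 100
conditions:
  baseline: {alpha_d1: 1.0, alpha_d2: 1.0, alpha_d1d2: 1.32}
  rtd: {alpha_d1: 1.0, alpha_d2: 1.0, alpha_d1d2: 0.0012}
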