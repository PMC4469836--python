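# Probabilistic reward-punishment classification in Parkinson's disease.
# Striatal gains: table8; GPi: table3.  The dopamine clamp (delta_lim,
# delta_med) applies in the PD conditions only.
experiment: pd_classification
gains_striatal: table8
gains_gpi: table3
etas: [0.01, 0.1, 0.1]
n_agents: 100
conditions:
  controls:
    alpha_d1: 1.0
    alpha_d2: 1.0
    alpha_d1d2: 0.2
    status: control
  pd_off:
    alpha_d1: 1.0
    alpha_d2: 0.99
    alpha_d1d2: 0.001
    status: pd_off
    delta_lim: 0.001
  pd_on:
    alpha_d1: 1.0
    alpha_d2: 0.2
    alpha_d1d2: 0.001
    status: pd_on
    delta_lim: 0.001
    delta_med: 0.021
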