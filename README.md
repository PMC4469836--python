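# bgrl — dopamine–serotonin basal ganglia decision-making simulator

`bgrl` is a tested simulator of utility-based decision making in the
basal ganglia (BG), for computational neuroscientists studying how
dopamine (DA) and serotonin (5HT) jointly shape reward, punishment and
risk sensitivity — in healthy subjects and in Parkinson's disease (PD).

The core idea: alongside the classical value function computed by
D1-receptor-expressing striatal medium spiny neurons (MSNs), MSNs that
co-express D1 and D2 receptors can compute **risk** (outcome variance),
because the sum of an increasing (D1-like) and a decreasing (D2-like)
sigmoidal dopamine gain is an even, U-shaped function of the reward
prediction error δ — it responds to δ², the instantaneous variance.
Decisions then maximize a mean–variance utility

    U(s,a) = Q(s,a) − α · sign(Q(s,a)) · h(s,a)

with `Q = y_D1` (value), `h = y_D1D2` (risk), and serotonin levels
entering as multipliers (α_D1, α_D2, α_D1D2) on the three MSN pools.
The `sign(Q)` term makes agents risk averse for gains and risk seeking
for losses.  Action selection is not a softmax: the direct ("Go") and
indirect ("NoGo"/"Explore") pathways compete at GPi/thalamus, gated by
the utility gradient δ_U, with exploration supplied by the chaotic
dynamics of the coupled STN–GPe loop.  Parkinsonian dopamine depletion
is a clamp on the plasticity signal (δ ≤ δ_Lim, plus a medication
increment δ_Med when ON).

The package provides:

* `bgrl.core_rl` — the abstract risk-sensitive RL model (value, risk,
  utility, softmax), also used as an oracle for the network;
* `bgrl.striatum` — dopamine gain functions (with the published
  parameter tables as presets), three-pool MSN plasticity and readout;
* `bgrl.bg_network` — STN–GPe–GPi–thalamus selection dynamics;
* `bgrl.neuromodulators` — DA signals, serotonin parameters, PD clamp;
* `bgrl.tasks` — harnesses for three behavioral experiments: safe/risky
  choice under tryptophan depletion, deterministic reversal learning,
  and probabilistic reward–punishment classification in PD;
* `bgrl.fitting` — grid sweeps with common random numbers and a small
  genetic algorithm for parameter calibration;
* a `bgrl` command line (`simulate`, `sweep`, `fit`, `validate-config`,
  `plot`).

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations of the printed parameter sets.

## Worked example

Run the risk-sensitivity experiment (safe vs risky juice targets) for a
small population:

```sh
bgrl simulate --experiment risk --n-agents 10 --master-seed 7 --out results/demo
cat results/demo/summary.csv
```

```
condition,statistic,mean,se,n
baseline,safe_overall,0.5363333333333333,0.007624683761910113,10
baseline,safe_eev,0.35200000000000004,0.012757955639473174,10
baseline,safe_uev,0.7206666666666667,0.010816083132122626,10
rtd,safe_overall,0.5463333333333333,0.007957448564352834,10
rtd,safe_eev,0.3586666666666667,0.010922849535506228,10
rtd,safe_uev,0.734,0.008746074957401968,10
```

Each row is the proportion of safe choices (mean ± SE over agents):
overall, in the equal-expected-value states (where only outcome variance
distinguishes the options — agents are risk *seeking* there because the
rewards sit below the 159.83 ms reward base, i.e. in the loss domain),
and in the unequal-expected-value states (where the safe target usually
pays more, so safe choice is high).  `baseline` is normal serotonin
(α_D1D2 = 1.32), `rtd` is rapid tryptophan depletion (α_D1D2 = 0.0012);
at the full N = 100 the baseline population chooses the safe target
slightly more often (≈ 56.0% vs 54.9% overall) — a small effect at
these published constants (see `docs/methods.md`).  At N = 10 the
difference is inside the noise, as the SEs show.

The same interface runs the other experiments
(`--experiment reversal`, `--experiment pd_classification --condition
pd_on ...`), parameter sweeps
(`bgrl sweep --experiment reversal --param alpha_d2=1.25,2.5,5,10 ...`)
and GA fits against target statistics.  Python access mirrors the CLI:

```python
import bgrl
summary = bgrl.run_pd_experiment(n_agents=100, master_seed=1)
print(summary.summary)
```

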