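# Methods

## The model

`bgrl` implements a mechanistic model of how dopamine (DA) and serotonin
(5HT) jointly shape reward-punishment-risk based decision making in the
basal ganglia (BG), at two levels of description.

### Abstract core

A tabular agent learns, for every state-action pair,

* a value `Q(s,a)` by temporal-difference (TD) updates
  `Q += eta_Q * delta`, with `delta = r - Q` in the single-step tasks used
  throughout (a multi-step form `delta = r + gamma*Q(s',a') - Q(s,a)` is
  provided and unit-tested, but no shipped experiment needs it);
* a risk estimate `h(s,a)` by `h += eta_h * (delta^2 - h)`, whose fixed
  point is `E[delta^2]` — the outcome variance once `Q` has converged
  (for Bernoulli(p) rewards, `p(1-p)`);
* a mean–variance utility `U = Q - alpha * sign(Q) * h`.  The `sign(Q)`
  factor makes the agent risk averse for gains and risk seeking for
  losses; `sign(0) := 0` so the utility degenerates to value at `Q = 0`.
  `alpha >= 0` is the lumped serotonin correlate.

Actions are sampled from a softmax with inverse temperature `beta`
(computed with max-shift; `beta` is a free test parameter because the
network below replaces the softmax entirely).

### Network model

Three striatal medium-spiny-neuron (MSN) pools respond to a one-hot
cortical state code, so each pool's response to `(s,a)` is its
cortico-striatal weight entry: `Q = y_D1`, `h = y_D1D2`, plus a `y_D2`
pool feeding the indirect pathway.  Plasticity is Hebbian with a
DA-dependent gain: `w_P += eta_P * lambda_P(delta)`, where each
`lambda` is a sigmoid of the TD error with constants `(c1, c2, c3)` —
bipolar (`2c1/(1+exp(c2(delta+c3))) - c1`) for the D1/D2 pools, and for
the co-expressing D1R-D2R pool the sum of two unipolar sigmoids
(`c1/(1+exp(c2(delta+c3)))`).  The sign of `c2` carries the receptor
direction (D1-like increasing, D2-like decreasing with DA).  When the two
unipolar components are mirror images the summed gain is an even,
U-shaped function of `delta`, which is what lets that pool's weight
accumulate in proportion to `delta^2` and hence track outcome variance.
Note the co-expressing pool's update is purely additive (the gains are
positive), so `y_D1D2` grows monotonically at a rate set by outcome
surprise; it is a variance *signal*, not a variance *estimator* like the
abstract `h` (which has a subtractive term and a true fixed point).

Action selection happens downstream.  Per decision, with the striatal
drives held fixed:

* direct pathway: `x_DP_i = alpha_D1 * lambda^GPi_D1(delta_U) * y_D1(s,a_i)`;
* indirect pathway: `x_IP_i = alpha_D2 * lambda^GPi_D2(delta_U) * y_D2
  + alpha_D1D2 * sign(y_D1) * lambda^GPi_D1D2(delta_U) * y_D1D2`,
  inhibiting GPe;
* the STN–GPe loop (one-to-one coupling, complete lateral connectivity:
  STN self 1+eps_s / lateral eps_s = +0.1, GPe all-to-all eps_g = −0.1)
  is integrated by explicit Euler with step sizes 1/tau_s = 0.1 and
  1/tau_g = 0.033 and STN output `tanh(3·x)`;
* GPi combines `x_GPi = -x_DP + w_STN-GPi * y_STN` (w = 1) and the
  thalamic afferent is its exact negation; thalamic neurons follow
  `dy/dt = -y + x` with unit-step Euler over the same 25 steps;
* the selected action is the argmax of thalamic activation at the last
  step (a running time-integral argmax is available via
  `NetworkParams(integral_argmax=True)`); exact float ties are broken
  uniformly at random.

The loop's sustained bounded activity supplies the exploratory
stochasticity that softmax noise provides in the abstract model.  The
gating signal `delta_U` — a second DA correlate, distinct from the
plasticity `delta` — opens the direct ("Go") pathway when positive and
the indirect ("NoGo"/"Explore") pathway when negative.

### The utility-gradient convention

The printed definition `delta_U(t) = U_t(s_t,a_t) - U_{t-1}(s_t,a_{t-1})`
is circular (the action being selected appears in the signal that gates
its selection) and names the current state in both terms.  We resolve it
as: `U_t` is the utility, under current weights, of the greedy-utility
action in the current state; `U_{t-1}` is the stored utility that the
state's previously executed action had at its selection; the first visit
of a state uses `delta_U = 0`.  Two alternatives were implemented and
evaluated during development — (a) the change in the previously executed
action's own utility, and (b) a per-channel gradient gating each action by
its own utility change — and both degraded the risk-sensitivity result
without rescuing the reversal result (see "Known limitations"), so the
greedy convention is kept.

### Trial loop

Per trial: observe state → select action through the network (using
`delta_U`) → observe reward → compute `delta = r - y_D1(s,a)` → apply the
PD clamp if configured → update all three weight pools at the experienced
entry only → store the executed action's selection-time utility for the
state's next visit.  Weights are initialized uniformly in `[0,1)` from
the agent's seeded generator and are not clipped; the bounded gains bound
per-step changes intrinsically.  STN/GPe states are re-initialized
uniformly in `[-0.1, 0.1]` per decision (no initial conditions are
prescribed by the model definition; small random values activate the
exploratory loop dynamics; a `persist_dynamics` flag carries them across
trials instead).

### Serotonin and Parkinson's disease

Tonic 5HT enters as three non-negative multipliers `alpha_D1, alpha_D2,
alpha_D1D2` on the three pools' pathway outputs (and `alpha_D1D2` also
scales the risk term inside `U`).  PD is a clamp on the plasticity DA
signal: OFF medication `delta := min(delta, delta_lim)`; ON medication
additionally `+ delta_med` on every trial.  `delta_U` is *not* clamped
independently — it is computed from utilities built on the
clamped-trained weights.  The medication increment is applied on every
trial (the static ON-range reading); a transient-increment variant would
require a within-trial DA time course the model does not represent.
The `sign(Q)` non-linearity can be ablated everywhere (utility and
indirect pathway) with `sign_term=False` / `--no-sign-term`.

## Experiments

All three harnesses run `N = 100` independently seeded agents per
condition (population mean ± SE, SE = SD/√N).  Per-agent generators are
derived as `SeedSequence(master_seed, spawn_key=(agent,))`, so different
conditions reuse identical per-agent streams (common random numbers) and
every summary is bit-reproducible given the master seed.

**Risk sensitivity.** Six states pair a safe juice target against a
50/50 risky target (three equal-expected-value, three unequal); the
subjective reward is `r_j - r_b` with reward base `r_b = 159.83` ms, so
outcomes below the base act as losses.  Learning rates (0.3, 0.1, 0.1);
striatal gains `table5`, selection gains `table3`.  Baseline serotonin
`[1, 1, 1.32]` vs rapid tryptophan depletion `[1, 1, 0.0012]`
(`alpha_D1D2` carries the effect).  The task definition does not fix a
session length; we use 50 trials per state per agent, interleaved in
random order — enough for the D1 values to converge at these learning
rates while keeping a 100-agent population run under a minute.

**Reversal learning.** Two stimuli deterministically coupled to reward
(`r=+1`) / punishment (`r=-1`) outcomes; the agent predicts the outcome
category; erroneous trials repeat the same stimulus.  Four 120-trial
blocks (two per condition: unexpected reward / unexpected punishment,
order shuffled per agent), each an acquisition stage plus up to 16
reversal stages; a stage ends after k correct responses with
k ~ uniform{5..9} drawn at stage start (a consecutive-correct variant is
available via `ReversalProtocol(consecutive_criterion=True)`).  The first
trial after each reversal presents the stimulus whose outcome changed per
the block condition and is excluded ("switch trial"), as are acquisition
trials.  The D1 weights obey the task's built-in complementarity
(`w(s,a1) = -w(s,a2)`, `w(s1,a) = -w(s2,a)`) after every update — only
one of the four entries is free — while `w_D2`/`w_D1D2` train
unconstrained.  Learning rates (0.01, 0.01, 0.01); gains `table6`/`table3`;
balanced serotonin `[1, 5, 1]` vs depleted `[1, 2.25, 1]`.

**PD classification.** Four stimuli, two responses; reward stimuli pay
+25 points (`r=+1`) or 0, punishment stimuli 0 or −25 (`r=-1`); the
optimal response draws the good outcome with probability 0.8.  160
trials in 4 balanced blocks.  Learning rates (0.01, 0.1, 0.1); gains
`table8`/`table3`.  Conditions: controls `alpha = [1, 1, 0.2]`; PD-OFF
`delta_lim = 0.001, alpha = [1, 0.99, 0.001]`; PD-ON `delta_lim = 0.001,
delta_med = 0.021, alpha = [1, 0.2, 0.001]`.  Reported statistics:
fraction of optimal responses on reward stimuli and on punishment
stimuli.

The environments are exact implementations of the printed schedules; what
they do *not* emulate about the source behavioral data: no practice
block, no subject-level covariates, no motor/timing component, and the
reversal task's feedback is purely the stimulus-repetition rule.  Passing
harness tests therefore validates the simulator and its statistics, not
any claim about human or monkey data beyond the model's own behavior.

## Parameter search

`bgrl.fitting` provides grid sweeps (common random numbers across points;
re-evaluating a vector reproduces its statistics exactly) and a small
real-coded genetic algorithm (population 24, 40 generations, uniform
crossover 0.7, per-gene Gaussian mutation 0.1 scaled to 10% of the bound
width, tournament size 3, elitism 1, bounds enforced by clipping).  The
objective is a weighted sum of squared differences to user-supplied
target statistics.  These GA settings are a deliberately small desk-scale
configuration; the shipped parameter presets are the published constants
used directly, not re-fitted values.

## Numerical choices

* Sigmoid arguments are clipped at ±500 before `exp` (both forms are
  saturated to double precision far earlier), so gains are finite for any
  finite DA signal.
* A `linear` gain form (`lambda(delta) = c1*delta`) exists so the network
  plasticity rule can be checked bit-for-bit against abstract TD learning
  on a shared reward stream.
* Ties in the thalamic argmax are broken by the agent's generator;
  degenerate inputs (empty action sets, dimension mismatches, non-finite
  activations) raise immediately with diagnostics rather than propagating.
* SE uses the n−1 denominator.

## Known limitations

The published figure-level results this model family is associated with
were produced with genetic-algorithm-fitted constants whose bar heights
are not printed; only qualitative patterns can be checked.  Under the
printed parameter tables and our best-faith reading of the architecture,
three of those patterns do **not** emerge robustly, and we report them as
failing rather than adjusting the study conditions:

* **Unequal-expected-value split of the risk effect.**  The serotonin
  depletion effect on safe choice is reliable overall and in the
  equal-expected-value states, but in two of the three unequal-EV states
  the safe and risky values differ by ~60 reward units, so selection is
  value-dominated and the risk term (bounded by `alpha_D1D2 * y_D1D2`
  with `y_D1D2` of order 1) cannot move it; the third unequal-EV state
  has exactly equal means as printed.  The UEV contrast lands within
  noise at N = 100.
* **Reversal-learning serotonin contrast.**  With the printed gains the
  co-expressing pool's weights grow by ~0.007/trial without bound; the
  unchosen action's utility diverges from the stored executed-action
  utility, `delta_U` locks positive, and the Go pathway — anchored on
  `y_D1`, which cannot re-learn within a block at `eta = 0.01` and gain
  amplitude 0.06 — reselects the stale value-argmax.  Post-reversal
  performance is therefore error-dominated for every serotonin setting,
  and the balanced-vs-depleted error contrast is statistically flat.
  The alternative `delta_U` conventions remove the lock but reverse the
  risk-sensitivity result and still do not separate the printed
  `alpha_D2` contrast.
* **PD punishment optimality.**  Driving punishment-avoidance through the
  D1 values would require the non-optimal response's weight to fall below
  the optimal one's; starting from the prescribed uniform [0,1) init with
  `eta_D1 = 0.01` and gain amplitude 1, at most ±0.2 of change is
  available over each stimulus's ~40 trials, which cannot invert the
  initial ordering reliably.  The `table8` D2 gain as printed crosses
  zero at `delta = +1`, making `w_D2` an outcome-insensitive choice
  counter, so the indirect pathway cannot supply the discrimination
  either.  Punishment optimality consequently stays near chance in all
  three conditions, and the control balance / OFF-reversal patterns are
  not reproduced.

These analyses, with the measured numbers, are what the failing
acceptance tests assert against.
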