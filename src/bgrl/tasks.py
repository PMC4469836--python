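"""The three behavioral experiments and their harnesses.

* Risk sensitivity: six juice-reward states pairing a safe against a risky
  target (equal or unequal expected value); lowering the serotonin
  multiplier on the co-expressing pool (``alpha_d1d2``) models rapid
  tryptophan depletion and shifts choice toward the risky target.
* Reversal learning under tryptophan depletion: two stimuli deterministically
  coupled to reward/punishment outcomes, with repeated contingency
  reversals; ``alpha_d2`` carries the serotonin effect on punishment-driven
  behavioral inhibition.
* Probabilistic reward-punishment classification in Parkinson's disease:
  four stimuli with 80/20 outcome contingencies, run under control, PD-OFF
  and PD-ON dopamine conditions.

Each experiment runs a population of independently seeded agents and
reports population mean +- SE of its headline statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .bg_network import BGDynamicsState, NetworkParams, thalamus_select
from .neuromodulators import CONTROL, PDCondition, SerotoninParams, apply_pd, compute_delta
from .striatum import (
    GAIN_PRESETS,
    GainSet,
    MSNWeights,
    network_utility,
    update_weights,
    utility_vector,
)

__all__ = [
    "NetworkAgent",
    "RiskSchedule",
    "ReversalProtocol",
    "ClassificationTask",
    "ExperimentSummary",
    "RISK_CONDITIONS",
    "REVERSAL_CONDITIONS",
    "PD_CONDITIONS",
    "EXPERIMENT_DEFAULTS",
    "sample_risk_outcome",
    "run_risk_experiment",
    "run_reversal_experiment",
    "run_pd_experiment",
    "agent_rng",
]


# ---------------------------------------------------------------------------
# seeding

def agent_rng(master_seed: int, agent_index: int) -> np.random.Generator:
    """Per-agent generator derived from the master seed.

    The derivation depends only on ``(master_seed, agent_index)``, so
    re-running any condition -- or a different condition -- with the same
    master seed reuses identical per-agent streams (common random numbers).
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(agent_index,))
    )


# ---------------------------------------------------------------------------
# network agent (trial loop glue shared by the three harnesses)


class NetworkAgent:
    """One simulated subject: striatal weights plus the selection network.

    Per trial: observe the state, select an action through the
    STN-GPe-GPi-thalamus dynamics (gated by ``delta_U``), observe the
    reward, compute the (possibly PD-clamped) TD error, update all three
    weight pools, and store the executed action's utility for the next
    trial's ``delta_U``.  ``delta_U`` compares the current state's greedy
    utility under current weights with the stored utility of the action
    executed at this state's previous visit (evaluated at its selection
    time); a drop hands control to the indirect pathway.  It is 0 on a
    state's first visit.
    """

    def __init__(
        self,
        n_states: int,
        n_actions: int,
        rng: np.random.Generator,
        *,
        gains_striatal: GainSet,
        gains_gpi: GainSet,
        serotonin: SerotoninParams,
        pd: PDCondition = CONTROL,
        etas: tuple[float, float, float] = (0.01, 0.01, 0.01),
        net_params: NetworkParams | None = None,
        sign_term: bool = True,
        persist_dynamics: bool = False,
        silence_stn: bool = False,
        complementary_w_d1: bool = False,
        weights: MSNWeights | None = None,
    ):
        self.rng = rng
        self.gains_striatal = gains_striatal
        self.gains_gpi = gains_gpi
        self.serotonin = serotonin
        self.pd = pd
        self.net_params = net_params or NetworkParams()
        self.sign_term = sign_term
        self.persist_dynamics = persist_dynamics
        self.silence_stn = silence_stn
        self.complementary_w_d1 = complementary_w_d1
        self.weights = weights if weights is not None else MSNWeights.random_init(
            n_states, n_actions, rng, etas
        )
        if complementary_w_d1:
            self._mirror_w_d1(0, 0)
        self._dynamics: BGDynamicsState | None = None
        # per-state memory of the last executed action and the utility it
        # had at its selection: the utility gradient tracks how the
        # incumbent action's utility has changed since it was taken
        self._u_prev = np.zeros(n_states)
        self._a_prev = np.zeros(n_states, dtype=int)
        self._visited = np.zeros(n_states, dtype=bool)
        self._u_exec = 0.0
        self.last_delta_u = 0.0
        self.last_delta = 0.0

    def _mirror_w_d1(self, state: int, action: int) -> None:
        """Enforce the reversal-task complementarity identities on w_D1:
        the (state, action) entry is the single trained value, the other
        three are its sign mirrors."""
        w = self.weights.w_d1
        v = w[state, action]
        w[state, 1 - action] = -v
        w[1 - state, action] = -v
        w[1 - state, 1 - action] = v

    def delta_u(self, state: int) -> float:
        """Utility gradient: the current state's greedy utility under
        current weights minus the utility the previously executed action
        (in this state) had at its selection.  Zero on a state's first
        visit."""
        if not self._visited[state]:
            return 0.0
        u_greedy = float(
            np.max(
                utility_vector(
                    self.weights, self.serotonin.alpha_d1d2, state, sign_term=self.sign_term
                )
            )
        )
        return u_greedy - self._u_prev[state]

    def select(self, state: int) -> int:
        du = self.delta_u(state)
        self.last_delta_u = du
        action, dyn = thalamus_select(
            self.weights,
            self.gains_gpi,
            self.serotonin,
            du,
            state,
            self.net_params,
            self.rng,
            sign_term=self.sign_term,
            silence_stn=self.silence_stn,
            dynamics=self._dynamics if self.persist_dynamics else None,
        )
        if self.persist_dynamics:
            self._dynamics = dyn
        self._u_exec = network_utility(
            self.weights, self.serotonin.alpha_d1d2, state, action, sign_term=self.sign_term
        )
        return action

    def learn(self, state: int, action: int, reward: float) -> float:
        delta = apply_pd(compute_delta(self.weights, state, action, reward), self.pd)
        self.last_delta = delta
        update_weights(self.weights, self.gains_striatal, state, action, delta)
        if self.complementary_w_d1:
            self._mirror_w_d1(state, action)
        self._u_prev[state] = self._u_exec
        self._a_prev[state] = action
        self._visited[state] = True
        return delta


# ---------------------------------------------------------------------------
# task specifications


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("bgrl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class RiskSchedule:
    """Safe-vs-risky juice schedule: six states, a deterministic safe
    target and a 50/50 risky target each, and the reward base ``r_b``
    subtracted to give the subjective reward (outcomes below ``r_b`` act
    as losses, above as gains)."""

    safe: np.ndarray  # (6,) ms juice
    risky: np.ndarray  # (6, 2) ms juice, each outcome probability 0.5
    r_b: float = 159.83

    #: protocol grouping: the first three states pair choices of equal
    #: expected value, the last three of unequal expected value
    eev_states = (0, 1, 2)
    uev_states = (3, 4, 5)

    @classmethod
    def default(cls, r_b: float = 159.83) -> "RiskSchedule":
        df = _load_csv("long_reward_schedule.csv")
        sched = cls(
            safe=df["safe"].to_numpy(float),
            risky=df[["risky1", "risky2"]].to_numpy(float),
            r_b=r_b,
        )
        sched.validate()
        return sched

    @property
    def n_states(self) -> int:
        return len(self.safe)

    def validate(self) -> None:
        means = self.risky.mean(axis=1)
        for s in self.eev_states:
            if abs(means[s] - self.safe[s]) > 1e-9:
                raise ValueError(f"EEV state {s} has mean(risky) != safe")

    def sample(self, state: int, choice: int, rng: np.random.Generator) -> float:
        """Objective juice outcome ``r_j`` for choice 0 (safe) / 1 (risky)."""
        if choice == 0:
            return float(self.safe[state])
        return float(self.risky[state, rng.integers(2)])


def sample_risk_outcome(
    schedule: RiskSchedule, state: int, choice: int, rng: np.random.Generator
) -> float:
    """Subjective reward ``r = r_j - r_b`` for one safe/risky choice."""
    return schedule.sample(state, choice, rng) - schedule.r_b


@dataclass(frozen=True)
class ReversalProtocol:
    """Block structure of the reversal-learning task.

    Four blocks of at most 120 trials, two per condition (unexpected
    reward / unexpected punishment).  Each block starts with an
    acquisition stage followed by up to ``max_reversals`` reversal stages;
    a stage ends once the number of correct responses reaches a criterion
    drawn uniformly from ``criterion_range`` at stage start.  With
    ``consecutive_criterion`` the correct-response count resets on errors
    (the alternative reading of the protocol).
    """

    n_blocks: int = 4
    trials_per_block: int = 120
    max_reversals: int = 16
    criterion_range: tuple[int, int] = (5, 9)
    consecutive_criterion: bool = False

    conditions = ("unexpected_reward", "unexpected_punishment")


@dataclass(frozen=True)
class ClassificationTask:
    """Probabilistic reward-punishment classification (four fractal images).

    Images I1/I2 are reward stimuli (outcomes +25 points coded ``r=+1`` or
    0), I3/I4 punishment stimuli (outcomes 0 or -25 coded ``r=-1``).  The
    optimal response draws the good outcome with probability
    ``p_good_optimal``; the non-optimal response with its complement.
    """

    optimal: tuple[int, ...] = (0, 1, 0, 1)  # 0 = response A, 1 = response B
    reward_stimuli: tuple[int, ...] = (0, 1)
    p_good_optimal: float = 0.8
    n_blocks: int = 4
    trials_per_block: int = 40

    @classmethod
    def default(cls) -> "ClassificationTask":
        df = _load_csv("classification_contingencies.csv")
        optimal = tuple(0 if a == "A" else 1 for a in df["optimal_action"])
        reward_stimuli = tuple(i for i, v in enumerate(df["valence"]) if v == "reward")
        return cls(
            optimal=optimal,
            reward_stimuli=reward_stimuli,
            p_good_optimal=float(df["p_good_optimal"].iloc[0]),
        )

    @property
    def n_states(self) -> int:
        return len(self.optimal)

    def sample(self, stimulus: int, action: int, rng: np.random.Generator) -> float:
        """Coded outcome r in {+1, 0, -1}; reward stimuli never punish and
        punishment stimuli never reward."""
        p_good = self.p_good_optimal if action == self.optimal[stimulus] else 1.0 - self.p_good_optimal
        good = rng.random() < p_good
        if stimulus in self.reward_stimuli:
            return 1.0 if good else 0.0
        return 0.0 if good else -1.0


# ---------------------------------------------------------------------------
# population summaries


@dataclass
class ExperimentSummary:
    """Population result: tidy summary (condition, statistic, mean, se, n),
    the per-agent statistics behind it, and optionally the full trial log."""

    experiment: str
    summary: pd.DataFrame
    per_agent: pd.DataFrame
    trials: pd.DataFrame | None = None

    def value(self, condition: str, statistic: str) -> float:
        rows = self.summary
        m = rows[(rows.condition == condition) & (rows.statistic == statistic)]
        return float(m["mean"].iloc[0])

    def se(self, condition: str, statistic: str) -> float:
        rows = self.summary
        m = rows[(rows.condition == condition) & (rows.statistic == statistic)]
        return float(m["se"].iloc[0])


def _summarize(experiment: str, per_agent: pd.DataFrame, stat_cols: list[str]) -> pd.DataFrame:
    rows = []
    for cond, grp in per_agent.groupby("condition", sort=False):
        n = len(grp)
        for col in stat_cols:
            vals = grp[col].to_numpy(float)
            se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            rows.append((cond, col, vals.mean(), se, n))
    return pd.DataFrame(rows, columns=["condition", "statistic", "mean", "se", "n"])


# ---------------------------------------------------------------------------
# condition presets (the study conditions for each experiment)

RISK_CONDITIONS: dict[str, SerotoninParams] = {
    "baseline": SerotoninParams(1.0, 1.0, 1.32),
    "rtd": SerotoninParams(1.0, 1.0, 0.0012),
}

REVERSAL_CONDITIONS: dict[str, SerotoninParams] = {
    "balanced": SerotoninParams(1.0, 5.0, 1.0),
    "depleted": SerotoninParams(1.0, 2.25, 1.0),
}

PD_CONDITIONS: dict[str, tuple[SerotoninParams, PDCondition]] = {
    "controls": (SerotoninParams(1.0, 1.0, 0.2), CONTROL),
    "pd_off": (
        SerotoninParams(1.0, 0.99, 0.001),
        PDCondition("pd_off", delta_lim=0.001),
    ),
    "pd_on": (
        SerotoninParams(1.0, 0.2, 0.001),
        PDCondition("pd_on", delta_lim=0.001, delta_med=0.021),
    ),
}

#: learning rates and gain presets per experiment
EXPERIMENT_DEFAULTS = {
    "risk": {"etas": (0.3, 0.1, 0.1), "gains_striatal": "table5", "gains_gpi": "table3"},
    "reversal": {"etas": (0.01, 0.01, 0.01), "gains_striatal": "table6", "gains_gpi": "table3"},
    "pd_classification": {
        "etas": (0.01, 0.1, 0.1),
        "gains_striatal": "table8",
        "gains_gpi": "table3",
    },
}


def _resolve_gains(gains: str | GainSet) -> GainSet:
    if isinstance(gains, str):
        return GAIN_PRESETS[gains]
    return gains


# ---------------------------------------------------------------------------
# experiment harnesses


def run_risk_experiment(
    *,
    n_agents: int = 100,
    trials_per_state: int = 50,
    master_seed: int = 0,
    conditions: dict[str, SerotoninParams] | None = None,
    schedule: RiskSchedule | None = None,
    gains_striatal: str | GainSet = "table5",
    gains_gpi: str | GainSet = "table3",
    etas: tuple[float, float, float] = (0.3, 0.1, 0.1),
    net_params: NetworkParams | None = None,
    sign_term: bool = True,
    persist_dynamics: bool = False,
    silence_stn: bool = False,
    keep_trials: bool = False,
) -> ExperimentSummary:
    """Safe-vs-risky choice under baseline vs. tryptophan-depleted serotonin.

    Returns safe-choice proportions overall and split into equal/unequal
    expected-value states, mean +- SE over the agent population.
    """
    conditions = conditions if conditions is not None else RISK_CONDITIONS
    if not conditions:
        raise ValueError("risk experiment needs at least one serotonin condition")
    schedule = schedule or RiskSchedule.default()
    g_str = _resolve_gains(gains_striatal)
    g_gpi = _resolve_gains(gains_gpi)
    eev = set(schedule.eev_states)

    agent_rows = []
    trial_rows = [] if keep_trials else None
    for cond_name, sero in conditions.items():
        for i in range(n_agents):
            rng = agent_rng(master_seed, i)
            agent = NetworkAgent(
                schedule.n_states,
                2,
                rng,
                gains_striatal=g_str,
                gains_gpi=g_gpi,
                serotonin=sero,
                etas=etas,
                net_params=net_params,
                sign_term=sign_term,
                persist_dynamics=persist_dynamics,
                silence_stn=silence_stn,
            )
            seq = np.repeat(np.arange(schedule.n_states), trials_per_state)
            rng.shuffle(seq)
            safe = np.zeros(schedule.n_states)
            count = np.zeros(schedule.n_states)
            for t, s in enumerate(seq):
                s = int(s)
                a = agent.select(s)
                r = sample_risk_outcome(schedule, s, a, rng)
                agent.learn(s, a, r)
                safe[s] += a == 0
                count[s] += 1
                if trial_rows is not None:
                    trial_rows.append(
                        (cond_name, i, t, s, a, r, agent.last_delta, agent.last_delta_u)
                    )
            frac = safe / count
            agent_rows.append(
                (
                    cond_name,
                    i,
                    safe.sum() / count.sum(),
                    np.mean([frac[s] for s in range(schedule.n_states) if s in eev]),
                    np.mean([frac[s] for s in range(schedule.n_states) if s not in eev]),
                )
            )

    per_agent = pd.DataFrame(
        agent_rows,
        columns=["condition", "agent", "safe_overall", "safe_eev", "safe_uev"],
    )
    trials = (
        pd.DataFrame(
            trial_rows,
            columns=["condition", "agent", "trial", "state", "action", "reward", "delta", "delta_u"],
        )
        if trial_rows is not None
        else None
    )
    summary = _summarize("risk", per_agent, ["safe_overall", "safe_eev", "safe_uev"])
    return ExperimentSummary("risk", summary, per_agent, trials)


def _run_reversal_agent(
    agent: NetworkAgent,
    protocol: ReversalProtocol,
    rng: np.random.Generator,
    policy=None,
):
    """Run one agent through the full 4-block reversal protocol.

    ``policy`` optionally overrides the agent's action choice (used for
    harness sanity checks with an always-correct oracle).  Returns a list
    of per-trial records.
    """
    records = []
    block_conditions = np.array([0, 0, 1, 1])
    rng.shuffle(block_conditions)
    for block in range(protocol.n_blocks):
        cond = protocol.conditions[block_conditions[block]]
        reward_stim = int(rng.integers(2))  # stimulus currently yielding reward
        stage = 0
        ncorrect = 0
        criterion = int(rng.integers(protocol.criterion_range[0], protocol.criterion_range[1] + 1))
        repeat_stim: int | None = None
        switch_pending = False
        for trial in range(protocol.trials_per_block):
            if repeat_stim is not None:
                stim, is_switch = repeat_stim, False
            elif switch_pending:
                stim = reward_stim if cond == "unexpected_reward" else 1 - reward_stim
                is_switch = True
                switch_pending = False
            else:
                stim, is_switch = int(rng.integers(2)), False
            outcome = 1.0 if stim == reward_stim else -1.0
            action = agent.select(stim) if policy is None else policy(stim, outcome)
            predicted = 1.0 if action == 0 else -1.0
            correct = predicted == outcome
            agent.learn(stim, action, outcome)
            records.append(
                (block, cond, stage, trial, stim, action, outcome, correct, is_switch, stage == 0)
            )
            repeat_stim = None if correct else stim
            if correct:
                ncorrect += 1
            elif protocol.consecutive_criterion:
                ncorrect = 0
            if ncorrect >= criterion and stage < protocol.max_reversals:
                reward_stim = 1 - reward_stim
                stage += 1
                ncorrect = 0
                criterion = int(
                    rng.integers(protocol.criterion_range[0], protocol.criterion_range[1] + 1)
                )
                switch_pending = True
    return records


_REV_COLS = [
    "block",
    "condition_type",
    "stage",
    "trial",
    "stimulus",
    "action",
    "outcome",
    "correct",
    "is_switch",
    "is_acquisition",
]

_REV_STATS = [
    "errors_reward",
    "errors_punishment",
    "errors_unexpected_reward",
    "errors_unexpected_punishment",
    "errors_total",
]


def _reversal_agent_stats(df: pd.DataFrame) -> tuple[float, ...]:
    """Non-switch error counts, excluding acquisition-stage trials, split
    by realized outcome type and by block condition."""
    scored = df[~df.is_switch & ~df.is_acquisition & ~df.correct]
    return (
        float((scored.outcome > 0).sum()),
        float((scored.outcome < 0).sum()),
        float((scored.condition_type == "unexpected_reward").sum()),
        float((scored.condition_type == "unexpected_punishment").sum()),
        float(len(scored)),
    )


def run_reversal_experiment(
    *,
    n_agents: int = 100,
    master_seed: int = 0,
    conditions: dict[str, SerotoninParams] | None = None,
    protocol: ReversalProtocol | None = None,
    gains_striatal: str | GainSet = "table6",
    gains_gpi: str | GainSet = "table3",
    etas: tuple[float, float, float] = (0.01, 0.01, 0.01),
    net_params: NetworkParams | None = None,
    sign_term: bool = True,
    persist_dynamics: bool = False,
    silence_stn: bool = False,
    keep_trials: bool = False,
) -> ExperimentSummary:
    """Deterministic reward/punishment reversal learning under balanced vs.
    tryptophan-depleted serotonin.

    Returns mean non-switch-trial error counts split by outcome type
    (reward- vs punishment-prediction trials) and by block condition
    (unexpected reward vs unexpected punishment).
    """
    conditions = conditions if conditions is not None else REVERSAL_CONDITIONS
    protocol = protocol or ReversalProtocol()
    g_str = _resolve_gains(gains_striatal)
    g_gpi = _resolve_gains(gains_gpi)

    agent_rows = []
    trial_frames = [] if keep_trials else None
    for cond_name, sero in conditions.items():
        for i in range(n_agents):
            rng = agent_rng(master_seed, i)
            agent = NetworkAgent(
                2,
                2,
                rng,
                gains_striatal=g_str,
                gains_gpi=g_gpi,
                serotonin=sero,
                etas=etas,
                net_params=net_params,
                sign_term=sign_term,
                persist_dynamics=persist_dynamics,
                silence_stn=silence_stn,
                complementary_w_d1=True,
            )
            records = _run_reversal_agent(agent, protocol, rng)
            df = pd.DataFrame(records, columns=_REV_COLS)
            agent_rows.append((cond_name, i, *_reversal_agent_stats(df)))
            if trial_frames is not None:
                df.insert(0, "agent", i)
                df.insert(0, "condition", cond_name)
                trial_frames.append(df)

    per_agent = pd.DataFrame(agent_rows, columns=["condition", "agent", *_REV_STATS])
    trials = pd.concat(trial_frames, ignore_index=True) if trial_frames else None
    summary = _summarize("reversal", per_agent, _REV_STATS)
    return ExperimentSummary("reversal", summary, per_agent, trials)


def run_pd_experiment(
    *,
    n_agents: int = 100,
    master_seed: int = 0,
    conditions: dict[str, tuple[SerotoninParams, PDCondition]] | None = None,
    task: ClassificationTask | None = None,
    gains_striatal: str | GainSet = "table8",
    gains_gpi: str | GainSet = "table3",
    etas: tuple[float, float, float] = (0.01, 0.1, 0.1),
    net_params: NetworkParams | None = None,
    sign_term: bool = True,
    persist_dynamics: bool = False,
    silence_stn: bool = False,
    keep_trials: bool = False,
) -> ExperimentSummary:
    """Probabilistic classification under control, PD-OFF and PD-ON
    dopamine conditions.

    Returns reward optimality (fraction of optimal responses on reward
    stimuli) and punishment optimality (on punishment stimuli), mean +- SE
    over agents.
    """
    conditions = conditions if conditions is not None else PD_CONDITIONS
    task = task or ClassificationTask.default()
    g_str = _resolve_gains(gains_striatal)
    g_gpi = _resolve_gains(gains_gpi)
    reward_set = set(task.reward_stimuli)

    agent_rows = []
    trial_rows = [] if keep_trials else None
    for cond_name, (sero, pd_cond) in conditions.items():
        for i in range(n_agents):
            rng = agent_rng(master_seed, i)
            agent = NetworkAgent(
                task.n_states,
                2,
                rng,
                gains_striatal=g_str,
                gains_gpi=g_gpi,
                serotonin=sero,
                pd=pd_cond,
                etas=etas,
                net_params=net_params,
                sign_term=sign_term,
                persist_dynamics=persist_dynamics,
                silence_stn=silence_stn,
            )
            opt = np.zeros(task.n_states)
            count = np.zeros(task.n_states)
            t = 0
            for block in range(task.n_blocks):
                seq = np.repeat(
                    np.arange(task.n_states), task.trials_per_block // task.n_states
                )
                rng.shuffle(seq)
                for s in seq:
                    s = int(s)
                    a = agent.select(s)
                    r = task.sample(s, a, rng)
                    agent.learn(s, a, r)
                    opt[s] += a == task.optimal[s]
                    count[s] += 1
                    if trial_rows is not None:
                        trial_rows.append(
                            (cond_name, i, block, t, s, a, r, agent.last_delta, agent.last_delta_u)
                        )
                    t += 1
            reward_opt = sum(opt[s] for s in reward_set) / sum(count[s] for s in reward_set)
            punish_opt = sum(
                opt[s] for s in range(task.n_states) if s not in reward_set
            ) / sum(count[s] for s in range(task.n_states) if s not in reward_set)
            agent_rows.append((cond_name, i, reward_opt, punish_opt))

    per_agent = pd.DataFrame(
        agent_rows, columns=["condition", "agent", "reward_optimality", "punishment_optimality"]
    )
    trials = (
        pd.DataFrame(
            trial_rows,
            columns=[
                "condition",
                "agent",
                "block",
                "trial",
                "stimulus",
                "action",
                "reward",
                "delta",
                "delta_u",
            ],
        )
        if trial_rows is not None
        else None
    )
    summary = _summarize(
        "pd_classification", per_agent, ["reward_optimality", "punishment_optimality"]
    )
    return ExperimentSummary("pd_classification", summary, per_agent, trials)
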