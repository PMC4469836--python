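"""Experiment environments, trial accounting, and harness behavior."""

import numpy as np
import pandas as pd
import pytest

from bgrl.neuromodulators import SerotoninParams
from bgrl.striatum import GAIN_PRESETS
from bgrl.tasks import (
    ClassificationTask,
    NetworkAgent,
    ReversalProtocol,
    RiskSchedule,
    _REV_COLS,
    _run_reversal_agent,
    agent_rng,
    run_pd_experiment,
    run_reversal_experiment,
    run_risk_experiment,
    sample_risk_outcome,
)


class TestRiskSchedule:
    def test_default_loads_and_validates(self):
        sched = RiskSchedule.default()
        assert sched.n_states == 6
        # the first three states pair equal expected values
        assert np.allclose(sched.risky[:3].mean(axis=1), sched.safe[:3])

    def test_eev_violation_detected(self):
        bad = RiskSchedule(safe=np.array([150.0] * 6), risky=np.tile([100.0, 180.0], (6, 1)))
        with pytest.raises(ValueError):
            bad.validate()

    def test_subjective_reward_examples(self, rng):
        sched = RiskSchedule.default()
        # safe choice in state 1: 150 ms against the 159.83 ms reward base
        assert sample_risk_outcome(sched, 0, 0, rng) == pytest.approx(-9.83)
        # an outcome equal to the base is subjectively neutral
        neutral = RiskSchedule(safe=np.full(6, 159.83), risky=sched.risky)
        assert sample_risk_outcome(neutral, 0, 0, rng) == pytest.approx(0.0)

    def test_risky_split_is_half_half(self):
        sched = RiskSchedule.default()
        gen = np.random.default_rng(77)
        draws = np.array([sched.sample(1, 1, gen) for _ in range(100_000)])
        assert abs((draws == 100.0).mean() - 0.5) < 0.01
        assert draws.mean() == pytest.approx(150.0, abs=0.5)


class TestClassificationTask:
    def test_default_contingencies(self):
        task = ClassificationTask.default()
        assert task.optimal == (0, 1, 0, 1)
        assert task.reward_stimuli == (0, 1)

    def test_outcome_supports(self, rng):
        task = ClassificationTask.default()
        for s in range(4):
            outcomes = {task.sample(s, a, rng) for a in (0, 1) for _ in range(200)}
            if s in task.reward_stimuli:
                assert outcomes <= {0.0, 1.0}  # reward stimuli never punish
            else:
                assert outcomes <= {0.0, -1.0}  # punishment stimuli never reward

    def test_optimal_good_outcome_marginal(self):
        task = ClassificationTask.default()
        gen = np.random.default_rng(99)
        good = sum(task.sample(0, 0, gen) == 1.0 for _ in range(100_000)) / 100_000
        assert abs(good - 0.8) < 0.01


class TestReversalHarness:
    def _agent(self, seed=0, **kw):
        rng = agent_rng(seed, 0)
        agent = NetworkAgent(
            2,
            2,
            rng,
            gains_striatal=GAIN_PRESETS["table6"],
            gains_gpi=GAIN_PRESETS["table3"],
            serotonin=SerotoninParams(1, 5, 1),
            etas=(0.01, 0.01, 0.01),
            complementary_w_d1=True,
            **kw,
        )
        return agent, rng

    def test_trial_accounting(self):
        agent, rng = self._agent()
        df = pd.DataFrame(_run_reversal_agent(agent, ReversalProtocol(), rng), columns=_REV_COLS)
        assert len(df) == 480
        assert df.groupby("block").size().eq(120).all()
        assert sorted(df.condition_type.unique()) == [
            "unexpected_punishment",
            "unexpected_reward",
        ]
        assert df.stage.max() <= 16

    def test_complementarity_after_every_update(self):
        """The four D1 weights stay an exact sign-mirror quadruple through
        the whole session."""
        agent, rng = self._agent(seed=3)
        protocol = ReversalProtocol(n_blocks=1)
        orig_learn = agent.learn

        def checked_learn(state, action, reward):
            out = orig_learn(state, action, reward)
            w = agent.weights.w_d1
            assert w[0, 0] == -w[0, 1] == -w[1, 0] == w[1, 1]
            return out

        agent.learn = checked_learn
        _run_reversal_agent(agent, protocol, rng)

    def test_oracle_policy_zero_errors(self):
        """An always-correct oracle run through the harness scores no
        errors and ends stages at the criterion minima."""
        agent, rng = self._agent(seed=1)
        df = pd.DataFrame(
            _run_reversal_agent(
                agent,
                ReversalProtocol(),
                rng,
                policy=lambda stim, outcome: 0 if outcome > 0 else 1,
            ),
            columns=_REV_COLS,
        )
        assert df.correct.all()
        # every completed stage lasted between 5 and 9 trials (all correct)
        lengths = df.groupby(["block", "stage"]).size()
        done = lengths.groupby("block").head(-1)  # last stage of a block is truncated
        assert done.between(5, 9).all()

    def test_consecutive_criterion_flag(self):
        agent, rng = self._agent(seed=2)
        protocol = ReversalProtocol(n_blocks=1, consecutive_criterion=True)
        df = pd.DataFrame(_run_reversal_agent(agent, protocol, rng), columns=_REV_COLS)
        assert len(df) == 120

    def test_error_trials_repeat_the_stimulus(self):
        agent, rng = self._agent(seed=4)
        df = pd.DataFrame(
            _run_reversal_agent(agent, ReversalProtocol(n_blocks=1), rng), columns=_REV_COLS
        )
        wrong = df[~df.correct].index
        followers = [i + 1 for i in wrong if i + 1 < len(df)]
        assert (df.loc[followers, "stimulus"].to_numpy()
                == df.loc[[i - 1 for i in followers], "stimulus"].to_numpy()).all()


class TestExperimentSummaries:
    def test_risk_summary_shape_and_determinism(self):
        kw = dict(n_agents=3, trials_per_state=8, master_seed=11)
        s1 = run_risk_experiment(**kw)
        s2 = run_risk_experiment(**kw)
        pd.testing.assert_frame_equal(s1.summary, s2.summary)
        assert set(s1.summary.statistic) == {"safe_overall", "safe_eev", "safe_uev"}
        assert set(s1.summary.condition) == {"baseline", "rtd"}
        assert s1.summary["n"].eq(3).all()

    def test_summary_se_definition(self):
        s = run_risk_experiment(n_agents=4, trials_per_state=5, master_seed=2)
        grp = s.per_agent[s.per_agent.condition == "baseline"]["safe_overall"]
        expected_se = grp.std(ddof=1) / np.sqrt(4)
        assert s.se("baseline", "safe_overall") == pytest.approx(expected_se)

    def test_pd_trial_accounting(self):
        s = run_pd_experiment(n_agents=2, master_seed=5, keep_trials=True)
        counts = s.trials.groupby(["condition", "agent"]).size()
        assert counts.eq(160).all()
        per_block = s.trials.groupby(["condition", "agent", "block"]).size()
        assert per_block.eq(40).all()

    def test_reversal_population_accounting(self):
        s = run_reversal_experiment(n_agents=2, master_seed=5, keep_trials=True)
        counts = s.trials.groupby(["condition", "agent"]).size()
        assert counts.eq(480).all()
        assert set(s.summary.statistic) == {
            "errors_reward",
            "errors_punishment",
            "errors_unexpected_reward",
            "errors_unexpected_punishment",
            "errors_total",
        }

    def test_common_random_numbers_across_conditions(self):
        """Identical serotonin parameters under different condition names
        give bit-identical per-agent statistics (shared per-agent seeds)."""
        conds = {"a": SerotoninParams(1, 1, 1.0), "b": SerotoninParams(1, 1, 1.0)}
        s = run_risk_experiment(
            n_agents=3, trials_per_state=6, master_seed=9, conditions=conds
        )
        a = s.per_agent[s.per_agent.condition == "a"].drop(columns="condition")
        b = s.per_agent[s.per_agent.condition == "b"].drop(columns="condition")
        assert np.array_equal(a.to_numpy(float), b.to_numpy(float))
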