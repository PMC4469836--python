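"""STN-GPe-GPi-thalamus action-selection dynamics."""

import numpy as np
import pytest

from bgrl.bg_network import (
    BGDynamicsState,
    NetworkParams,
    dp_contribution,
    gpi_combine,
    ip_contribution,
    step_stn_gpe,
    thalamus_select,
)
from bgrl.neuromodulators import SerotoninParams
from bgrl.striatum import GAIN_PRESETS, MSNWeights

GPI = GAIN_PRESETS["table3"]


def _weights(rng, n_states=1, n_actions=2):
    return MSNWeights.random_init(n_states, n_actions, rng)


class TestPathwayContributions:
    def test_dp_zero_serotonin(self, rng):
        x = dp_contribution(_weights(rng), GPI, 0.0, 0.5, 0)
        assert np.all(x == 0)

    def test_dp_vanishes_at_gain_midpoint(self, rng):
        # bipolar midpoint of the selection gain sits at dU = -c3 = -0.01
        x = dp_contribution(_weights(rng), GPI, 1.0, -0.01, 0)
        assert np.allclose(x, 0.0, atol=1e-12)

    def test_dp_asymptote_recovers_d1_response(self, rng):
        w = _weights(rng)
        w.w_d1[0] = [0.5, 0.2]
        x = dp_contribution(w, GPI, 1.0, 1e3, 0)
        assert x == pytest.approx([0.5, 0.2])  # c1 = 1 saturates the gain

    def test_ip_zero_serotonin(self, rng):
        x = ip_contribution(_weights(rng), GPI, 0.0, 0.0, 0.3, 0)
        assert np.all(x == 0)

    def test_ip_sign_term_flips_with_value_sign(self, rng):
        w = _weights(rng)
        w.w_d1[0] = [0.4, 0.4]
        base = ip_contribution(w, GPI, 0.0, 1.0, 0.2, 0)
        w.w_d1[0] = [-0.4, -0.4]
        flipped = ip_contribution(w, GPI, 0.0, 1.0, 0.2, 0)
        assert np.allclose(flipped, -base)

    def test_ip_sign_ablation_ignores_value_sign(self, rng):
        w = _weights(rng)
        w.w_d1[0] = [0.4, 0.4]
        a = ip_contribution(w, GPI, 0.3, 1.0, 0.2, 0, sign_term=False)
        w.w_d1[0] = [-0.4, -0.4]
        b = ip_contribution(w, GPI, 0.3, 1.0, 0.2, 0, sign_term=False)
        assert np.allclose(a, b)

    def test_ip_requires_d2_gain(self, rng):
        with pytest.raises(ValueError):
            ip_contribution(_weights(rng), GAIN_PRESETS["table1"], 1.0, 1.0, 0.0, 0)


class TestSTNGPeDynamics:
    def test_origin_is_fixed_point_without_input(self):
        state = BGDynamicsState(np.zeros(3), np.zeros(3), np.zeros(3))
        step_stn_gpe(state, np.zeros(3), NetworkParams())
        assert np.all(state.x_stn == 0) and np.all(state.x_gpe == 0)

    def test_lateral_sums_match_explicit_matrices(self, rng):
        """The complete-connectivity shortcut equals W @ y with the stated
        lateral weight matrices."""
        p = NetworkParams()
        n = 4
        x_stn = rng.uniform(-1, 1, n)
        x_gpe = rng.uniform(-1, 1, n)
        x_ip = rng.uniform(-0.5, 0.5, n)
        W_stn = np.full((n, n), p.eps_s) + np.eye(n)
        W_gpe = np.full((n, n), p.eps_g)
        y_stn = np.tanh(p.lambda_stn * x_stn)
        expect_stn = x_stn + p.inv_tau_s * (-x_stn + W_stn @ y_stn - x_gpe)
        expect_gpe = x_gpe + p.inv_tau_g * (-x_gpe + W_gpe @ x_gpe + y_stn - x_ip)
        state = BGDynamicsState(x_stn.copy(), x_gpe.copy(), np.zeros(n))
        step_stn_gpe(state, x_ip, p)
        assert np.allclose(state.x_stn, expect_stn, atol=1e-14)
        assert np.allclose(state.x_gpe, expect_gpe, atol=1e-14)

    def test_decoupled_contraction_and_bounded_output(self):
        p = NetworkParams(eps_s=0.0, eps_g=0.0)
        state = BGDynamicsState(np.ones(1), np.zeros(1), np.zeros(1))
        for _ in range(200):
            step_stn_gpe(state, np.zeros(1), p)
            assert abs(state.y_stn(p.lambda_stn)[0]) <= 1.0
        assert abs(state.x_stn[0]) < 1.5

    def test_default_dynamics_bounded_and_nonconstant(self, rng):
        p = NetworkParams()
        state = BGDynamicsState.random_init(2, rng)
        traj = []
        for _ in range(500):
            step_stn_gpe(state, np.zeros(2), p)
            traj.append(state.x_stn.copy())
        traj = np.array(traj)
        assert np.max(np.abs(traj)) < 10.0
        assert traj[-100:].std() > 1e-4  # sustained activity, not a quiescent point

    def test_long_run_finiteness(self, rng):
        p = NetworkParams()
        state = BGDynamicsState.random_init(3, rng)
        for _ in range(100_000):
            step_stn_gpe(state, np.zeros(3), p)
        assert np.all(np.isfinite(state.x_stn)) and np.all(np.isfinite(state.x_gpe))

    def test_dimension_mismatch_rejected(self, rng):
        state = BGDynamicsState.random_init(2, rng)
        with pytest.raises(ValueError):
            step_stn_gpe(state, np.zeros(3), NetworkParams())


class TestGPiCombine:
    @pytest.mark.parametrize(
        "x_dp, y_stn, w, expected",
        [
            ((1.0, 0.0), (0.0, 0.0), 1.0, (-1.0, 0.0)),
            ((0.3, -0.2), (0.5, 0.5), 0.0, (-0.3, 0.2)),
            ((0.0, 0.0), (0.3, -0.3), 1.0, (0.3, -0.3)),
        ],
    )
    def test_combination(self, x_dp, y_stn, w, expected):
        p = NetworkParams(w_stn_gpi=w)
        out = gpi_combine(np.array(x_dp), np.array(y_stn), p)
        assert out == pytest.approx(expected)


class TestThalamusSelect:
    def _select_many(self, w, sero, du, n, seed0=0, **kw):
        picks = np.empty(n, dtype=int)
        for i in range(n):
            gen = np.random.default_rng(seed0 + i)
            picks[i], _ = thalamus_select(w, GPI, sero, du, 0, NetworkParams(), gen, **kw)
        return picks

    def test_dp_dominance_with_silenced_stn(self, rng):
        w = _weights(rng)
        w.w_d1[0] = [1.0, 0.0]
        a, _ = thalamus_select(
            w, GPI, SerotoninParams(), 1.0, 0, NetworkParams(), rng, silence_stn=True
        )
        assert a == 0

    def test_symmetric_inputs_select_each_action_half_the_time(self, rng):
        w = _weights(rng)
        w.w_d1[0] = [0.5, 0.5]
        w.w_d2[0] = [0.5, 0.5]
        w.w_d1d2[0] = [0.5, 0.5]
        picks = self._select_many(w, SerotoninParams(), 0.0, 10_000)
        assert abs((picks == 0).mean() - 0.5) < 0.02

    def test_exploration_regime_without_striatal_drive(self, rng):
        # all serotonin multipliers zero: selection driven by STN-GPe alone
        w = _weights(rng)
        picks = self._select_many(w, SerotoninParams(0.0, 0.0, 0.0), 0.7, 10_000)
        assert abs((picks == 0).mean() - 0.5) < 0.05

    def test_exploitation_limit(self, rng):
        """Strong positive utility gradient with a dominant value channel
        selects that channel on almost every decision (Go pathway)."""
        w = _weights(rng)
        w.w_d1[0] = [5.0, 0.1]
        w.w_d2[0] = [0.1, 0.1]
        w.w_d1d2[0] = [0.1, 0.1]
        picks = self._select_many(w, SerotoninParams(), 2.0, 1000)
        assert (picks == 0).mean() > 0.95

    def test_thalamic_afferent_negates_gpi(self, rng):
        w = _weights(rng)
        _, dyn = thalamus_select(
            w, GPI, SerotoninParams(), 0.2, 0, NetworkParams(), rng, record_trace=True
        )
        x_gpi = dyn.trace[:, 3]
        y_thal = dyn.trace[:, 4]
        # unit-step Euler makes the thalamic state equal its afferent -x_GPi
        assert np.allclose(y_thal, -x_gpi, atol=1e-14)

    def test_deterministic_under_seed(self, rng):
        w = _weights(rng)
        out1 = [
            thalamus_select(
                w, GPI, SerotoninParams(), 0.1, 0, NetworkParams(), np.random.default_rng(k)
            )[0]
            for k in range(20)
        ]
        out2 = [
            thalamus_select(
                w, GPI, SerotoninParams(), 0.1, 0, NetworkParams(), np.random.default_rng(k)
            )[0]
            for k in range(20)
        ]
        assert out1 == out2

    def test_nonfinite_weights_raise_diagnostic(self, rng):
        w = _weights(rng)
        w.w_d1[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            thalamus_select(w, GPI, SerotoninParams(), 0.5, 0, NetworkParams(), rng)


class TestTraceExport:
    def test_trace_frame_layout(self, rng):
        from bgrl.bg_network import trace_frame

        w = _weights(rng)
        _, dyn = thalamus_select(
            w, GPI, SerotoninParams(), 0.1, 0, NetworkParams(), rng, record_trace=True
        )
        df = trace_frame(dyn)
        assert list(df.columns) == ["step", "channel", "x_stn", "x_gpe", "y_stn", "x_gpi", "y_thal"]
        assert len(df) == 25 * 2
        assert np.allclose(df.y_thal, -df.x_gpi)

    def test_trace_frame_requires_recording(self, rng):
        from bgrl.bg_network import trace_frame

        w = _weights(rng)
        _, dyn = thalamus_select(w, GPI, SerotoninParams(), 0.1, 0, NetworkParams(), rng)
        with pytest.raises(ValueError):
            trace_frame(dyn)
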