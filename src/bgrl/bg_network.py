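"""Downstream action-selection dynamics: direct/indirect pathways, the
coupled STN-GPe system, GPi combination and thalamic integration.

One decision integrates the excitatory-inhibitory STN-GPe loop for a fixed
number of Euler steps while the striatal drive is held constant, then picks
the action channel with the largest thalamic activation.  The loop's
bi-directional connectivity sustains bounded, non-constant (chaotic)
activity, which supplies the exploratory stochasticity that a softmax
temperature provides in the abstract model.  The utility gradient
``delta_U`` gates the pathways: strongly positive values open the direct
("Go") pathway and reselect the current best action, negative values hand
control to the indirect ("NoGo"/"Explore") pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neuromodulators import SerotoninParams
from .striatum import GainSet, MSNWeights

__all__ = [
    "NetworkParams",
    "BGDynamicsState",
    "dp_contribution",
    "ip_contribution",
    "step_stn_gpe",
    "gpi_combine",
    "thalamus_select",
    "trace_frame",
]


@dataclass(frozen=True)
class NetworkParams:
    """STN-GPe-GPi-thalamus constants.

    Lateral weights: within STN every neuron connects to every other with
    strength ``eps_s`` and to itself with ``1 + eps_s``; within GPe all
    connections (self included) have strength ``eps_g``.  The two nuclei
    are coupled one-to-one.  ``inv_tau_s``/``inv_tau_g`` are the Euler step
    sizes of the two layers, ``lambda_stn`` the STN output (tanh) slope,
    ``w_stn_gpi`` the per-channel STN->GPi weight, and ``n_steps`` the
    number of integration steps per decision.
    """

    eps_s: float = 0.1
    eps_g: float = -0.1
    inv_tau_s: float = 0.1
    inv_tau_g: float = 0.033
    lambda_stn: float = 3.0
    w_stn_gpi: float = 1.0
    n_steps: int = 25
    init_scale: float = 0.1
    integral_argmax: bool = False


@dataclass
class BGDynamicsState:
    """Per-decision activation vectors over action channels."""

    x_stn: np.ndarray
    x_gpe: np.ndarray
    y_thal: np.ndarray

    @classmethod
    def random_init(
        cls, n_channels: int, rng: np.random.Generator, scale: float = 0.1
    ) -> "BGDynamicsState":
        """Small uniform random initial conditions in ``[-scale, scale]``
        for STN and GPe; thalamic activations start at zero."""
        return cls(
            x_stn=rng.uniform(-scale, scale, n_channels),
            x_gpe=rng.uniform(-scale, scale, n_channels),
            y_thal=np.zeros(n_channels),
        )

    def y_stn(self, lambda_stn: float) -> np.ndarray:
        return np.tanh(lambda_stn * self.x_stn)


def dp_contribution(
    weights: MSNWeights,
    gains_gpi: GainSet,
    alpha_d1: float,
    du: float,
    state: int,
) -> np.ndarray:
    """Direct-pathway drive per channel:
    ``x_DP[i] = alpha_D1 * lambda^GPi_D1(delta_U) * y_D1(s, a_i)``.

    ``delta_U`` is a single scalar shared across channels."""
    return alpha_d1 * gains_gpi.d1(du) * weights.w_d1[state]


def ip_contribution(
    weights: MSNWeights,
    gains_gpi: GainSet,
    alpha_d2: float,
    alpha_d1d2: float,
    du: float,
    state: int,
    *,
    sign_term: bool = True,
) -> np.ndarray:
    """Indirect-pathway (striatum -> GPe) drive per channel: the D2 term
    plus the signed risk term from the co-expressing pool,
    ``alpha_D2 * lambda^GPi_D2(dU) * y_D2
    + alpha_D1D2 * sign(y_D1) * lambda^GPi_D1D2(dU) * y_D1D2``.

    ``sign(0) = 0``; ``sign_term=False`` ablates the sign factor.
    """
    y_d1 = weights.w_d1[state]
    y_d2 = weights.w_d2[state]
    y_d1d2 = weights.w_d1d2[state]
    if gains_gpi.d2 is None:
        raise ValueError("indirect pathway requires a D2 gain function")
    s = np.sign(y_d1) if sign_term else 1.0
    return (
        alpha_d2 * gains_gpi.d2(du) * y_d2
        + alpha_d1d2 * s * gains_gpi.d1d2(du) * y_d1d2
    )


def step_stn_gpe(
    state: BGDynamicsState, x_ip: np.ndarray, params: NetworkParams
) -> BGDynamicsState:
    """One explicit-Euler step of the coupled STN-GPe system.

    STN receives its lateral input plus inhibition from GPe; GPe receives
    its (uniformly inhibitory) lateral input, excitation from STN, and
    inhibition from the striatal indirect-pathway drive ``x_ip``.  The
    complete uniform connectivity lets the lateral terms reduce to sums:
    ``W_STN @ y = y + eps_s * sum(y)`` and ``W_GPe @ x = eps_g * sum(x)``.
    """
    x_stn, x_gpe = state.x_stn, state.x_gpe
    if x_ip.shape != x_gpe.shape:
        raise ValueError("x_IP dimension does not match the number of channels")
    y_stn = np.tanh(params.lambda_stn * x_stn)
    dx_stn = params.inv_tau_s * (-x_stn + y_stn + params.eps_s * y_stn.sum() - x_gpe)
    dx_gpe = params.inv_tau_g * (-x_gpe + params.eps_g * x_gpe.sum() + y_stn - x_ip)
    state.x_stn = x_stn + dx_stn
    state.x_gpe = x_gpe + dx_gpe
    return state


def gpi_combine(x_dp: np.ndarray, y_stn: np.ndarray, params: NetworkParams) -> np.ndarray:
    """GPi activation ``x_GPi = -x_DP + w_STN-GPi * y_STN`` per channel."""
    return -x_dp + params.w_stn_gpi * y_stn


def thalamus_select(
    weights: MSNWeights,
    gains_gpi: GainSet,
    neuromod: SerotoninParams,
    du: float,
    state: int,
    params: NetworkParams,
    rng: np.random.Generator,
    *,
    sign_term: bool = True,
    silence_stn: bool = False,
    dynamics: BGDynamicsState | None = None,
    record_trace: bool = False,
):
    """Run one decision and return ``(action, dynamics)``.

    The striatal drives ``x_DP``/``x_IP`` are held constant over the
    ``n_steps`` joint Euler steps of STN-GPe and thalamus.  The thalamic
    afferent is the exact negation of GPi output
    (``x_Thal = x_DP - w * y_STN = -x_GPi``) and thalamic neurons follow
    ``dy/dt = -y + x`` integrated with unit-step Euler.  The winner is the
    channel with maximal thalamic activation at the last step (or of the
    running time-integral when ``params.integral_argmax``); exact ties are
    broken uniformly at random.

    ``dynamics`` may carry STN-GPe state persisted from a previous
    decision; by default fresh small random initial conditions are drawn
    from ``rng``.  With ``record_trace`` the returned dynamics object gains
    a ``trace`` attribute: an ``(n_steps, 5, n)`` array of per-step
    ``x_stn, x_gpe, y_stn, x_gpi, y_thal``.
    """
    n = weights.n_actions
    x_dp = dp_contribution(weights, gains_gpi, neuromod.alpha_d1, du, state)
    x_ip = ip_contribution(
        weights,
        gains_gpi,
        neuromod.alpha_d2,
        neuromod.alpha_d1d2,
        du,
        state,
        sign_term=sign_term,
    )
    if dynamics is None:
        dynamics = BGDynamicsState.random_init(n, rng, params.init_scale)
    else:
        dynamics.y_thal = np.zeros(n)

    trace = np.empty((params.n_steps, 5, n)) if record_trace else None
    integral = np.zeros(n)
    for t in range(params.n_steps):
        step_stn_gpe(dynamics, x_ip, params)
        y_stn = np.tanh(params.lambda_stn * dynamics.x_stn)
        if silence_stn:
            y_stn = np.zeros(n)
        x_gpi = gpi_combine(x_dp, y_stn, params)
        x_thal = -x_gpi
        # unit-step Euler of dy/dt = -y + x collapses to y := x
        dynamics.y_thal = dynamics.y_thal + (-dynamics.y_thal + x_thal)
        integral += dynamics.y_thal
        if record_trace:
            trace[t, 0] = dynamics.x_stn
            trace[t, 1] = dynamics.x_gpe
            trace[t, 2] = y_stn
            trace[t, 3] = x_gpi
            trace[t, 4] = dynamics.y_thal

    score = integral if params.integral_argmax else dynamics.y_thal
    if not np.all(np.isfinite(score)):
        raise FloatingPointError(
            f"non-finite thalamic activation {score!r} (state={state}, dU={du}, "
            f"params={params})"
        )
    best = np.flatnonzero(score == score.max())
    action = int(best[0]) if best.size == 1 else int(rng.choice(best))
    if record_trace:
        dynamics.trace = trace  # type: ignore[attr-defined]
    return action, dynamics


def trace_frame(dynamics: BGDynamicsState):
    """Tidy per-step trace of one decision for debugging.

    Requires a dynamics object returned by ``thalamus_select(...,
    record_trace=True)``; one row per (step, channel) with the STN, GPe,
    GPi and thalamic activations.
    """
    import pandas as pd

    trace = getattr(dynamics, "trace", None)
    if trace is None:
        raise ValueError("no trace recorded; call thalamus_select with record_trace=True")
    n_steps, _, n = trace.shape
    steps = np.repeat(np.arange(n_steps), n)
    chans = np.tile(np.arange(n), n_steps)
    cols = ["x_stn", "x_gpe", "y_stn", "x_gpi", "y_thal"]
    data = {"step": steps, "channel": chans}
    for j, c in enumerate(cols):
        data[c] = trace[:, j, :].ravel()
    return pd.DataFrame(data)
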