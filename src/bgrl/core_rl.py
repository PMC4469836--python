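"""Abstract (lumped) risk-sensitive reinforcement-learning model.

This module implements utility-based decision making without any network
machinery: a tabular value function ``Q`` learned by temporal-difference
(TD) updates, a tabular risk function ``h`` that tracks the variance of the
TD error, a mean--variance utility ``U = Q - alpha * sign(Q) * h`` and a
softmax policy.  The risk term flips sign with the sign of ``Q`` so the
agent is risk averse for gains and risk seeking for losses.

Besides standing on its own, this module serves as a brute-force oracle for
the striatal network model: with a linear dopamine gain the network's D1
weight trajectory must reproduce the Q trajectory here bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AbstractAgent",
    "td_error",
    "update_value",
    "risk_prediction_error",
    "update_risk",
    "utility",
    "softmax_policy",
]


def td_error(
    Q: np.ndarray,
    state: int,
    action: int,
    reward: float,
    *,
    gamma: float = 1.0,
    next_state: int | None = None,
    next_action: int | None = None,
    mode: str = "single_step",
) -> float:
    """TD (reward-prediction) error, the model's dopamine correlate.

    ``single_step`` gives ``r - Q(s, a)`` (immediate-reward tasks);
    ``multi_step`` gives ``r + gamma * Q(s', a') - Q(s, a)``.
    """
    if mode == "single_step":
        return float(reward - Q[state, action])
    if mode == "multi_step":
        if next_state is None or next_action is None:
            raise ValueError("multi_step TD error requires next_state and next_action")
        return float(reward + gamma * Q[next_state, next_action] - Q[state, action])
    raise ValueError(f"unknown TD mode: {mode!r}")


def update_value(Q: np.ndarray, state: int, action: int, delta: float, eta_q: float) -> np.ndarray:
    """In-place TD update ``Q(s,a) += eta_q * delta``; returns ``Q``."""
    if eta_q <= 0:
        raise ValueError("eta_q must be > 0")
    Q[state, action] += eta_q * delta
    return Q


def risk_prediction_error(delta: float, h: np.ndarray, state: int, action: int) -> float:
    """Risk prediction error ``xi = delta**2 - h(s, a)``.

    Its fixed point makes ``h`` an estimate of ``E[delta**2]``, i.e. the
    outcome variance once ``Q`` has converged to the mean reward.
    """
    return float(delta * delta - h[state, action])


def update_risk(h: np.ndarray, state: int, action: int, xi: float, eta_h: float) -> np.ndarray:
    """In-place risk update ``h(s,a) += eta_h * xi``; returns ``h``."""
    if eta_h <= 0:
        raise ValueError("eta_h must be > 0")
    h[state, action] += eta_h * xi
    return h


def utility(q_value: float, h_value: float, alpha: float, *, sign_term: bool = True) -> float:
    """Mean--variance utility ``U = Q - alpha * sign(Q) * h``.

    ``sign(0)`` is taken as 0, so utility degenerates to value at ``Q = 0``.
    With ``sign_term=False`` the sign factor is replaced by 1 (ablation of
    the non-linear risk sensitivity): the agent is then risk averse on both
    the gain and the loss side.
    """
    s = float(np.sign(q_value)) if sign_term else 1.0
    return float(q_value - alpha * s * h_value)


def softmax_policy(
    u_values: np.ndarray, beta: float, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    """Sample an action from ``P(a) = exp(beta*U_a) / sum_i exp(beta*U_i)``.

    Computed with max-subtraction for overflow safety.  Returns the sampled
    action index and the full probability vector.
    """
    u = np.asarray(u_values, dtype=float)
    if u.size == 0:
        raise ValueError("softmax_policy requires at least one action")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    z = beta * u
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    action = int(rng.choice(u.size, p=p))
    return action, p


@dataclass
class AbstractAgent:
    """Tabular utility-based RL agent over an enumerated state x action space.

    Parameters
    ----------
    Q, h
        Dense ``(n_states, n_actions)`` tables for value and risk.  Both
        start at zero by default; ``h`` is driven toward ``E[delta**2]``
        which is non-negative at the fixed point.
    gamma
        Discount factor (used only in multi-step mode).
    eta_q, eta_h
        Learning rates for the value and risk tables.
    alpha
        Risk-sensitivity coefficient (the lumped serotonin correlate).
    beta
        Softmax inverse temperature; 0 gives equiprobable actions.
    """

    Q: np.ndarray
    h: np.ndarray
    gamma: float = 1.0
    eta_q: float = 0.1
    eta_h: float = 0.1
    alpha: float = 0.0
    beta: float = 1.0
    sign_term: bool = True
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @classmethod
    def zeros(cls, n_states: int, n_actions: int, **kwargs) -> "AbstractAgent":
        return cls(Q=np.zeros((n_states, n_actions)), h=np.zeros((n_states, n_actions)), **kwargs)

    @property
    def n_actions(self) -> int:
        return self.Q.shape[1]

    def utilities(self, state: int) -> np.ndarray:
        """Per-action utilities in ``state`` under the current tables."""
        return np.array(
            [
                utility(self.Q[state, a], self.h[state, a], self.alpha, sign_term=self.sign_term)
                for a in range(self.n_actions)
            ]
        )

    def act(self, state: int) -> int:
        action, _ = softmax_policy(self.utilities(state), self.beta, self.rng)
        return action

    def observe(self, state: int, action: int, reward: float) -> tuple[float, float]:
        """Single-step learning update; returns ``(delta, xi)``."""
        delta = td_error(self.Q, state, action, reward, mode="single_step")
        update_value(self.Q, state, action, delta, self.eta_q)
        xi = risk_prediction_error(delta, self.h, state, action)
        update_risk(self.h, state, action, xi, self.eta_h)
        return delta, xi

    def to_frame(self):
        """Serialize the agent tables to a tidy (state, action, Q, h) table."""
        import pandas as pd

        ns, na = self.Q.shape
        rows = [
            (s, a, self.Q[s, a], self.h[s, a]) for s in range(ns) for a in range(na)
        ]
        return pd.DataFrame(rows, columns=["state", "action", "Q", "h"])
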