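"""Dopamine and serotonin correlates, and the Parkinson's-disease clamp.

Dopamine appears in three forms: the TD error ``delta = r - Q`` driving
cortico-striatal plasticity, the utility gradient ``delta_U`` gating the
direct vs. indirect pathway at GPi, and ``sign(Q)`` controlling the
non-linear risk sensitivity.  Tonic serotonin is parameterized as three
non-negative multipliers ``alpha_D1, alpha_D2, alpha_D1D2`` on the three
MSN pools' pathway outputs.

Parkinson's disease is modeled by clamping the plasticity dopamine signal:
OFF medication caps ``delta`` at ``delta_lim``; ON medication additionally
adds a fixed medication increment ``delta_med``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .striatum import MSNWeights

__all__ = [
    "SerotoninParams",
    "PDCondition",
    "CONTROL",
    "compute_delta",
    "apply_pd",
]

_STATUSES = ("control", "pd_off", "pd_on")


@dataclass(frozen=True)
class SerotoninParams:
    """Tonic serotonin multipliers on the D1R, D2R and D1R-D2R pools."""

    alpha_d1: float = 1.0
    alpha_d2: float = 1.0
    alpha_d1d2: float = 1.0

    def __post_init__(self):
        if self.alpha_d1 < 0 or self.alpha_d2 < 0 or self.alpha_d1d2 < 0:
            raise ValueError("serotonin alphas must be >= 0")


@dataclass(frozen=True)
class PDCondition:
    """Dopamine-availability condition.

    ``control`` leaves ``delta`` untouched.  ``pd_off`` caps it at
    ``delta_lim`` (degenerated SNc can signal reliably only at low rates);
    ``pd_on`` additionally adds the medication increment ``delta_med`` on
    every trial, so the attainable range becomes ``delta_lim + delta_med``
    -- still below the healthy ceiling.
    """

    status: str = "control"
    delta_lim: float = 0.0
    delta_med: float = 0.0

    def __post_init__(self):
        if self.status not in _STATUSES:
            raise ValueError(f"unknown PD status: {self.status!r}")


CONTROL = PDCondition()


def compute_delta(weights: MSNWeights, state: int, action: int, reward: float) -> float:
    """Immediate-reward TD error ``delta = r - y_D1(s, a)``."""
    return float(reward - weights.w_d1[state, action])


def apply_pd(delta: float, condition: PDCondition) -> float:
    """Clamp the plasticity dopamine signal per the PD condition.

    Monotone non-decreasing in ``delta``; the identity map for controls.
    Negative ``delta`` always passes through, which is why OFF-state
    learning keeps punishment sensitivity while positive surprises are
    crippled.
    """
    if condition.status == "control":
        return delta
    clamped = min(delta, condition.delta_lim)
    if condition.status == "pd_on":
        clamped += condition.delta_med
    return clamped
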