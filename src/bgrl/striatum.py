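"""Striatal medium-spiny-neuron (MSN) model: dopamine gain functions,
cortico-striatal weights, and value/risk/utility readout.

Three MSN pools are modeled.  D1-receptor-expressing MSNs compute value
(``Q = y_D1``), D1R-D2R co-expressing MSNs compute risk (``h = y_D1D2``),
and D2R MSNs feed the indirect pathway.  Dopamine (the TD error ``delta``)
enters Hebbian plasticity through sigmoidal gain functions whose constants
``(c1, c2, c3)`` encode the receptor type: an increasing sigmoid for D1R,
a decreasing one for D2R, and for the co-expressing pool the sum of two
unipolar sigmoids which -- when mirror-symmetric -- is an even, U-shaped
function of ``delta``, exactly what is needed to track ``delta**2`` and
hence outcome variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GainParams",
    "GainSet",
    "MSNWeights",
    "GAIN_PRESETS",
    "evaluate_gain",
    "d1d2_gain",
    "msn_response",
    "update_weights",
    "network_utility",
    "utility_vector",
    "delta_u",
]

_FORMS = ("tangent_sigmoid", "log_sigmoid", "linear")

# exp() argument clip; exp(+-500) already saturates both sigmoid forms to
# double precision, and clipping avoids overflow warnings at extreme delta
_ZMAX = 500.0


@dataclass(frozen=True)
class GainParams:
    """One dopamine gain function ``lambda(delta)``.

    ``tangent_sigmoid``: ``2*c1/(1 + exp(c2*(delta + c3))) - c1`` -- bipolar,
    range ``(-c1, c1)``.  ``log_sigmoid``: ``c1/(1 + exp(c2*(delta + c3)))``
    -- unipolar, range ``(0, c1)``.  The sign of ``c2`` carries the receptor
    direction (negative: increasing with dopamine, D1-like; positive:
    decreasing, D2-like).  ``linear`` (``c1 * delta``) is provided for
    oracle equivalence with plain TD learning.
    """

    c1: float
    c2: float
    c3: float
    form: str = "tangent_sigmoid"

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown gain form: {self.form!r}")

    def __call__(self, delta):
        if self.form == "linear":
            return self.c1 * delta
        z = np.clip(self.c2 * (np.asarray(delta, dtype=float) + self.c3), -_ZMAX, _ZMAX)
        if self.form == "tangent_sigmoid":
            out = 2.0 * self.c1 / (1.0 + np.exp(z)) - self.c1
        else:
            out = self.c1 / (1.0 + np.exp(z))
        return float(out) if np.ndim(delta) == 0 else out


def evaluate_gain(params: GainParams, delta):
    """Evaluate one gain function; finite for all finite ``delta``."""
    return params(delta)


@dataclass(frozen=True)
class GainSet:
    """The gain functions used at one site.

    ``site`` is ``"striatal_plasticity"`` (gains of the weight updates,
    functions of the TD error ``delta``) or ``"gpi_selection"`` (gains of
    the pathway outputs at GPi, functions of the utility gradient
    ``delta_U``).  The co-expressing pool's gain is always the sum
    ``h_d1 + h_d2``; ``d2`` may be absent (the value/risk demonstration
    parameter set prints no D2 column).
    """

    d1: GainParams
    h_d1: GainParams
    h_d2: GainParams
    d2: GainParams | None = None
    site: str = "striatal_plasticity"

    def d1d2(self, delta):
        return self.h_d1(delta) + self.h_d2(delta)


def d1d2_gain(gains: GainSet, delta):
    """Co-expressing-pool gain ``lambda_D1D2 = lambda_h-D1 + lambda_h-D2``."""
    return gains.d1d2(delta)


def _g(c1, c2, c3, form):
    return GainParams(c1=c1, c2=c2, c3=c3, form=form)


#: Named gain presets, keyed by the parameter table they implement.
#: table1: striatal demonstration set (value/risk readout figure);
#: table3: GPi action-selection gains shared by all three experiments;
#: table5/6/8: striatal plasticity gains of the risk, reversal and
#: PD-classification experiments respectively.
GAIN_PRESETS: dict[str, GainSet] = {
    "table1": GainSet(
        d1=_g(1.0, -5.0, 0.0, "tangent_sigmoid"),
        h_d1=_g(0.1, -25.0, -0.5, "log_sigmoid"),
        h_d2=_g(0.1, 25.0, 0.5, "log_sigmoid"),
        site="striatal_plasticity",
    ),
    "table3": GainSet(
        d1=_g(1.0, -50.0, 0.01, "tangent_sigmoid"),
        d2=_g(1.0, 50.0, 0.01, "tangent_sigmoid"),
        h_d1=_g(0.05, -0.01, -0.05, "log_sigmoid"),
        h_d2=_g(0.05, 0.01, 0.05, "log_sigmoid"),
        site="gpi_selection",
    ),
    "table5": GainSet(
        d1=_g(10.0, -0.1, 0.0, "tangent_sigmoid"),
        d2=_g(0.01, 0.05, 0.0, "tangent_sigmoid"),
        h_d1=_g(0.05, -5.0, -100.1, "log_sigmoid"),
        h_d2=_g(0.05, 0.5, 100.1, "log_sigmoid"),
        site="striatal_plasticity",
    ),
    "table6": GainSet(
        d1=_g(0.06, -0.155, -0.574, "tangent_sigmoid"),
        d2=_g(0.115, 0.488, 0.317, "tangent_sigmoid"),
        h_d1=_g(0.939, -0.188, -1.723, "log_sigmoid"),
        h_d2=_g(0.939, 0.188, 1.723, "log_sigmoid"),
        site="striatal_plasticity",
    ),
    "table8": GainSet(
        d1=_g(1.0, -50.0, 0.0, "tangent_sigmoid"),
        d2=_g(1.0, 50.0, -1.0, "tangent_sigmoid"),
        h_d1=_g(0.05, -0.01, -0.05, "log_sigmoid"),
        h_d2=_g(0.05, 0.01, 0.05, "log_sigmoid"),
        site="striatal_plasticity",
    ),
}


def mirror_symmetric_h(gains: GainSet, tol: float = 0.0) -> bool:
    """True when the two h-components are mirror images of each other
    (equal c1, opposite c2 and c3), which makes lambda_D1D2 an even
    function of delta."""
    a, b = gains.h_d1, gains.h_d2
    return (
        abs(a.c1 - b.c1) <= tol
        and abs(a.c2 + b.c2) <= tol
        and abs(a.c3 + b.c3) <= tol
    )


@dataclass
class MSNWeights:
    """Cortico-striatal weight tables for the three MSN pools.

    Each table is a dense ``(n_states, n_actions)`` array; the cortical
    state code is one-hot, so a pool's response to ``(s, a)`` is simply its
    weight entry and only the experienced entry changes per trial.
    """

    w_d1: np.ndarray
    w_d2: np.ndarray
    w_d1d2: np.ndarray
    eta_d1: float = 0.01
    eta_d2: float = 0.01
    eta_d1d2: float = 0.01

    def __post_init__(self):
        if not (self.eta_d1 > 0 and self.eta_d2 > 0 and self.eta_d1d2 > 0):
            raise ValueError("learning rates must be > 0")

    @classmethod
    def random_init(
        cls,
        n_states: int,
        n_actions: int,
        rng: np.random.Generator,
        etas: tuple[float, float, float] = (0.01, 0.01, 0.01),
    ) -> "MSNWeights":
        """Weights initialized uniformly at random in [0, 1) from the
        experiment's seeded RNG (the initialization used by every task)."""
        shape = (n_states, n_actions)
        return cls(
            w_d1=rng.uniform(0.0, 1.0, shape),
            w_d2=rng.uniform(0.0, 1.0, shape),
            w_d1d2=rng.uniform(0.0, 1.0, shape),
            eta_d1=etas[0],
            eta_d2=etas[1],
            eta_d1d2=etas[2],
        )

    @property
    def n_states(self) -> int:
        return self.w_d1.shape[0]

    @property
    def n_actions(self) -> int:
        return self.w_d1.shape[1]


def msn_response(weights: MSNWeights, state: int, action: int) -> tuple[float, float, float]:
    """Pool responses ``(y_D1, y_D2, y_D1D2)`` for a one-hot state code:
    the weight entries themselves.  ``Q = y_D1`` and ``h = y_D1D2``."""
    return (
        float(weights.w_d1[state, action]),
        float(weights.w_d2[state, action]),
        float(weights.w_d1d2[state, action]),
    )


def update_weights(
    weights: MSNWeights, gains_striatal: GainSet, state: int, action: int, delta: float
) -> MSNWeights:
    """Dopamine-gated Hebbian update of the experienced ``(s, a)`` entry.

    ``w_P(s,a) += eta_P * lambda^Str_P(delta)`` for each pool ``P``; the
    (possibly PD-clamped) ``delta`` must be supplied by the caller.
    """
    weights.w_d1[state, action] += weights.eta_d1 * gains_striatal.d1(delta)
    if gains_striatal.d2 is not None:
        weights.w_d2[state, action] += weights.eta_d2 * gains_striatal.d2(delta)
    weights.w_d1d2[state, action] += weights.eta_d1d2 * gains_striatal.d1d2(delta)
    return weights


def network_utility(
    weights: MSNWeights,
    alpha_d1d2: float,
    state: int,
    action: int,
    *,
    sign_term: bool = True,
) -> float:
    """Utility read out from the network: ``U = y_D1 - alpha_D1D2 *
    sign(y_D1) * y_D1D2`` with ``sign(0) = 0``.

    ``sign_term=False`` ablates the sign factor (replaced by 1)."""
    q = weights.w_d1[state, action]
    h = weights.w_d1d2[state, action]
    s = np.sign(q) if sign_term else 1.0
    return float(q - alpha_d1d2 * s * h)


def utility_vector(
    weights: MSNWeights, alpha_d1d2: float, state: int, *, sign_term: bool = True
) -> np.ndarray:
    """Per-action network utilities in ``state`` (vector over channels)."""
    q = weights.w_d1[state]
    h = weights.w_d1d2[state]
    s = np.sign(q) if sign_term else 1.0
    return q - alpha_d1d2 * s * h


def delta_u(u_current: float, u_previous: float) -> float:
    """Trial-to-trial change in utility, ``delta_U = U_t - U_{t-1}``.

    ``U_t`` is taken as the utility, under current weights, of the
    greedy-utility action in the current state; ``U_{t-1}`` is the stored
    utility of the previously executed action at its selection time.  On
    an agent's first trial the caller should use ``delta_U = 0``.
    """
    return float(u_current - u_previous)
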