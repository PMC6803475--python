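"""Hodgkin-Huxley point-neuron dynamics for the master and slave neurons.

The model is the classical four-state conductance description

    C dV/dt = I_ext - g_K n^4 (V - V_K) - g_Na m^3 h (V - V_Na) - g_L (V - V_L)
    dj/dt   = alpha_j(V) (1 - j) - beta_j(V) j,     j in {n, m, h}

with the rate functions used by the study this package reproduces.  Those
rates differ from the canonical 1952 fits (for instance the alpha_n
denominator uses 100 instead of 10, and beta_n = 0.15 exp(-V/100)); they are
implemented verbatim, and as a consequence the resting potential of the
model sits close to V_K rather than 0.  The sign convention is the original
Hodgkin-Huxley one (V_Na = -115, V_K = +12); all quantities are treated as
dimensionless simulation units carrying the printed numeric values.

Two parameter presets are bundled: ``master`` and a "slave" neuron whose
conductances and reversal potentials are 10% smaller, making the pair
dissimilar so that they do not synchronize spontaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HHParameters",
    "HHState",
    "MASTER",
    "SLAVE",
    "preset",
    "gating_rates",
    "hh_derivative",
    "equilibrium_gating",
]

#: Guard radius for the removable singularities of alpha_n and alpha_m.
_SINGULARITY_TOL = 1e-8


@dataclass(frozen=True)
class HHParameters:
    """Constants of one Hodgkin-Huxley neuron.

    Parameters
    ----------
    C : float
        Membrane capacitance (uF/cm^2), must be positive.
    g_K, g_Na, g_L : float
        Maximal potassium / sodium / leak conductances (mS/cm^2).
    V_K, V_Na, V_L : float
        Reversal (equilibrium) potentials (mV) of the three currents.
    """

    C: float
    g_K: float
    g_Na: float
    g_L: float
    V_K: float
    V_Na: float
    V_L: float

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise ValueError(f"membrane capacitance must be positive, got C={self.C}")
        for name in ("g_K", "g_Na", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be nonnegative, got {getattr(self, name)}")
        for name in ("C", "g_K", "g_Na", "g_L", "V_K", "V_Na", "V_L"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")


@dataclass(frozen=True)
class HHState:
    """Instantaneous state (V, n, m, h) of one neuron.

    ``V`` is the membrane potential; ``n``, ``m``, ``h`` are the
    dimensionless gating variables (potassium activation, sodium activation
    and sodium inactivation).  Along any trajectory started with gating
    values inside [0, 1] the rates keep them there up to integrator
    round-off.
    """

    V: float
    n: float
    m: float
    h: float

    def as_array(self):
        import numpy as np

        return np.array([self.V, self.n, self.m, self.h], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "HHState":
        V, n, m, h = (float(v) for v in arr)
        return cls(V, n, m, h)


# Parameter presets: the master set and the 10%-detuned slave set.
MASTER = HHParameters(C=1.0, g_K=36.0, g_Na=120.0, g_L=0.3,
                      V_K=12.0, V_Na=-115.0, V_L=-10.613)
# The slave's leak potential is -9.5517 (0.9 * the master's);
# every slave constant is the master's scaled by 0.9.
SLAVE = HHParameters(C=0.9, g_K=32.4, g_Na=108.0, g_L=0.27,
                     V_K=10.8, V_Na=-103.5, V_L=-9.5517)

_PRESETS = {"master_table1": MASTER, "slave_table1": SLAVE,
            "master": MASTER, "slave": SLAVE}


def preset(name: str) -> HHParameters:
    """Return a bundled parameter preset by name (``master`` / ``slave``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown HH preset {name!r}; available: {sorted(_PRESETS)}") from None


def _ratio(a: float, c: float) -> float:
    """a / (exp(a/c) - 1) with the analytic limit c as a -> 0."""
    if abs(a) < _SINGULARITY_TOL:
        return c
    return a / math.expm1(a / c)


def gating_rates(V: float):
    """Voltage-dependent opening/closing rates of the three gates.

    Returns ``(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)``.  The
    removable singularities of ``alpha_n`` (V = 100) and ``alpha_m``
    (V = 15) are evaluated by their analytic limits.  All six rates are
    strictly positive for every finite V, which is what confines the gating
    variables to [0, 1].
    """
    V = float(V)
    if not math.isfinite(V):
        raise ValueError(f"membrane potential must be finite, got {V}")
    alpha_n = 0.1 * _ratio(100.0 - V, 100.0)
    beta_n = 0.15 * math.exp(-V / 100.0)
    alpha_m = 0.1 * _ratio(15.0 - V, 5.0)
    beta_m = 4.0 * math.exp(-V / 10.0)
    alpha_h = 0.08 * math.exp(-V / 10.0)
    beta_h = 1.0 / (math.exp((30.0 - V) / 10.0) + 1.0)
    return alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h


def hh_derivative(state: HHState, params: HHParameters,
                  i_ext: float = 0.0, u: float = 0.0) -> HHState:
    """Time derivative of an HH state.

    ``i_ext`` is the external stimulus current; ``u`` is an additive
    feedback input on the membrane equation (used by the slave neuron; the
    master runs with ``u = 0``).  The derivative is exactly linear in both.
    """
    V, n, m, h = state.V, state.n, state.m, state.h
    a_n, b_n, a_m, b_m, a_h, b_h = gating_rates(V)
    i_K = params.g_K * n ** 4 * (V - params.V_K)
    i_Na = params.g_Na * m ** 3 * h * (V - params.V_Na)
    i_L = params.g_L * (V - params.V_L)
    dV = (i_ext - i_K - i_Na - i_L) / params.C + u
    return HHState(
        V=dV,
        n=a_n * (1.0 - n) - b_n * n,
        m=a_m * (1.0 - m) - b_m * m,
        h=a_h * (1.0 - h) - b_h * h,
    )


def equilibrium_gating(V: float):
    """Steady-state gating values ``(n_inf, m_inf, h_inf)`` at potential V.

    Each is ``alpha / (alpha + beta)``, the fixed point of the gating ODE
    at frozen V; useful for initializing a neuron at rest.
    """
    a_n, b_n, a_m, b_m, a_h, b_h = gating_rates(V)
    out = []
    for a, b in ((a_n, b_n), (a_m, b_m), (a_h, b_h)):
        s = a + b
        if s <= 0.0:
            raise ZeroDivisionError(f"degenerate gating rates at V={V}: alpha+beta={s}")
        out.append(a / s)
    return tuple(out)
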