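"""Prescribed-performance funnel and the bijective error transformation.

The synchronization error e(t) is required to evolve inside a shrinking
envelope ("funnel") built from the performance function

    beta(t) = (beta0 - beta_inf) * exp(-kappa t) + beta_inf

If the error starts nonnegative the admissible band is
(-H beta(t), beta(t)); if it starts nonpositive the band mirrors to
(-beta(t), H beta(t)).  The fraction H in (0, 1] caps the allowed
overshoot on the far side of zero.  A logistic-type bijection R maps the
open band onto the whole real line, turning the constrained problem into
an unconstrained one for the filtered error

    eps = ln[(H + e/beta) / (1 - e/beta)]        (nonnegative branch)
    eps = ln[(1 + e/beta) / (H - e/beta)]        (nonpositive branch)

phi = d eps / d e is the (always positive) transformation slope and gamma
collects the drift contributed by the shrinking envelope.  Contact of the
error with a funnel wall invalidates the transformation; it is reported as
a structured :class:`FunnelViolationError` rather than masked by clipping.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "PerformanceSpec",
    "FunnelBranch",
    "FunnelViolationError",
    "branch_for",
    "beta",
    "beta_dot",
    "funnel_bounds",
    "transform_R",
    "inverse_transform",
    "phi",
    "phi_partials",
    "gamma",
]


@dataclass(frozen=True)
class PerformanceSpec:
    """Funnel geometry: initial height, asymptotic height, decay rate, overshoot fraction.

    Defaults are the study's instance beta(t) = 0.28 exp(-0.6 t) + 0.02
    with overshoot fraction H = 0.9.
    """

    beta0: float = 0.3
    beta_inf: float = 0.02
    kappa: float = 0.6
    H: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.beta_inf <= self.beta0):
            raise ValueError(
                f"require 0 < beta_inf <= beta0, got beta_inf={self.beta_inf}, beta0={self.beta0}")
        if not (self.kappa > 0):
            raise ValueError(f"decay rate kappa must be positive, got {self.kappa}")
        if not (0.0 < self.H <= 1.0):
            raise ValueError(f"overshoot fraction H must lie in (0, 1], got {self.H}")


class FunnelBranch(enum.Enum):
    """Which side the error started on; fixed for the whole run.

    A zero initial error is assigned to the nonnegative branch.
    """

    NONNEGATIVE = "e0>=0"
    NONPOSITIVE = "e0<=0"


def branch_for(e0: float) -> FunnelBranch:
    """Branch selected by the sign of the initial error."""
    return FunnelBranch.NONNEGATIVE if e0 >= 0.0 else FunnelBranch.NONPOSITIVE


class FunnelViolationError(RuntimeError):
    """The error touched or crossed a funnel wall: the performance guarantee is lost.

    Attributes carry the offending time, error value and the wall positions
    so callers can diagnose (and a simulation can abort with context).
    """

    def __init__(self, t: float, e: float, lower: float, upper: float):
        self.t = t
        self.e = e
        self.lower = lower
        self.upper = upper
        super().__init__(
            f"error e={e:.6g} left the prescribed funnel ({lower:.6g}, {upper:.6g}) at t={t:.6g}")


def beta(t, spec: PerformanceSpec):
    """Performance function beta(t); strictly decreasing from beta0 to beta_inf."""
    if isinstance(t, (int, float)):
        if t < 0:
            raise ValueError(f"beta(t) is defined for t >= 0, got t={t}")
        return (spec.beta0 - spec.beta_inf) * math.exp(-spec.kappa * t) + spec.beta_inf
    import numpy as np

    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("beta(t) is defined for t >= 0")
    return (spec.beta0 - spec.beta_inf) * np.exp(-spec.kappa * t) + spec.beta_inf


def beta_dot(t, spec: PerformanceSpec):
    """d beta / dt = -kappa (beta0 - beta_inf) exp(-kappa t); nonpositive."""
    if isinstance(t, (int, float)):
        return -spec.kappa * (spec.beta0 - spec.beta_inf) * math.exp(-spec.kappa * t)
    import numpy as np

    return -spec.kappa * (spec.beta0 - spec.beta_inf) * np.exp(-spec.kappa * np.asarray(t, dtype=float))


def funnel_bounds(t, spec: PerformanceSpec, branch: FunnelBranch):
    """Open interval (lower, upper) the error must occupy at time t."""
    b = beta(t, spec)
    if branch is FunnelBranch.NONNEGATIVE:
        return -spec.H * b, b
    return -b, spec.H * b


def transform_R(eps: float, spec: PerformanceSpec, branch: FunnelBranch) -> float:
    """Normalized error ratio e/beta as a function of the filtered error.

    Strictly increasing and smooth, with range (-H, 1) on the nonnegative
    branch and (-1, H) on the mirrored one.
    """
    H = spec.H
    ex = math.exp(eps)
    if branch is FunnelBranch.NONNEGATIVE:
        return (ex - H) / (1.0 + ex)
    return (H * ex - 1.0) / (1.0 + ex)


def inverse_transform(e: float, t: float, spec: PerformanceSpec,
                      branch: FunnelBranch) -> float:
    """Filtered error eps = R^{-1}(e / beta(t)).

    Grows without bound as the error approaches the upper wall (and to
    -inf at the lower wall).  Raises :class:`FunnelViolationError` if the
    error is on or outside the walls.
    """
    b = beta(t, spec)
    H = spec.H
    ehat = e / b
    if branch is FunnelBranch.NONNEGATIVE:
        num, den = H + ehat, 1.0 - ehat
    else:
        num, den = 1.0 + ehat, H - ehat
    if num <= 0.0 or den <= 0.0:
        lo, up = funnel_bounds(t, spec, branch)
        raise FunnelViolationError(t, e, lo, up)
    return math.log(num / den)


def phi(e: float, t: float, spec: PerformanceSpec, branch: FunnelBranch) -> float:
    """Transformation slope phi = d eps / d e > 0; diverges at the walls."""
    return phi_partials(e, t, spec, branch)[0]


def phi_partials(e: float, t: float, spec: PerformanceSpec, branch: FunnelBranch):
    """phi together with its partial derivatives (phi, dphi/de, dphi/dt).

    The partials are what the gain k(t) = k1 + k2 - phi_dot / (2 phi^2)
    needs, since phi_dot = (dphi/de) de/dt + dphi/dt along a trajectory.
    """
    b = beta(t, spec)
    bd = beta_dot(t, spec)
    H = spec.H
    if branch is FunnelBranch.NONNEGATIVE:
        d1 = H * b + e    # distance to the lower wall
        d2 = e - b        # negative distance to the upper wall
        w1 = H * bd
    else:
        d1 = b + e
        d2 = e - H * b
        w1 = bd
        bd = H * bd       # wall speed attached to d2
    if d1 <= 0.0 or d2 >= 0.0:
        lo, up = funnel_bounds(t, spec, branch)
        raise FunnelViolationError(t, e, lo, up)
    p = 1.0 / d1 - 1.0 / d2
    dp_de = -1.0 / d1 ** 2 + 1.0 / d2 ** 2
    dp_dt = -w1 / d1 ** 2 - bd / d2 ** 2
    return p, dp_de, dp_dt


def gamma(e: float, t: float, spec: PerformanceSpec, branch: FunnelBranch) -> float:
    """Envelope-shrinkage drift gamma = phi * (beta_dot / beta) * e."""
    p = phi(e, t, spec, branch)
    return p * (beta_dot(t, spec) / beta(t, spec)) * e
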