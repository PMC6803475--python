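"""Synchronization-quality metrics against the prescribed funnel.

The report quantifies how a run performed relative to the performance
envelope: overshoot past zero (opposite to the initial error's sign),
worst error over the steady-state window, the time after which the error
stays below the asymptotic envelope height, and pointwise funnel
compliance.  Overshoot is reported in absolute error units and, for
traceability, as a percentage of the initial envelope height beta0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prescribed_performance import FunnelBranch, PerformanceSpec, beta

__all__ = ["MetricsReport", "compute_metrics", "compare_controllers"]


@dataclass(frozen=True)
class MetricsReport:
    """Per-run synchronization metrics (all finite for a completed run)."""

    e0: float
    max_overshoot: float
    max_overshoot_pct_beta0: float
    steady_state_error: float
    convergence_time: float
    funnel_compliant: bool
    first_violation_time: float | None
    sup_eps: float
    sup_weight_norm: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compute_metrics(traj, spec: PerformanceSpec, branch: FunnelBranch,
                    steady_window_fraction: float = 0.2) -> MetricsReport:
    """Metrics of one trajectory against a funnel specification.

    ``steady_window_fraction`` selects the final fraction of the run as
    the steady-state window (the run length is configurable, so the
    window is relative rather than a fixed time).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    t = traj.t
    e = traj.e
    b = beta(t, spec)
    if branch is FunnelBranch.NONNEGATIVE:
        lower, upper = -spec.H * b, b
        overshoot = np.maximum(0.0, -e)
    else:
        lower, upper = -b, spec.H * b
        overshoot = np.maximum(0.0, e)

    inside = (e > lower) & (e < upper)
    compliant = bool(np.all(inside)) and traj.status != "funnel_violation"
    first_violation = None
    if not np.all(inside):
        first_violation = float(t[np.argmax(~inside)])
    elif traj.status == "funnel_violation":
        first_violation = float(traj.t_stop)

    n = len(t)
    steady = slice(int(np.floor((1.0 - steady_window_fraction) * n)), n)
    sse = float(np.max(np.abs(e[steady])))

    # first time after which |e| stays below the asymptotic envelope height
    below = np.abs(e) < spec.beta_inf
    conv = np.inf
    if below[-1]:
        idx = np.where(~below)[0]
        conv = float(t[idx[-1] + 1]) if len(idx) and idx[-1] + 1 < n else float(t[0])

    eps = traj.eps
    sup_eps = float(np.nanmax(np.abs(eps))) if np.any(np.isfinite(eps)) else float("nan")

    return MetricsReport(
        e0=float(e[0]),
        max_overshoot=float(np.max(overshoot)),
        max_overshoot_pct_beta0=float(np.max(overshoot) / spec.beta0 * 100.0),
        steady_state_error=sse,
        convergence_time=conv,
        funnel_compliant=compliant,
        first_violation_time=first_violation,
        sup_eps=sup_eps,
        sup_weight_norm=float(np.max(traj.w_norm)),
    )


def compare_controllers(trajectories: dict, spec: PerformanceSpec,
                        branch: FunnelBranch,
                        post_transient_fraction: float = 0.5) -> pd.DataFrame:
    """Tabulate metrics of several runs of the same plant side by side.

    ``trajectories`` maps a label (e.g. the controller name) to a
    trajectory.  All runs must share the master configuration and
    duration, otherwise the comparison is meaningless and a ValueError is
    raised.  The returned frame adds the post-transient worst error (final
    ``post_transient_fraction`` of the run) and flags the run with the
    smallest one.
    """
    if not trajectories:
        raise ValueError("no trajectories to compare")
    items = list(trajectories.items())
    ref = items[0][1]
    for label, traj in items[1:]:
        if traj.metadata.get("master") != ref.metadata.get("master") or \
           traj.metadata.get("tmas_master") != ref.metadata.get("tmas_master"):
            raise ValueError(f"run {label!r} has a different master configuration")
        if abs(traj.metadata["sim"]["duration"] - ref.metadata["sim"]["duration"]) > 0:
            raise ValueError(f"run {label!r} has a different duration")

    rows = {}
    for label, traj in items:
        rep = compute_metrics(traj, spec, branch)
        n = len(traj)
        post = slice(int((1.0 - post_transient_fraction) * n), n)
        rows[label] = {**rep.as_dict(),
                       "post_transient_sup_e": float(np.max(np.abs(traj.e[post])))}
    frame = pd.DataFrame(rows).T
    best = frame["post_transient_sup_e"].astype(float).idxmin()
    frame["smallest_post_transient_error"] = [lbl == best for lbl in frame.index]
    return frame
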