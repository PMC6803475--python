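"""Closed-loop master-slave simulation.

Assembles master neuron, slave neuron, magneto-acoustic stimuli, funnel,
controller and adaptive weights into one coupled ODE and integrates it
with a fixed-step scheme.  The public entry point is :func:`run`, which
takes a (possibly partial) configuration mapping, validates it against
the bundled defaults, and returns a :class:`Trajectory`.

Error convention: the synchronization error is ``e = x_S,1 - x_M,1`` by
default (the slave's membrane potential minus the master's), which makes
the bundled initial conditions give ``e(0) = 0.2``; the opposite
convention is available through ``error_sign: master_minus_slave``.

The solver clock is dimensionless simulation time; the stimulus clock is
``time_scale`` times it (default 1, i.e. the solver clock is read as
seconds against the stimulus frequencies in Hz).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import _engine
from .controllers import MECState, ObserverState, PPCGains, phi_dot_closure
from .hh_model import HHParameters, HHState, MASTER, SLAVE
from .prescribed_performance import (FunnelBranch, FunnelViolationError,
                                     PerformanceSpec, branch_for, funnel_bounds)
from .rbf_approximator import NNInputMap, RBFApproximator, grid_centers
from .tmas_stimulus import TMASParameters, stimulus_current

__all__ = [
    "SimulationConfig",
    "ResolvedConfig",
    "Trajectory",
    "ConfigError",
    "default_config",
    "validate_config",
    "assemble_state",
    "unpack_state",
    "global_derivative",
    "run",
]

CONTROLLER_TYPES = ("none", "ppc", "observer", "mec")
_CTRL_CODES = {"none": _engine.CTRL_NONE, "ppc": _engine.CTRL_PPC,
               "observer": _engine.CTRL_OBSERVER, "mec": _engine.CTRL_MEC}
_ZMAP_CODES = {"error": _engine.ZMAP_ERROR, "potentials": _engine.ZMAP_POTENTIALS,
               "full": _engine.ZMAP_FULL,
               "potentials_normalized": _engine.ZMAP_POTENTIALS_NORM}


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``dt`` is the fixed solver step and ``duration`` the simulated span,
    both in solver-clock units; ``record_every`` decimates the stored
    output; ``time_scale`` converts the solver clock to the stimulus clock
    (seconds).  ``seed`` is recorded in the metadata but unused: the
    system is fully deterministic.
    """

    dt: float = 5e-6
    duration: float = 30.0
    record_every: int = 40
    time_scale: float = 1.0
    solver: str = "rk4"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not (self.duration > self.dt):
            raise ValueError(f"duration must exceed dt, got {self.duration}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every}")
        if self.solver not in ("rk4", "euler"):
            raise ValueError(f"solver must be 'rk4' or 'euler', got {self.solver!r}")


@dataclass(frozen=True)
class ResolvedConfig:
    """Fully validated configuration bundle consumed by :func:`run`."""

    master: HHParameters
    slave: HHParameters
    tmas_master: TMASParameters
    tmas_slave: TMASParameters
    performance: PerformanceSpec
    rbf_nodes_per_dim: int
    rbf_bounds: tuple
    rbf_width: float
    rbf_adapt_gain: float
    rbf_leak: float
    input_map: NNInputMap
    controller: str
    gains: PPCGains
    phi_dot_mode: str
    det_guard: float
    gain_floor: float
    observer: ObserverState
    mec: MECState
    sim: SimulationConfig
    x_master0: tuple
    x_slave0: tuple
    error_sign: str = "slave_minus_master"

    @property
    def branch(self) -> FunnelBranch:
        return branch_for(self.initial_error)

    @property
    def initial_error(self) -> float:
        e0 = self.x_slave0[0] - self.x_master0[0]
        return e0 if self.error_sign == "slave_minus_master" else -e0

    def build_network(self) -> RBFApproximator:
        centers = grid_centers(self.rbf_bounds, self.rbf_nodes_per_dim,
                               ndim=self.input_map.q)
        return RBFApproximator(centers=centers, width=self.rbf_width,
                               adapt_gain=self.rbf_adapt_gain, leak=self.rbf_leak)

    def metadata(self) -> dict:
        meta = {
            "master": asdict(self.master), "slave": asdict(self.slave),
            "tmas_master": asdict(self.tmas_master), "tmas_slave": asdict(self.tmas_slave),
            "performance": asdict(self.performance),
            "rbf": {"nodes_per_dim": self.rbf_nodes_per_dim, "bounds": list(self.rbf_bounds),
                    "width": self.rbf_width, "adapt_gain": self.rbf_adapt_gain,
                    "leak": self.rbf_leak, "input_map": self.input_map.name,
                    "potential_range": list(self.input_map.v_range)},
            "controller": self.controller, "gains": asdict(self.gains),
            "phi_dot_mode": self.phi_dot_mode, "det_guard": self.det_guard,
            "gain_floor": self.gain_floor,
            "observer": {k: getattr(self.observer, k) for k in
                         ("L0", "k1_star", "k2_star", "k")},
            "mec": {"tau_c": self.mec.tau_c, "tau_e": self.mec.tau_e},
            "sim": asdict(self.sim),
            "x_master0": list(self.x_master0), "x_slave0": list(self.x_slave0),
            "error_sign": self.error_sign,
            "slave_capacitance": "CS",
        }
        return meta


def default_config() -> dict:
    """The bundled default configuration as a plain nested mapping.

    It reproduces the study conditions: the two bundled neuron parameter
    sets, the magneto-acoustic stimulus constants with modulation
    frequencies 100 Hz (master) and 104 Hz (slave), the funnel
    beta(t) = 0.28 exp(-0.6 t) + 0.02 with H = 0.9, a 21 x 21 RBF grid on
    [-2.5, 2.5] with width 0.25 and zero initial weights, total
    proportional gain 4, adaptation gain 1 and leak 0.001, and the initial
    states x_M(0) = (0.1, 0.2, 0, 0.2), x_S(0) = (0.3, 0.1, 0.2, 0).
    """
    return {
        "master": asdict(MASTER),
        "slave": asdict(SLAVE),
        "slave_capacitance": "CS",
        "tmas": asdict(TMASParameters()),
        "mf_master": 100.0,
        "mf_slave": 104.0,
        "performance": {"beta0": 0.3, "beta_inf": 0.02, "kappa": 0.6, "H": 0.9},
        "rbf": {"nodes_per_dim": 21, "bounds": [-2.5, 2.5], "width": 0.25,
                "adapt_gain": 1.0, "leak": 1e-3,
                "input_map": "potentials_normalized", "potential_range": [0.0, 12.0]},
        "controller": {"type": "ppc", "k1": 2.0, "k2": 2.0,
                       "phi_dot_mode": "zero", "det_guard": 0.05, "gain_floor": 0.0},
        "observer": {"L0": 20.0, "k1_star": 2.0, "k2_star": 1.0, "k": -4.0},
        "mec": {"tau_c": 0.5, "tau_e": 0.05},
        "sim": asdict(SimulationConfig()),
        "initial": {"x_master": [0.1, 0.2, 0.0, 0.2], "x_slave": [0.3, 0.1, 0.2, 0.0]},
        "error_sign": "slave_minus_master",
    }


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def validate_config(raw: Mapping | None = None) -> ResolvedConfig:
    """Merge a partial configuration over the defaults and validate it.

    Every type invariant is checked and all problems are reported together
    in a single :class:`ConfigError`.  An empty or missing mapping yields
    the full default run.
    """
    cfg = _merge(default_config(), raw or {})
    problems: list[str] = []

    def build(what, fn):
        try:
            return fn()
        except (ValueError, KeyError, TypeError) as exc:
            problems.append(f"{what}: {exc}")
            return None

    if cfg.get("slave_capacitance") not in ("CS", "CM"):
        problems.append("slave_capacitance: must be 'CS' or 'CM'")
    master = build("master", lambda: HHParameters(**cfg["master"]))
    slave_params = dict(cfg["slave"])
    # The slave's membrane equation can optionally be divided by the
    # master's capacitance instead of its own (a printed-form reading).
    if cfg.get("slave_capacitance") == "CM" and master is not None:
        slave_params["C"] = cfg["master"]["C"]
    slave = build("slave", lambda: HHParameters(**slave_params))
    tmas_m = build("tmas (master)", lambda: TMASParameters(
        **{**cfg["tmas"], "mf": float(cfg["mf_master"])}))
    tmas_s = build("tmas (slave)", lambda: TMASParameters(
        **{**cfg["tmas"], "mf": float(cfg["mf_slave"])}))
    perf = build("performance", lambda: PerformanceSpec(**cfg["performance"]))

    rbf = cfg["rbf"]
    input_map = build("rbf.input_map", lambda: NNInputMap(
        rbf["input_map"], v_range=tuple(rbf["potential_range"])))
    if not (isinstance(rbf["nodes_per_dim"], int) and rbf["nodes_per_dim"] >= 1):
        problems.append(f"rbf.nodes_per_dim: must be a positive integer, got {rbf['nodes_per_dim']}")
    if not (rbf["width"] > 0):
        problems.append(f"rbf.width: must be positive, got {rbf['width']}")
    if not (rbf["adapt_gain"] > 0):
        problems.append(f"rbf.adapt_gain: must be positive, got {rbf['adapt_gain']}")
    if not (rbf["leak"] > 0):
        problems.append(f"rbf.leak: must be positive, got {rbf['leak']}")

    ctrl = cfg["controller"]
    if ctrl["type"] not in CONTROLLER_TYPES:
        problems.append(f"controller.type: must be one of {CONTROLLER_TYPES}, got {ctrl['type']!r}")
    gains = build("controller gains", lambda: PPCGains(k1=ctrl["k1"], k2=ctrl["k2"]))
    if ctrl["phi_dot_mode"] not in ("fd", "algebraic", "zero"):
        problems.append(
            f"controller.phi_dot_mode: must be 'fd', 'algebraic' or 'zero', got {ctrl['phi_dot_mode']!r}")
    if ctrl["gain_floor"] < 0:
        problems.append(f"controller.gain_floor: must be >= 0, got {ctrl['gain_floor']}")
    observer = build("observer", lambda: ObserverState(**cfg["observer"]))
    mec = build("mec", lambda: MECState(**cfg["mec"]))
    sim = build("sim", lambda: SimulationConfig(**cfg["sim"]))

    init = cfg["initial"]
    xm0 = tuple(float(v) for v in init["x_master"])
    xs0 = tuple(float(v) for v in init["x_slave"])
    for name, x0 in (("x_master", xm0), ("x_slave", xs0)):
        if len(x0) != 4:
            problems.append(f"initial.{name}: need 4 components (V, n, m, h), got {len(x0)}")
        elif not all(0.0 <= g <= 1.0 for g in x0[1:]):
            problems.append(f"initial.{name}: gating values must lie in [0, 1], got {x0[1:]}")
    if cfg["error_sign"] not in ("slave_minus_master", "master_minus_slave"):
        problems.append("error_sign: must be 'slave_minus_master' or 'master_minus_slave'")

    # funnel feasibility of the initial error (only binding for the
    # funnel controller): e(0) must start strictly inside the envelope.
    if perf is not None and ctrl["type"] == "ppc" and len(xm0) == 4 and len(xs0) == 4:
        e0 = xs0[0] - xm0[0]
        if cfg["error_sign"] == "master_minus_slave":
            e0 = -e0
        lo, up = funnel_bounds(0.0, perf, branch_for(e0))
        if not (lo < e0 < up):
            problems.append(
                f"initial error e(0)={e0} must start strictly inside the funnel "
                f"({lo}, {up}): the performance guarantee requires e(0) < beta(0)")

    if problems:
        raise ConfigError(problems)

    return ResolvedConfig(
        master=master, slave=slave, tmas_master=tmas_m, tmas_slave=tmas_s,
        performance=perf, rbf_nodes_per_dim=rbf["nodes_per_dim"],
        rbf_bounds=(float(rbf["bounds"][0]), float(rbf["bounds"][1])),
        rbf_width=float(rbf["width"]), rbf_adapt_gain=float(rbf["adapt_gain"]),
        rbf_leak=float(rbf["leak"]), input_map=input_map,
        controller=ctrl["type"], gains=gains, phi_dot_mode=ctrl["phi_dot_mode"],
        det_guard=float(ctrl["det_guard"]), gain_floor=float(ctrl["gain_floor"]), observer=observer, mec=mec, sim=sim,
        x_master0=xm0, x_slave0=xs0, error_sign=cfg["error_sign"],
    )


# ---------------------------------------------------------------------------
# state packing and the composable reference derivative
# ---------------------------------------------------------------------------

def assemble_state(master: HHState, slave: HHState, weights=None) -> np.ndarray:
    """Pack (master, slave, weights) into one flat vector; invertible."""
    w = np.asarray(weights, dtype=float).ravel() if weights is not None else np.empty(0)
    return np.concatenate([master.as_array(), slave.as_array(), w])


def unpack_state(y: np.ndarray):
    """Inverse of :func:`assemble_state`."""
    y = np.asarray(y, dtype=float)
    return HHState.from_array(y[:4]), HHState.from_array(y[4:8]), y[8:].copy()


def global_derivative(y: np.ndarray, t: float, config: ResolvedConfig,
                      net: RBFApproximator | None = None,
                      phi_dot_fd: float = 0.0) -> np.ndarray:
    """Reference (pure-Python) global derivative for the funnel controller.

    Composes the public module operations; used for cross-checking the
    compiled engine and for direct inspection.  Only the ``none`` and
    ``ppc`` controller types are meaningful here (the baselines carry
    discrete per-step state and live in the engine loop).
    """
    from .hh_model import hh_derivative

    master, slave, w = unpack_state(y)
    sgn = 1.0 if config.error_sign == "slave_minus_master" else -1.0
    ts = t * config.sim.time_scale
    i_m = stimulus_current(ts, config.tmas_master)
    i_s = stimulus_current(ts, config.tmas_slave)
    dm = hh_derivative(master, config.master, i_m, 0.0)

    u = 0.0
    dw = np.zeros_like(w)
    if config.controller == "ppc":
        if net is None:
            net = config.build_network()
        e = sgn * (slave.V - master.V)
        from .prescribed_performance import inverse_transform

        eps = inverse_transform(e, t, config.performance, config.branch)
        ds0 = hh_derivative(slave, config.slave, i_s, 0.0)
        f = sgn * (ds0.V - dm.V)
        Z = config.input_map(master.as_array(), slave.as_array(), e, eps)
        nn = net.predict(Z, weights=w)
        _, u, _ = phi_dot_closure(
            f, e, eps, t, nn, config.performance, config.branch, config.gains,
            phi_dot_fallback=phi_dot_fd, mode=config.phi_dot_mode,
            det_guard=config.det_guard)
        dw = net.weight_derivative(Z, eps, weights=w)

    dsl = hh_derivative(slave, config.slave, i_s, sgn * u)
    return np.concatenate([dm.as_array(), dsl.as_array(), dw])


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Recorded closed-loop run.

    ``data`` holds one row per recorded step (columns
    ``t, V_m, n_m, m_m, h_m, V_s, n_s, m_s, h_s, e, eps, u, w_norm,
    i_ext_m, i_ext_s``).  ``status`` is ``"completed"``,
    ``"funnel_violation"`` or ``"nonfinite"``; a violated run still carries
    the partial trajectory for diagnosis.  ``metadata`` is the fully
    resolved configuration.
    """

    data: pd.DataFrame
    status: str
    t_stop: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.data["t"].to_numpy()
        if len(t) == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def completed(self) -> bool:
        return self.status == "completed"

    def __getattr__(self, name):
        if name.startswith("_") or name in ("data", "status", "t_stop", "metadata"):
            raise AttributeError(name)
        if name == "t":
            return self.data["t"].to_numpy()
        if name in self.data.columns:
            return self.data[name].to_numpy()
        raise AttributeError(name)

    def __len__(self) -> int:
        return len(self.data)

    def to_dataframe(self) -> pd.DataFrame:
        return self.data.copy()

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the records as CSV plus a JSON sidecar with metadata."""
        self.data.to_csv(path, index=False)
        if sidecar:
            side = {"status": self.status, "t_stop": self.t_stop, "config": self.metadata}
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=2, default=float)

    def decimate(self, factor: int) -> "Trajectory":
        """Keep every ``factor``-th record (robustness checks)."""
        return Trajectory(self.data.iloc[::factor].reset_index(drop=True),
                          self.status, self.t_stop, self.metadata)


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

def _initial_flat(config: ResolvedConfig) -> np.ndarray:
    xm = np.array(config.x_master0)
    xs = np.array(config.x_slave0)
    if config.controller == "ppc":
        l = config.rbf_nodes_per_dim ** config.input_map.q
        extra = np.zeros(l)
    elif config.controller == "observer":
        extra = np.array([config.observer.z1_hat, config.observer.eta_hat])
    elif config.controller == "mec":
        extra = np.array([config.mec.eta])
    else:
        extra = np.empty(0)
    return np.concatenate([xm, xs, extra])


def run(config: ResolvedConfig | Mapping | None = None, *,
        engine: str = "auto", raise_on_violation: bool = False) -> Trajectory:
    """Integrate the closed loop and return its :class:`Trajectory`.

    Parameters
    ----------
    config : mapping or ResolvedConfig, optional
        Partial configuration merged over the defaults.
    engine : {"auto", "numba", "python"}
        ``python`` forces the readable reference loop (slow; intended for
        short cross-check windows).
    raise_on_violation : bool
        When True, a funnel violation raises
        :class:`~hhsync.prescribed_performance.FunnelViolationError`
        carrying the partial trajectory in its ``trajectory`` attribute;
        when False the partial trajectory is returned with
        ``status == "funnel_violation"``.

    Identical resolved configurations produce identical trajectories on a
    given platform: the integration is fixed-step and fully deterministic
    (the recorded seed is never consumed).
    """
    if not isinstance(config, ResolvedConfig):
        config = validate_config(config)

    y0 = _initial_flat(config)
    sim = config.sim
    n_steps = int(round(sim.duration / sim.dt))

    if config.controller == "ppc":
        centers = grid_centers(config.rbf_bounds, config.rbf_nodes_per_dim,
                               ndim=config.input_map.q)
    else:
        centers = np.zeros((0, 1))

    pm = np.array([config.master.C, config.master.g_K, config.master.g_Na,
                   config.master.g_L, config.master.V_K, config.master.V_Na,
                   config.master.V_L])
    ps = np.array([config.slave.C, config.slave.g_K, config.slave.g_Na,
                   config.slave.g_L, config.slave.V_K, config.slave.V_Na,
                   config.slave.V_L])
    from .tmas_stimulus import current_amplitude

    stim_m = np.array([current_amplitude(config.tmas_master) * config.tmas_master.amplitude_scale,
                       config.tmas_master.mf, config.tmas_master.f])
    stim_s = np.array([current_amplitude(config.tmas_slave) * config.tmas_slave.amplitude_scale,
                       config.tmas_slave.mf, config.tmas_slave.f])
    perf = np.array([config.performance.beta0, config.performance.beta_inf,
                     config.performance.kappa, config.performance.H])
    branch_sign = 1.0 if config.branch is FunnelBranch.NONNEGATIVE else -1.0
    err_sign = 1.0 if config.error_sign == "slave_minus_master" else -1.0
    obs_gains = np.array([config.observer.L0, config.observer.k1_star,
                          config.observer.k2_star, config.observer.k])
    mec_consts = np.array([config.mec.tau_c, config.mec.tau_e])

    use_python = engine == "python" or (engine == "auto" and not _engine.HAVE_NUMBA)
    if engine not in ("auto", "numba", "python"):
        raise ValueError(f"unknown engine {engine!r}")

    args = (y0, n_steps, sim.dt, sim.record_every, pm, ps, stim_m, stim_s,
            sim.time_scale, perf, branch_sign, err_sign,
            config.gains.k1 + config.gains.k2, centers,
            config.rbf_width ** 2, config.rbf_adapt_gain, config.rbf_leak,
            _CTRL_CODES[config.controller], _ZMAP_CODES[config.input_map.name],
            np.array(config.input_map.normalization()),
            {"fd": 0, "algebraic": 1, "zero": 2}[config.phi_dot_mode],
            config.det_guard, config.gain_floor,
            obs_gains, mec_consts, sim.solver == "euler")
    if use_python:
        rec, n_rec, status, t_stop = _engine.integrate.py_func(*args) \
            if hasattr(_engine.integrate, "py_func") else _engine.integrate(*args)
    else:
        rec, n_rec, status, t_stop = _engine.integrate(*args)

    frame = pd.DataFrame(rec[:n_rec], columns=list(_engine.RECORD_COLUMNS))
    status_name = {_engine.STATUS_OK: "completed",
                   _engine.STATUS_FUNNEL: "funnel_violation",
                   _engine.STATUS_NONFINITE: "nonfinite"}[status]
    traj = Trajectory(frame, status_name, float(t_stop), config.metadata())

    if status_name == "nonfinite":
        raise FloatingPointError(
            f"state became non-finite at t={t_stop:.6g} (step {int(round(t_stop / sim.dt))})")
    if status_name == "funnel_violation" and raise_on_violation:
        lo, up = funnel_bounds(t_stop, config.performance, config.branch)
        err = FunnelViolationError(t_stop, float("nan"), lo, up)
        err.trajectory = traj
        raise err
    return traj
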