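"""Fixed-step integration engine.

The closed loop couples the two neurons, the funnel controller and the
adaptive weights into one ODE whose dimension is 8 + l (l RBF nodes) for
the neural controller, 8 + 2 for the observer baseline, 8 + 1 for the
modelling-error baseline and 8 in open loop.  The engine integrates it
with classical four-stage Runge-Kutta (or explicit Euler for
cross-checks) at a fixed step, which keeps runs bit-reproducible and the
funnel check step-exact.

The hot loop is compiled with numba when available; the pure-Python twin
in :mod:`hhsync.closed_loop_sim` (``engine="python"``) produces identical
trajectories and serves as the readable reference.

Controller codes: 0 none, 1 funnel (PPC), 2 observer, 3 MEC.
Input-map codes: 0 (e, eps), 1 (V_M, V_S), 2 full joint state,
3 normalized potentials.
Status codes: 0 completed, 1 funnel violation, 2 non-finite state.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly by every jitted call
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


CTRL_NONE, CTRL_PPC, CTRL_OBSERVER, CTRL_MEC = 0, 1, 2, 3
ZMAP_ERROR, ZMAP_POTENTIALS, ZMAP_FULL, ZMAP_POTENTIALS_NORM = 0, 1, 2, 3
STATUS_OK, STATUS_FUNNEL, STATUS_NONFINITE = 0, 1, 2

#: record columns, in order
RECORD_COLUMNS = (
    "t", "V_m", "n_m", "m_m", "h_m", "V_s", "n_s", "m_s", "h_s",
    "e", "eps", "u", "w_norm", "i_ext_m", "i_ext_s",
)


@njit(cache=True)
def _gating_rates(V):
    x = 100.0 - V
    if abs(x) < 1e-8:
        a_n = 0.1 * 100.0
    else:
        a_n = 0.1 * x / (math.expm1(x / 100.0))
    b_n = 0.15 * math.exp(-V / 100.0)
    x = 15.0 - V
    if abs(x) < 1e-8:
        a_m = 0.1 * 5.0
    else:
        a_m = 0.1 * x / (math.expm1(x / 5.0))
    b_m = 4.0 * math.exp(-V / 10.0)
    a_h = 0.08 * math.exp(-V / 10.0)
    b_h = 1.0 / (math.exp((30.0 - V) / 10.0) + 1.0)
    return a_n, b_n, a_m, b_m, a_h, b_h


@njit(cache=True)
def _membrane_drift(V, n, m, h, p, i_ext):
    """(i_ext - ionic currents)/C for parameter vector p = (C,gK,gNa,gL,VK,VNa,VL)."""
    i_K = p[1] * n ** 4 * (V - p[4])
    i_Na = p[2] * m ** 3 * h * (V - p[5])
    i_L = p[3] * (V - p[6])
    return (i_ext - i_K - i_Na - i_L) / p[0]


@njit(cache=True)
def _stimulus(t, amp, mf, f):
    return amp * math.sin(2.0 * math.pi * mf * t) * (math.sin(2.0 * math.pi * f * t) + 1.0)


@njit(cache=True)
def _rhs(t, y, out, pm, ps, stim_m, stim_s, time_scale,
         perf, branch_sign, err_sign, k12, centers, width2, adapt_gain, leak,
         ctype, zmode, znorm, phi_dot_fd, closure_mode, det_guard, gain_floor,
         obs_gains, mec_consts, mec_eta_bar):
    """Global derivative.  Returns (ok, e, eps, u, phi, i_m, i_s).

    ``ok`` is False when the funnel transformation is undefined at the
    evaluation state (wall contact) under the funnel controller.
    perf = (beta0, beta_inf, kappa, H); branch_sign = +1 for the e(0) >= 0
    branch, -1 for the mirror.  width2 is the squared basis width.
    """
    ts = t * time_scale
    i_m = _stimulus(ts, stim_m[0], stim_m[1], stim_m[2])
    i_s = _stimulus(ts, stim_s[0], stim_s[1], stim_s[2])

    Vm, nm, mm, hm = y[0], y[1], y[2], y[3]
    Vs, ns, ms, hs = y[4], y[5], y[6], y[7]

    fm = _membrane_drift(Vm, nm, mm, hm, pm, i_m)
    fs = _membrane_drift(Vs, ns, ms, hs, ps, i_s)
    e = err_sign * (Vs - Vm)
    f = err_sign * (fs - fm)

    # funnel quantities
    beta0, beta_inf, kappa, H = perf[0], perf[1], perf[2], perf[3]
    ex = math.exp(-kappa * t)
    b = (beta0 - beta_inf) * ex + beta_inf
    bd = -kappa * (beta0 - beta_inf) * ex

    eps = np.nan
    u = 0.0
    phi = np.nan
    if ctype == CTRL_PPC:
        ehat = e / b
        if branch_sign > 0:
            num = H + ehat
            den = 1.0 - ehat
            d1 = H * b + e
            d2 = e - b
            w1 = H * bd
            w2 = bd
        else:
            num = 1.0 + ehat
            den = H - ehat
            d1 = b + e
            d2 = e - H * b
            w1 = bd
            w2 = H * bd
        if num <= 0.0 or den <= 0.0:
            return False, e, eps, u, phi, i_m, i_s
        eps = math.log(num / den)
        phi = 1.0 / d1 - 1.0 / d2
        dp_de = -1.0 / d1 ** 2 + 1.0 / d2 ** 2
        dp_dt = -w1 / d1 ** 2 - w2 / d2 ** 2

        # network input and activations
        l = centers.shape[0]
        q = centers.shape[1]
        nn = 0.0
        sbuf = out[8:8 + l]  # reuse the weight slot of out as scratch
        for i in range(l):
            d2c = 0.0
            for j in range(q):
                if zmode == ZMAP_ERROR:
                    zj = e if j == 0 else eps
                elif zmode == ZMAP_POTENTIALS:
                    zj = Vm if j == 0 else Vs
                elif zmode == ZMAP_POTENTIALS_NORM:
                    zj = ((Vm if j == 0 else Vs) - znorm[0]) * znorm[1]
                else:
                    zj = y[j]
                dz = zj - centers[i, j]
                d2c += dz * dz
            s = math.exp(-d2c / width2)
            sbuf[i] = s
            nn += y[8 + i] * s

        gamma_over_phi = (bd / b) * e
        u0 = -k12 * eps - nn - gamma_over_phi
        c = eps / (2.0 * phi * phi)
        if closure_mode == 1:  # algebraic with guarded fallback
            det = 1.0 - dp_de * c
            if abs(det) < det_guard:
                phi_dot = phi_dot_fd
            else:
                phi_dot = (dp_de * (f + u0) + dp_dt) / det
        elif closure_mode == 2:  # drop the phi_dot gain correction
            phi_dot = 0.0
        else:
            phi_dot = phi_dot_fd
        # gain floor: k(t) = k12 - phi_dot/(2 phi^2) is kept >= gain_floor
        # (a numerical guard near the funnel walls, where the discretized
        # phi_dot correction can otherwise flip the gain sign)
        if gain_floor > 0.0:
            k_t = k12 - c * phi_dot / eps if eps != 0.0 else k12
            # c*phi_dot = eps*phi_dot/(2 phi^2); k_t*eps reconstructs u's gain term
            if k_t < gain_floor:
                phi_dot = (k12 - gain_floor) * (2.0 * phi * phi)
        u = u0 + c * phi_dot

        # weight law (after using sbuf for activations)
        for i in range(l):
            s = sbuf[i]
            out[8 + i] = adapt_gain * (s * eps - leak * y[8 + i])
    elif ctype == CTRL_OBSERVER:
        # y[8] = z1_hat, y[9] = eta_hat; obs_gains = (L0, k1*, k2*, k)
        z1_hat, eta_hat = y[8], y[9]
        u = eta_hat + obs_gains[3] * z1_hat
        innov = e - z1_hat
        out[8] = eta_hat - u + obs_gains[0] * obs_gains[1] * innov
        out[9] = obs_gains[0] ** 2 * obs_gains[2] * innov
    elif ctype == CTRL_MEC:
        # y[8] = eta; mec_consts = (tau_c, tau_e); mec_eta_bar frozen per step
        u = -e / mec_consts[0] + y[8]
        out[8] = -(y[8] - mec_eta_bar) / mec_consts[1]

    a_n, b_n, a_m, b_m, a_h, b_h = _gating_rates(Vm)
    out[0] = fm
    out[1] = a_n * (1.0 - nm) - b_n * nm
    out[2] = a_m * (1.0 - mm) - b_m * mm
    out[3] = a_h * (1.0 - hm) - b_h * hm
    a_n, b_n, a_m, b_m, a_h, b_h = _gating_rates(Vs)
    out[4] = fs + err_sign * u
    out[5] = a_n * (1.0 - ns) - b_n * ns
    out[6] = a_m * (1.0 - ms) - b_m * ms
    out[7] = a_h * (1.0 - hs) - b_h * hs
    return True, e, eps, u, phi, i_m, i_s


@njit(cache=True)
def integrate(y0, n_steps, dt, record_every,
              pm, ps, stim_m, stim_s, time_scale,
              perf, branch_sign, err_sign, k12, centers, width2, adapt_gain, leak,
              ctype, zmode, znorm, closure_mode, det_guard, gain_floor,
              obs_gains, mec_consts, use_euler):
    """Fixed-step integration of the closed loop.

    Returns ``(records, n_rec, status, t_stop)`` where ``records`` holds one
    row per recorded step with columns :data:`RECORD_COLUMNS` (the final
    state is always recorded), ``status`` is one of the STATUS codes and
    ``t_stop`` the time of the last accepted state.
    """
    dim = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    ytmp = np.empty(dim)

    n_rec_max = n_steps // record_every + 2
    rec = np.empty((n_rec_max, 15))
    n_rec = 0

    phi_dot_fd = 0.0
    phi_prev = np.nan
    # MEC backward-difference memory
    e_prev = err_sign * (y[4] - y[0])
    u_prev = 0.0
    mec_eta_bar = 0.0

    status = STATUS_OK
    t_stop = 0.0
    l = centers.shape[0]

    for i in range(n_steps):
        t = i * dt
        if ctype == CTRL_MEC and i > 0:
            mec_eta_bar = u_prev - (err_sign * (y[4] - y[0]) - e_prev) / dt
            e_prev = err_sign * (y[4] - y[0])

        ok, e, eps, u, phi, im, isx = _rhs(
            t, y, k1, pm, ps, stim_m, stim_s, time_scale, perf, branch_sign, err_sign,
            k12, centers, width2, adapt_gain, leak, ctype, zmode, znorm,
            phi_dot_fd, closure_mode, det_guard, gain_floor, obs_gains, mec_consts, mec_eta_bar)
        if ctype == CTRL_PPC and not ok:
            status = STATUS_FUNNEL
            t_stop = t
            break
        if not (math.isfinite(y[0]) and math.isfinite(y[4])):
            status = STATUS_NONFINITE
            t_stop = t
            break
        u_prev = u

        if i % record_every == 0:
            wn = 0.0
            if ctype == CTRL_PPC:
                for j in range(l):
                    wn += y[8 + j] ** 2
            rec[n_rec, 0] = t
            for j in range(8):
                rec[n_rec, 1 + j] = y[j]
            rec[n_rec, 9] = e
            rec[n_rec, 10] = eps
            rec[n_rec, 11] = u
            rec[n_rec, 12] = math.sqrt(wn)
            rec[n_rec, 13] = im
            rec[n_rec, 14] = isx
            n_rec += 1

        if use_euler:
            for j in range(dim):
                y[j] = y[j] + dt * k1[j]
        else:
            h2 = dt * 0.5
            for j in range(dim):
                ytmp[j] = y[j] + h2 * k1[j]
            ok2, _, _, _, _, _, _ = _rhs(
                t + h2, ytmp, k2, pm, ps, stim_m, stim_s, time_scale, perf,
                branch_sign, err_sign, k12, centers, width2, adapt_gain, leak, ctype,
                zmode, znorm, phi_dot_fd, closure_mode, det_guard, gain_floor,
                obs_gains, mec_consts, mec_eta_bar)
            for j in range(dim):
                ytmp[j] = y[j] + h2 * k2[j]
            ok3, _, _, _, _, _, _ = _rhs(
                t + h2, ytmp, k3, pm, ps, stim_m, stim_s, time_scale, perf,
                branch_sign, err_sign, k12, centers, width2, adapt_gain, leak, ctype,
                zmode, znorm, phi_dot_fd, closure_mode, det_guard, gain_floor,
                obs_gains, mec_consts, mec_eta_bar)
            for j in range(dim):
                ytmp[j] = y[j] + dt * k3[j]
            ok4, _, _, _, _, _, _ = _rhs(
                t + dt, ytmp, k4, pm, ps, stim_m, stim_s, time_scale, perf,
                branch_sign, err_sign, k12, centers, width2, adapt_gain, leak, ctype,
                zmode, znorm, phi_dot_fd, closure_mode, det_guard, gain_floor,
                obs_gains, mec_consts, mec_eta_bar)
            if ctype == CTRL_PPC and not (ok2 and ok3 and ok4):
                status = STATUS_FUNNEL
                t_stop = t
                break
            d6 = dt / 6.0
            for j in range(dim):
                y[j] = y[j] + d6 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        if ctype == CTRL_PPC:
            if math.isfinite(phi_prev):
                phi_dot_fd = (phi - phi_prev) / dt
            phi_prev = phi
        t_stop = t + dt

    if status == STATUS_OK:
        # final state row
        t = n_steps * dt
        if ctype == CTRL_MEC:
            mec_eta_bar = u_prev - (err_sign * (y[4] - y[0]) - e_prev) / dt
        ok, e, eps, u, phi, im, isx = _rhs(
            t, y, k1, pm, ps, stim_m, stim_s, time_scale, perf, branch_sign, err_sign,
            k12, centers, width2, adapt_gain, leak, ctype, zmode, znorm,
            phi_dot_fd, closure_mode, det_guard, gain_floor, obs_gains, mec_consts, mec_eta_bar)
        if ctype == CTRL_PPC and not ok:
            status = STATUS_FUNNEL
            t_stop = t
        else:
            wn = 0.0
            if ctype == CTRL_PPC:
                for j in range(l):
                    wn += y[8 + j] ** 2
            rec[n_rec, 0] = t
            for j in range(8):
                rec[n_rec, 1 + j] = y[j]
            rec[n_rec, 9] = e
            rec[n_rec, 10] = eps
            rec[n_rec, 11] = u
            rec[n_rec, 12] = math.sqrt(wn)
            rec[n_rec, 13] = im
            rec[n_rec, 14] = isx
            n_rec += 1
            t_stop = t

    return rec, n_rec, status, t_stop
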