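"""Compiled fixed-step RK4 / method-of-steps integrator.

All model right-hand sides live here in scalar numba code so that the
optimal-control objective (thousands of re-simulations under perturbed
effort paths) stays cheap.  The public, documented entry points in
:mod:`forageweb.ecology` wrap these kernels; pure-python mirrors of the
individual rate functions are exposed there for testing and inspection.

State ordering: [Xa, Na, Xs, Ns, Xh, Nh, Nbp].

Packed parameter arrays (see ``FullParameterSet.pack``)::

    forc[i] = [r_bar, A, p, s_deg]                 (i = 0 anchovy, 1 sardine)
    fbio[i] = [w_r, w_inf, kappa, M, eta]
    hal     = [a, b, M_j, tau, kappa, w_r, w_inf0, Cmax, alpha_a, alpha_s,
               Y, gamma_w, M, f_base, kappa_in_numbers_flag]
    pel     = [Mbar, tau_bp, Phi, K_bp, z, tr1, tr2, tr3, ts1, ts2, ts3,
               Gamma_a, Gamma_s, Gamma_other, Xa_o, Xs_o,
               use_lagged_phi_r_flag, phi_floor]
    econ[i] = [p_tilde, q, c1, c2]                 (i = 0 a, 1 s, 2 h)
    polc    = [hcr_cutoff, hcr_cap, hcr_share, hcr_f0, hcr_f1,
               hs_lower, hs_upper, hs_fmax_mult, M_s, Xs_o]

Per-species policy codes::

    0 closed   1 open access   2 open loop (effort grid)   3 sardine HCR
    4 sardine hockey stick     5 constant F                6 myopic effort
"""

import numpy as np
from numba import njit

# policy codes
CLOSED, OPEN_ACCESS, OPEN_LOOP, HCR, HOCKEY, CONST_F, MYOPIC = range(7)


@njit(cache=True)
def _rrate(t, rbar, A, p, s_deg):
    """Sinusoidal per-capita recruitment rate with lognormal bias correction."""
    if A == 0.0:
        return rbar
    return rbar * np.exp(A * np.sin(2.0 * np.pi * t / p + s_deg * np.pi / 180.0
                                    + np.pi) - A * A / 4.0)


@njit(cache=True)
def _prey_response(d, t1, t2, t3):
    """Saturating prey-response scalar phi(d) in [0, 1]; zero for d <= t1."""
    if d <= t1:
        return 0.0
    if t2 <= 0.0:
        return 1.0  # decoupled limit
    num = t3 * (1.0 - t1 - t2) * (d - t1)
    den = (1.0 - t1) * t2 * (1.0 - t3) + num
    phi = num / den
    if phi < 0.0:
        phi = 0.0
    elif phi > 1.0:
        phi = 1.0
    return phi


@njit(cache=True)
def _lagged(Y, y0, ycur, j, ts, lag, dt, kmax):
    """State component j at time ts - lag, by linear interpolation.

    History is constant at the initial state for negative times; a lag
    shorter than half a step means "current" and returns the stage value.
    """
    if lag < 0.5 * dt:
        return ycur[j]
    tl = ts - lag
    if tl <= 0.0:
        return y0[j]
    u = tl / dt
    i0 = int(u)
    if i0 >= kmax:
        i0 = kmax - 1
    frac = u - i0
    return Y[i0, j] * (1.0 - frac) + Y[i0 + 1, j] * frac


@njit(cache=True)
def _rhs(t, y, F, Xh_lag, Xa_lag, Xs_lag, Nbp_lag, forc, fbio, hal, pel):
    """Time derivative of the 7-state system under fishing mortalities F."""
    dy = np.zeros(7)
    Xa = max(y[0], 0.0)
    Na = max(y[1], 0.0)
    Xs = max(y[2], 0.0)
    Ns = max(y[3], 0.0)
    Xh = max(y[4], 0.0)
    Nh = max(y[5], 0.0)
    Nbp = max(y[6], 0.0)

    # -- Type-II multi-prey predation by halibut -----------------------------
    Cmax = hal[7]
    aa = hal[8]
    as_ = hal[9]
    Yc = hal[10]
    den = Cmax + aa * Xa + as_ * Xs + Yc
    if den > 0.0:
        Pa = Cmax * aa * Xh / den
        Ps = Cmax * as_ * Xh / den
        f_rel = (aa * Xa + as_ * Xs + Yc) / den
    else:
        Pa = 0.0
        Ps = 0.0
        f_rel = 0.0

    # -- forage species (delay-difference biomass, density-independent N) ----
    for i in range(2):
        X = Xa if i == 0 else Xs
        N = Na if i == 0 else Ns
        P = Pa if i == 0 else Ps
        r = _rrate(t, forc[i, 0], forc[i, 1], forc[i, 2], forc[i, 3])
        w_r = fbio[i, 0]
        w_inf = fbio[i, 1]
        kap = fbio[i, 2]
        M = fbio[i, 3]
        loss = M + P + F[i]
        dy[2 * i] = r * w_r * N + kap * (w_inf * N - X) - loss * X
        dy[2 * i + 1] = (r - loss) * N

    # -- halibut (Beverton-Holt delayed recruitment, prey-dependent w_inf) ---
    a_bh = hal[0]
    b_bh = hal[1]
    Rh = a_bh * Xh_lag / (1.0 + b_bh * Xh_lag) * np.exp(-hal[2] * hal[3])
    w_inf_h = hal[6]
    if hal[11] != 0.0 and hal[13] > 0.0:
        w_inf_h = hal[6] * (f_rel / hal[13]) ** hal[11]
    kap_h = hal[4]
    loss_h = hal[12] + F[2]
    dy[4] = Rh * hal[5] + kap_h * (w_inf_h * Nh - Xh) - loss_h * Xh
    extra = kap_h if hal[14] != 0.0 else 0.0
    dy[5] = Rh - (loss_h + extra) * Nh

    # -- Brown Pelican -------------------------------------------------------
    Ga = pel[11]
    Gs = pel[12]
    Go = pel[13]
    d_now = Ga * Xa / pel[14] + Gs * Xs / pel[15] + Go
    phi_v = _prey_response(d_now, pel[8], pel[9], pel[10])
    if phi_v < pel[17]:
        phi_v = pel[17]
    Mbp = pel[0] - np.log(phi_v)

    if pel[16] != 0.0:
        d_rep = Ga * max(Xa_lag, 0.0) / pel[14] + Gs * max(Xs_lag, 0.0) / pel[15] + Go
    else:
        d_rep = d_now
    phi_r = _prey_response(d_rep, pel[5], pel[6], pel[7])
    Nl = max(Nbp_lag, 0.0)
    dens = 1.0 + (pel[2] - 1.0) * (1.0 - (Nl / pel[3]) ** pel[4])
    if dens < 0.0:
        dens = 0.0
    Rbp = 0.5 * np.exp(-pel[0] * pel[1]) * Nl * phi_r * dens
    dy[6] = Rbp - Mbp * Nbp
    return dy


@njit(cache=True)
def _policy_effort(code, i, t, X, econ, polc, forc, eol_k, constF_i):
    """Effort for species i at time t given its policy code. Returns E."""
    q = econ[i, 1]
    if code == CLOSED:
        return 0.0
    if code == OPEN_ACCESS:
        E = (econ[i, 0] * q * X - econ[i, 2]) / econ[i, 3]
        return E if E > 0.0 else 0.0
    if code == MYOPIC:
        E = (econ[i, 0] * q * X - econ[i, 2]) / (2.0 * econ[i, 3])
        return E if E > 0.0 else 0.0
    if code == OPEN_LOOP:
        return eol_k
    if code == CONST_F:
        return constF_i / q if q > 0.0 else 0.0
    if code == HCR:
        # stylized current sardine harvest guideline (catch-based)
        rs = _rrate(t, forc[1, 0], forc[1, 1], forc[1, 2], forc[1, 3])
        fexp = polc[3] + polc[4] * rs / forc[1, 0]
        if X <= polc[0]:
            C = 0.0
        else:
            C = polc[2] * (X - polc[0]) * fexp
            if C > polc[1]:
                C = polc[1]
        F = C / X if X > 0.0 else 0.0
        return F / q if q > 0.0 else 0.0
    if code == HOCKEY:
        Ms = polc[8]
        Xso = polc[9]
        xr = X / Xso
        if xr <= polc[5]:
            F = 0.0
        elif xr >= polc[6]:
            F = polc[7] * Ms
        else:
            F = polc[7] * Ms * (xr - polc[5]) / (polc[6] - polc[5])
        return F / q if q > 0.0 else 0.0
    return 0.0


@njit(cache=True)
def simulate_core(y0, nsteps, dt, forc, fbio, hal, pel, econ, polc,
                  codes, eol, constF):
    """Integrate the system over nsteps of size dt.

    Closed-loop efforts are evaluated once per step from the step-start
    state and held constant across the RK4 stages (piecewise-constant
    policy at resolution dt).  Returns (Y, E, F) on the nsteps+1 grid.
    """
    Y = np.empty((nsteps + 1, 7))
    E = np.zeros((nsteps + 1, 3))
    Fm = np.zeros((nsteps + 1, 3))
    for j in range(7):
        Y[0, j] = max(y0[j], 0.0)

    tau_h = hal[3]
    lag_a = fbio[0, 4]
    lag_s = fbio[1, 4]
    tau_bp = pel[1]

    Fol = np.zeros(3)   # per-step fishing rate for the open-loop codes
    for k in range(nsteps):
        t = k * dt
        y = Y[k]
        for i in range(3):
            Ei = _policy_effort(codes[i], i, t, y[2 * i], econ, polc, forc,
                                eol[i, k], constF[i])
            if Ei < 0.0:
                Ei = 0.0
            E[k, i] = Ei
            Fm[k, i] = econ[i, 1] * Ei
            # open-loop/constant efforts are held over the step; feedback
            # rules are re-evaluated at each RK4 stage state below
            Fol[i] = Fm[k, i]

        # RK4 with lagged states interpolated from the stored history
        k1 = _stage(t, y, Fol, codes, constF, Y, y0, k, dt, tau_h,
                    lag_a, lag_s, tau_bp, forc, fbio, hal, pel, econ, polc)
        y2 = y + 0.5 * dt * k1
        k2 = _stage(t + 0.5 * dt, y2, Fol, codes, constF, Y, y0, k, dt, tau_h,
                    lag_a, lag_s, tau_bp, forc, fbio, hal, pel, econ, polc)
        y3 = y + 0.5 * dt * k2
        k3 = _stage(t + 0.5 * dt, y3, Fol, codes, constF, Y, y0, k, dt, tau_h,
                    lag_a, lag_s, tau_bp, forc, fbio, hal, pel, econ, polc)
        y4 = y + dt * k3
        k4 = _stage(t + dt, y4, Fol, codes, constF, Y, y0, k, dt, tau_h,
                    lag_a, lag_s, tau_bp, forc, fbio, hal, pel, econ, polc)
        for j in range(7):
            v = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            Y[k + 1, j] = v if v > 0.0 else 0.0

    # bookkeeping at the terminal node
    tT = nsteps * dt
    for i in range(3):
        Ei = _policy_effort(codes[i], i, tT, Y[nsteps, 2 * i], econ, polc,
                            forc, eol[i, nsteps - 1] if nsteps > 0 else 0.0,
                            constF[i])
        if Ei < 0.0:
            Ei = 0.0
        E[nsteps, i] = Ei
        Fm[nsteps, i] = econ[i, 1] * Ei
    return Y, E, Fm


@njit(cache=True)
def _stage(ts, ycur, Fol, codes, constF, Y, y0, k, dt, tau_h, lag_a, lag_s,
           tau_bp, forc, fbio, hal, pel, econ, polc):
    F = np.empty(3)
    for i in range(3):
        c = codes[i]
        if c == CLOSED or c == OPEN_LOOP or c == CONST_F:
            F[i] = Fol[i]
        else:
            Ei = _policy_effort(c, i, ts, max(ycur[2 * i], 0.0), econ, polc,
                                forc, 0.0, constF[i])
            F[i] = econ[i, 1] * Ei if Ei > 0.0 else 0.0
    Xh_lag = _lagged(Y, y0, ycur, 4, ts, tau_h, dt, k)
    Xa_lag = _lagged(Y, y0, ycur, 0, ts, lag_a, dt, k)
    Xs_lag = _lagged(Y, y0, ycur, 2, ts, lag_s, dt, k)
    Nbp_lag = _lagged(Y, y0, ycur, 6, ts, tau_bp, dt, k)
    return _rhs(ts, ycur, F, Xh_lag, Xa_lag, Xs_lag, Nbp_lag,
                forc, fbio, hal, pel)
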