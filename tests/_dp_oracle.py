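"""Independent value-iteration oracle for the single-stock reduction.

With constant recruitment, no delays (tau = 0), no predation coupling
(alpha = 0, gamma_w = 0) and recruit mass equal to asymptotic mass, the
halibut sub-model collapses to one biomass state:

    dX/dt = w a X / (1 + b X) - (M + q E) X

The finite-horizon discounted-profit problem (with the same
sustainable-flow salvage convention the shooting solver uses) is solved
here by backward induction on a discretized biomass grid with an Euler
transition — a method entirely independent of the shooting transcription.
"""

import numpy as np


def reduced_growth(X, hp):
    """1-D biomass growth rate w a X/(1+bX) - M X (no fishing)."""
    w = hp.w_inf0
    return w * hp.a * X / (1.0 + hp.b * X) - hp.M * X


def _salvage(X, hp, ec, delta):
    """Sustainable-flow continuation value (same convention as the solver):
    profit at min(sustainable F, myopic F) capitalized at delta."""
    w = hp.w_inf0
    F_sus = np.maximum(0.0, w * hp.a / (1.0 + hp.b * X) - hp.M)
    E_myo = np.maximum(0.0, (ec.p_tilde * ec.q * X - ec.c1) / (2.0 * ec.c2))
    E = np.minimum(F_sus / ec.q, E_myo)
    psi = (ec.p_tilde * ec.q * X - ec.c1 - ec.c2 * E) * E
    return np.maximum(psi, 0.0) / delta


def value_iteration(hp, ec, delta, X0, T, Emax, dt=0.1, nX=1401, nE=201,
                    Xmax=None):
    """Optimal discounted value J from X0 over [0, T] by backward induction.

    Returns (J, X_grid, V0).
    """
    if Xmax is None:
        # well above the unfished equilibrium
        Xeq = (hp.w_inf0 * hp.a / hp.M - 1.0) / hp.b
        Xmax = 1.5 * Xeq
    X = np.linspace(0.0, Xmax, nX)
    E = np.linspace(0.0, Emax, nE)
    w = hp.w_inf0

    growth = w * hp.a * X / (1.0 + hp.b * X)            # (nX,)
    psi = (ec.p_tilde * ec.q * X[:, None] - ec.c1
           - ec.c2 * E[None, :]) * E[None, :]           # (nX, nE)
    Xnext = X[:, None] + dt * (growth[:, None]
                               - (hp.M + ec.q * E[None, :]) * X[:, None])
    Xnext = np.clip(Xnext, 0.0, Xmax)
    beta = np.exp(-delta * dt)

    V = _salvage(X, hp, ec, delta)
    nsteps = int(round(T / dt))
    flat = Xnext.ravel()
    for _ in range(nsteps):
        Vn = np.interp(flat, X, V).reshape(nX, nE)
        V = np.max(dt * psi + beta * Vn, axis=1)
    return float(np.interp(X0, X, V)), X, V
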