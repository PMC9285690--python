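"""Population dynamics of the four-species food web and the simulator.

The model couples:

* two forage species (anchovy, sardine) with delay-difference biomass
  growth, density-independent numbers dynamics, and deterministic
  sinusoidal recruitment forcing;
* California halibut with Beverton-Holt recruitment on lagged halibut
  biomass, a multi-prey Type-II functional response on the forage stocks,
  and a consumption-dependent asymptotic mass;
* a Brown Pelican index whose reproduction and adult survival respond to a
  diet-weighted forage depletion index through saturating prey-response
  scalars.

The individual rate functions here are the documented, pure-python forms of
the model; :func:`simulate` runs the compiled fixed-step RK4
(method-of-steps) integrator in :mod:`forageweb._kernel`, which implements
the same equations.  Simulations are deterministic and reproducible
bit-for-bit for a fixed step size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import _kernel as K
from .params import (ForageParams, HalibutParams, PelicanParams,
                     FullParameterSet, ValidationError, SPECIES)
from .policies import PolicyPath

__all__ = [
    "recruitment_rate", "predation_mortality", "halibut_recruitment",
    "halibut_asymptotic_mass", "forage_derivatives", "halibut_derivatives",
    "pelican_depletion", "prey_response", "pelican_reproduction",
    "pelican_mortality_rate", "pelican_derivative", "Trajectory", "simulate",
    "STATE_COLUMNS",
]

STATE_COLUMNS = ("Xa", "Na", "Xs", "Ns", "Xh", "Nh", "Nbp")


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

def recruitment_rate(t, fp: ForageParams):
    """Per-capita recruitment rate r(t) (1/yr).

    r(t) = r_bar exp(A sin(2 pi t/p + s pi/180 + pi) - A^2/4); the last
    term is a bias correction keeping the period mean close to r_bar
    (exact to O(A^4), since the sine's variance is A^2/2).
    """
    if fp.A > 0 and fp.p <= 0:
        raise ValidationError("recruitment period p must be > 0 when A > 0")
    t = np.asarray(t, float)
    if fp.A == 0:
        out = np.full_like(t, fp.r_bar)
    else:
        out = fp.r_bar * np.exp(
            fp.A * np.sin(2 * np.pi * t / fp.p + fp.s * np.pi / 180 + np.pi)
            - fp.A ** 2 / 4)
    return float(out) if out.ndim == 0 else out


def predation_mortality(Xa, Xs, Xh, hp: HalibutParams) -> Tuple[float, float]:
    """Halibut predation rates (P_a, P_s) in 1/yr from the multi-prey
    Type-II functional response.

    P_i = Cmax alpha_i Xh / (Cmax + alpha_a Xa + alpha_s Xs + Y).  The
    shared denominator produces prey-switching buffering: P_a falls as the
    other prey becomes more abundant.  Pelican predation on the forage
    stocks is neglected (a small share of total mortality).
    """
    den = hp.Cmax + hp.alpha_a * Xa + hp.alpha_s * Xs + hp.Y
    if den <= 0:
        return 0.0, 0.0
    return (hp.Cmax * hp.alpha_a * Xh / den, hp.Cmax * hp.alpha_s * Xh / den)


def halibut_recruitment(Xh_lag: float, hp: HalibutParams) -> float:
    """Beverton-Holt recruits/yr from lagged halibut biomass, discounted by
    pre-recruit survival exp(-M_j tau)."""
    return hp.a * Xh_lag / (1.0 + hp.b * Xh_lag) * np.exp(-hp.M_j * hp.tau)


def halibut_asymptotic_mass(Xa, Xs, hp: HalibutParams) -> float:
    """Prey-dependent asymptotic mass w_inf (t).

    Relative realized consumption f = (alpha_a Xa + alpha_s Xs + Y) /
    (Cmax + alpha_a Xa + alpha_s Xs + Y) scales the baseline asymptotic
    mass as (f / f_base)^gamma_w (generalized von Bertalanffy energetics).
    """
    if hp.gamma_w == 0:
        return hp.w_inf0
    den = hp.Cmax + hp.alpha_a * Xa + hp.alpha_s * Xs + hp.Y
    f = (hp.alpha_a * Xa + hp.alpha_s * Xs + hp.Y) / den
    return hp.w_inf0 * (f / hp.f_base) ** hp.gamma_w


def forage_derivatives(state, t: float, F: Tuple[float, float],
                       params: FullParameterSet):
    """(dXa, dNa), (dXs, dNs) at time t under fishing mortalities F=(Fa, Fs).

    dN = [r(t) - (M + P + F)] N;
    dX = r(t) w_r N + kappa (w_inf N - X) - (M + P + F) X.
    """
    state = np.asarray(state, float)
    if np.any(state < 0):
        raise ValidationError("state variables must be non-negative")
    Xa, Na, Xs, Ns, Xh = state[0], state[1], state[2], state[3], state[4]
    Pa, Ps = predation_mortality(Xa, Xs, Xh, params.halibut)
    out = []
    for i, (fp, X, N, P) in enumerate(
            ((params.anchovy, Xa, Na, Pa), (params.sardine, Xs, Ns, Ps))):
        r = recruitment_rate(t, fp)
        loss = fp.M + P + F[i]
        dX = r * fp.w_r * N + fp.kappa * (fp.w_inf * N - X) - loss * X
        dN = (r - loss) * N
        out.append((dX, dN))
    return tuple(out)


def halibut_derivatives(state, t: float, lagged_Xh: float, F_h: float,
                        params: FullParameterSet) -> Tuple[float, float]:
    """(dXh, dNh) with recruitment from the lagged halibut biomass.

    dN = R(Xh(t - tau)) - (M + F) N (the metabolic rate does not remove
    individuals by default; set ``kappa_in_numbers_loss`` to recover the
    alternative bookkeeping);
    dX = R w_r + kappa (w_inf(Xa, Xs) N - X) - (M + F) X.
    """
    state = np.asarray(state, float)
    if np.any(state < 0) or lagged_Xh < 0:
        raise ValidationError("state variables must be non-negative")
    hp = params.halibut
    Xa, Xs, Xh, Nh = state[0], state[2], state[4], state[5]
    R = halibut_recruitment(lagged_Xh, hp)
    w_inf = halibut_asymptotic_mass(Xa, Xs, hp)
    dX = R * hp.w_r + hp.kappa * (w_inf * Nh - Xh) - (hp.M + F_h) * Xh
    extra = hp.kappa if hp.kappa_in_numbers_loss else 0.0
    dN = R - (hp.M + F_h + extra) * Nh
    return dX, dN


def pelican_depletion(Xa, Xs, pp: PelicanParams):
    """Diet-weighted forage depletion index d (dimensionless).

    d = Gamma_a Xa/Xa_o + Gamma_s Xs/Xs_o + Gamma_other; equals 1 at the
    unfished long-run means and Gamma_other with no forage at all.
    """
    if pp.Xa_o <= 0 or pp.Xs_o <= 0:
        raise ValidationError("baseline biomasses Xa_o, Xs_o must be > 0")
    return pp.Gamma_a * np.asarray(Xa, float) / pp.Xa_o \
        + pp.Gamma_s * np.asarray(Xs, float) / pp.Xs_o + pp.Gamma_other


def prey_response(d, theta) -> float:
    """Saturating prey-response scalar phi(d) in [0, 1].

    Zero for d <= theta1 (theta1 is the largest depletion with zero
    response), then rises as
    theta3 (1-theta1-theta2)(d-theta1) /
    [(1-theta1) theta2 (1-theta3) + theta3 (1-theta1-theta2)(d-theta1)],
    saturating at 1.  theta2 = 0 is the decoupled limit (phi = 1 above
    theta1).
    """
    t1, t2, t3 = theta
    if not (0 <= t1 < 1 and 0 <= t2 < 1 and 0 < t3 < 1 and t1 + t2 < 1):
        raise ValidationError(
            "prey-response parameters need 0 <= theta1 < 1, 0 <= theta2 < 1, "
            "0 < theta3 < 1, theta1 + theta2 < 1")
    return K._prey_response(float(d), t1, t2, t3)


def pelican_reproduction(Nbp_lag: float, phi_r: float,
                         pp: PelicanParams) -> float:
    """Successfully fledged chicks per year (female-only accounting).

    R = 0.5 exp(-Mbar tau_bp) Nbp_lag phi_r [1 + (Phi-1)(1 - (Nbp_lag /
    K_bp)^z)]; the density multiplier is Phi as N -> 0, 1 at N = K_bp, and
    is floored at 0.
    """
    if Nbp_lag < 0 or not 0 <= phi_r <= 1:
        raise ValidationError("Nbp_lag must be >= 0 and phi_r in [0, 1]")
    dens = 1.0 + (pp.Phi - 1.0) * (1.0 - (Nbp_lag / pp.K_bp) ** pp.z)
    return 0.5 * np.exp(-pp.Mbar * pp.tau_bp) * Nbp_lag * phi_r * max(dens, 0.0)


def pelican_mortality_rate(d: float, pp: PelicanParams) -> float:
    """Adult mortality M_bp = Mbar - log(phi_v(d)); equals Mbar when prey
    are abundant and grows as the survival scalar collapses (phi_v floored
    so the rate stays finite; extinction is reached dynamically)."""
    phi_v = max(prey_response(d, pp.theta_s), pp.phi_floor)
    return pp.Mbar - np.log(phi_v)


def pelican_derivative(state, t: float, lagged: Dict[str, float],
                       params: FullParameterSet) -> float:
    """dNbp/dt from lagged reproduction and current-prey mortality.

    ``lagged`` carries 'Xa', 'Xs' (prey at the forage maturation lags) and
    'Nbp' (pelicans at the pelican maturation lag).
    """
    state = np.asarray(state, float)
    if np.any(state < 0):
        raise ValidationError("state variables must be non-negative")
    pp = params.pelican
    d_now = pelican_depletion(state[0], state[2], pp)
    if pp.use_lagged_phi_r:
        d_rep = pelican_depletion(lagged["Xa"], lagged["Xs"], pp)
    else:
        d_rep = d_now
    phi_r = prey_response(d_rep, pp.theta_r)
    R = pelican_reproduction(lagged["Nbp"], phi_r, pp)
    return R - pelican_mortality_rate(d_now, pp) * state[6]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Dense model trajectory with lagged-state access.

    ``states`` has columns (Xa, Na, Xs, Ns, Xh, Nh, Nbp) on the uniform
    grid ``t``; ``effort``/``F`` carry the per-species (a, s, h) effort and
    fishing-mortality paths actually applied.
    """

    t: np.ndarray
    states: np.ndarray
    effort: np.ndarray
    F: np.ndarray
    dt: float

    def state(self, t):
        """State at time(s) t by linear interpolation; times before 0 use
        the constant initial history."""
        t = np.clip(np.asarray(t, float), None, self.t[-1])
        cols = [np.interp(t, self.t, self.states[:, j],
                          left=self.states[0, j]) for j in range(7)]
        return np.stack(cols, axis=-1)

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_COLUMNS.index(name)]

    def effort_of(self, species: str) -> np.ndarray:
        return self.effort[:, SPECIES.index(species)]

    def F_of(self, species: str) -> np.ndarray:
        return self.F[:, SPECIES.index(species)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: t, the seven states, efforts and fishing rates."""
        data = {"t": self.t}
        for j, c in enumerate(STATE_COLUMNS):
            data[c] = self.states[:, j]
        for i, sp in enumerate(("a", "s", "h")):
            data[f"E{sp}"] = self.effort[:, i]
        for i, sp in enumerate(("a", "s", "h")):
            data[f"F{sp}"] = self.F[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(scenario_or_params, policy: PolicyPath,
             T: Optional[float] = None, dt: float = 0.05) -> Trajectory:
    """Integrate the food web under a policy over [0, T].

    ``scenario_or_params`` is a :class:`FullParameterSet` or anything with
    ``.params`` and ``.T`` (a scenario).  The initial history for all
    delayed terms is constant at the initial state.  States are clipped at
    zero (no resurrection).  The run is deterministic for fixed dt.
    """
    params = getattr(scenario_or_params, "params", scenario_or_params)
    if T is None:
        T = getattr(scenario_or_params, "T", 60.0)
    if dt <= 0 or T <= 0:
        raise ValidationError("T and dt must be > 0")
    nsteps = int(round(T / dt))
    packed = params.pack()
    codes, eol, constF = policy.lower(nsteps, dt)
    y0 = params.initial_state()
    Y, E, F = K.simulate_core(y0, nsteps, dt, packed["forc"], packed["fbio"],
                              packed["hal"], packed["pel"], packed["econ"],
                              packed["polc"], codes, eol, constF)
    t = np.arange(nsteps + 1) * dt
    return Trajectory(t=t, states=Y, effort=E, F=F, dt=dt)
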