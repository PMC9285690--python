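"""Profit flows, the open-access effort closure, and discounted value.

Instantaneous profit is quadratic in own effort,
Psi(X, E) = (p_tilde q X - c1 - c2 E) E, with fishing mortality F = q E.
An unmanaged fishery expands effort until average profit Psi/E is zero,
instantaneously: E_oa = max(0, (p_tilde q X - c1) / c2) — so realized
open-access profit is identically zero.  The regulator's objective is the
discounted integral of total profit (net present value).
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .params import EconParams, FullParameterSet, ValidationError, SPECIES
from .ecology import Trajectory

__all__ = ["profit", "open_access_effort", "myopic_effort", "npv"]


def profit(X, E, ec: EconParams):
    """Instantaneous profit Psi = (p_tilde q X - c1 - c2 E) E (currency/yr)."""
    X = np.asarray(X, float)
    E = np.asarray(E, float)
    out = (ec.p_tilde * ec.q * X - ec.c1 - ec.c2 * E) * E
    return float(out) if out.ndim == 0 else out


def open_access_effort(X, ec: EconParams):
    """Zero-average-profit effort E_oa = max(0, (p_tilde q X - c1) / c2).

    Below the break-even biomass c1 / (p_tilde q) the fishery is idle; at
    any positive E_oa the average profit Psi/E is exactly zero.
    """
    if ec.c2 <= 0:
        raise ValidationError("open-access closure undefined for c2 <= 0")
    out = np.maximum(0.0, (ec.p_tilde * ec.q * np.asarray(X, float) - ec.c1) / ec.c2)
    return float(out) if out.ndim == 0 else out


def myopic_effort(X, ec: EconParams):
    """Effort maximizing instantaneous profit at fixed biomass:
    (p_tilde q X - c1) / (2 c2), floored at zero."""
    out = np.maximum(0.0, (ec.p_tilde * ec.q * np.asarray(X, float) - ec.c1)
                     / (2.0 * ec.c2))
    return float(out) if out.ndim == 0 else out


def npv(trajectory: Trajectory, params: FullParameterSet,
        delta: float = None) -> Tuple[Dict[str, float], float]:
    """Per-species and total net present value of a trajectory.

    J_i = int_0^T e^{-delta t} Psi_i(X_i(t), E_i(t)) dt by trapezoidal
    quadrature on the trajectory's own grid.  Returns ({species: J_i}, J).
    """
    if delta is None:
        delta = params.delta
    disc = np.exp(-delta * trajectory.t)
    per: Dict[str, float] = {}
    for i, sp in enumerate(SPECIES):
        ec = params.econ[i]
        psi = profit(trajectory.states[:, 2 * i], trajectory.effort[:, i], ec)
        per[sp] = float(np.trapezoid(disc * psi, trajectory.t))
    return per, float(sum(per.values()))
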