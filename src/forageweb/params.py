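"""Parameter containers for the four-species food-web model.

Units throughout: biomass in metric tons (t), time in years, masses of
individual fish in tons (so a 150 g sardine has ``w_inf = 1.5e-4``),
the Brown Pelican population as a dimensionless index (initial value 100),
prices in arbitrary currency per ton.

The shipped calibration is a documented STAND-IN (see
:func:`forageweb.scenarios.default_parameters`); every field can be
overridden from a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ForageParams",
    "HalibutParams",
    "PelicanParams",
    "EconParams",
    "PolicyConstants",
    "FullParameterSet",
    "ValidationError",
    "SPECIES",
]

#: fished-species order used everywhere (state vectors, effort arrays, ...)
SPECIES = ("anchovy", "sardine", "halibut")


class ValidationError(ValueError):
    """A parameter set violates one of the model invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class ForageParams:
    """One forage species (anchovy or sardine).

    Recruitment is density independent with a deterministic sinusoidal
    forcing r(t) = r_bar * exp(A sin(2 pi t / p + s pi/180 + pi) - A^2/4);
    biomass follows a delay-difference growth structure with recruit mass
    ``w_r``, asymptotic mass ``w_inf`` and metabolic rate ``kappa``.
    """

    r_bar: float      # mean per-capita recruitment rate (1/yr)
    A: float          # recruitment amplitude (dimensionless, log scale)
    p: float          # recruitment period (yr)
    s: float          # phase start (degrees)
    w_r: float        # mass of a recruit (t)
    w_inf: float      # asymptotic mass (t)
    kappa: float      # metabolic/growth rate (1/yr)
    M: float          # natural mortality (1/yr)
    eta: float        # age at maturation / recruitment delay (yr)
    X0: float         # initial biomass (t)
    N0: float         # initial numbers

    def validate(self) -> None:
        _require(self.r_bar >= 0, "forage r_bar must be >= 0")
        _require(self.A >= 0, "forage A must be >= 0")
        _require(self.p > 0, "forage p must be > 0")
        _require(self.w_r <= self.w_inf, "forage w_r must be <= w_inf")
        _require(min(self.w_r, self.w_inf, self.kappa, self.M) >= 0,
                 "forage rates and masses must be >= 0")
        _require(self.eta >= 0, "forage eta must be >= 0")
        _require(self.X0 >= 0 and self.N0 >= 0, "forage initial state must be >= 0")


@dataclass
class HalibutParams:
    """The harvested predator (California halibut).

    Recruitment is Beverton-Holt on lagged halibut biomass with pre-recruit
    mortality ``M_j`` over the delay ``tau``; consumption of the two forage
    stocks follows a multi-prey Type-II functional response and feeds back
    on the asymptotic mass via ``(f / f_base)^gamma_w``.
    """

    a: float          # Beverton-Holt slope (recruits / t / yr)
    b: float          # Beverton-Holt shape (1/t)
    M_j: float        # pre-recruit mortality (1/yr)
    tau: float        # recruitment delay (yr)
    kappa: float      # metabolic/growth rate (1/yr)
    w_r: float        # recruit mass (t)
    w_inf0: float     # baseline asymptotic mass (t)
    Cmax: float       # maximum specific consumption (1/yr)
    alpha_a: float    # effective search/capture rate on anchovy (1/(t yr))
    alpha_s: float    # effective search/capture rate on sardine (1/(t yr))
    Y: float          # other-prey consumption constant (1/yr)
    gamma_w: float    # consumption->asymptotic-mass exponent
    M: float          # adult natural mortality (1/yr)
    X0: float
    N0: float
    f_base: float = 1.0  # relative realized consumption at baseline prey
    kappa_in_numbers_loss: bool = False  # preserve the printed numbers-loss form

    def validate(self) -> None:
        _require(min(self.a, self.b, self.Cmax, self.alpha_a, self.alpha_s,
                     self.Y, self.M_j, self.M, self.kappa) >= 0,
                 "halibut rates must be >= 0")
        _require(self.tau >= 0, "halibut tau must be >= 0")
        _require(self.w_r <= self.w_inf0, "halibut w_r must be <= w_inf0")
        _require(0 < self.f_base <= 1, "halibut f_base must be in (0, 1]")
        _require(self.X0 >= 0 and self.N0 >= 0, "halibut initial state must be >= 0")


@dataclass
class PelicanParams:
    """The unfished predator of conservation concern (Brown Pelican).

    Population is a dimensionless index starting at 100.  Reproduction and
    adult survival respond to the diet-weighted forage depletion index
    d = Gamma_a Xa/Xa_o + Gamma_s Xs/Xs_o + Gamma_other through a shared
    saturating prey-response scalar phi(d; theta).
    """

    Mbar: float                       # baseline adult mortality (1/yr)
    tau_bp: float                     # age at maturation (yr)
    Phi: float                        # maximum-productivity factor (>= 1)
    K_bp: float                       # index at which all females fledge one chick
    z: float                          # density-dependence exponent
    theta_r: Tuple[float, float, float]  # reproduction prey-response (t1, t2, t3)
    theta_s: Tuple[float, float, float]  # survival prey-response (t1, t2, t3)
    Gamma_a: float                    # baseline diet fraction, anchovy
    Gamma_s: float                    # baseline diet fraction, sardine
    Gamma_other: float                # baseline diet fraction, other prey
    Xa_o: float                       # long-run unfished mean anchovy biomass (t)
    Xs_o: float                       # long-run unfished mean sardine biomass (t)
    N0: float = 100.0                 # initial index
    use_lagged_phi_r: bool = True     # reproduction scalar at lagged depletion
    phi_floor: float = 1e-6           # survival-scalar floor keeping M_bp finite

    def validate(self) -> None:
        _require(self.Mbar >= 0 and self.tau_bp >= 0, "pelican rates must be >= 0")
        _require(self.Phi >= 1, "pelican Phi must be >= 1")
        _require(self.K_bp > 0 and self.z > 0, "pelican K_bp, z must be > 0")
        for name, (t1, t2, t3) in (("theta_r", self.theta_r),
                                   ("theta_s", self.theta_s)):
            _require(0 <= t1 < 1, f"pelican {name}[0] must be in [0, 1)")
            _require(0 <= t2 < 1, f"pelican {name}[1] must be in [0, 1)")
            _require(0 < t3 < 1, f"pelican {name}[2] must be in (0, 1)")
            _require(t1 + t2 < 1, f"pelican {name}: theta1 + theta2 must be < 1")
        gsum = self.Gamma_a + self.Gamma_s + self.Gamma_other
        _require(abs(gsum - 1.0) < 1e-9,
                 f"pelican diet fractions must sum to 1 (got {gsum})")
        _require(min(self.Gamma_a, self.Gamma_s, self.Gamma_other) >= 0,
                 "pelican diet fractions must be >= 0")
        _require(self.Xa_o > 0 and self.Xs_o > 0,
                 "pelican Xa_o, Xs_o must be > 0")
        _require(self.N0 >= 0, "pelican N0 must be >= 0")


@dataclass
class EconParams:
    """Per-fishery economics: Psi = (p_tilde q X - c1 - c2 E) E, F = q E."""

    p_tilde: float    # price per ton (currency/t)
    q: float          # catchability (1/(effort yr))
    c1: float         # linear effort cost (currency/effort/yr)
    c2: float         # quadratic effort cost (currency/effort^2/yr)

    def validate(self) -> None:
        _require(min(self.p_tilde, self.q, self.c1) >= 0,
                 "economic parameters must be >= 0")
        _require(self.c2 > 0, "c2 must be > 0 (interior optimal effort)")


@dataclass
class PolicyConstants:
    """Constants of the stylized sardine control rules.

    ``hcr_*``: current-harvest-guideline cutoff/cap/allocation/exploitation
    constants; ``hs_*``: hockey-stick knots (fractions of unfished biomass)
    and plateau multiple of natural mortality.
    """

    hcr_cutoff: float = 150_000.0
    hcr_cap: float = 200_000.0
    hcr_share: float = 0.87
    hcr_f0: float = 0.0465824
    hcr_f1: float = 0.06224328
    hs_lower: float = 0.4
    hs_upper: float = 0.8
    hs_fmax_mult: float = 0.5

    def validate(self) -> None:
        vals = (self.hcr_cutoff, self.hcr_cap, self.hcr_share, self.hcr_f0,
                self.hcr_f1, self.hs_lower, self.hs_upper, self.hs_fmax_mult)
        _require(min(vals) >= 0, "policy constants must be >= 0")
        _require(self.hs_lower < self.hs_upper,
                 "hockey-stick lower knot must be below upper knot")


@dataclass
class FullParameterSet:
    """Every biological and economic parameter plus policy constants."""

    anchovy: ForageParams
    sardine: ForageParams
    halibut: HalibutParams
    pelican: PelicanParams
    econ_anchovy: EconParams
    econ_sardine: EconParams
    econ_halibut: EconParams
    policy: PolicyConstants = field(default_factory=PolicyConstants)
    delta: float = 0.05   # discount rate (1/yr), shared across fisheries

    def validate(self) -> "FullParameterSet":
        for f in fields(self):
            v = getattr(self, f.name)
            if hasattr(v, "validate"):
                v.validate()
        _require(self.delta >= 0, "delta must be >= 0")
        return self

    # -- convenience accessors ------------------------------------------------

    @property
    def forage(self) -> Tuple[ForageParams, ForageParams]:
        return (self.anchovy, self.sardine)

    @property
    def econ(self) -> Tuple[EconParams, EconParams, EconParams]:
        """Economics for (anchovy, sardine, halibut)."""
        return (self.econ_anchovy, self.econ_sardine, self.econ_halibut)

    def initial_state(self) -> np.ndarray:
        """State vector [Xa, Na, Xs, Ns, Xh, Nh, Nbp]."""
        return np.array([
            self.anchovy.X0, self.anchovy.N0,
            self.sardine.X0, self.sardine.N0,
            self.halibut.X0, self.halibut.N0,
            self.pelican.N0,
        ])

    def copy(self, **top_level) -> "FullParameterSet":
        """Deep-ish copy (all sub-dataclasses re-created)."""
        new = FullParameterSet(
            anchovy=replace(self.anchovy),
            sardine=replace(self.sardine),
            halibut=replace(self.halibut),
            pelican=replace(self.pelican),
            econ_anchovy=replace(self.econ_anchovy),
            econ_sardine=replace(self.econ_sardine),
            econ_halibut=replace(self.econ_halibut),
            policy=replace(self.policy),
            delta=self.delta,
        )
        for k, v in top_level.items():
            setattr(new, k, v)
        return new

    # -- packing for the compiled simulator ----------------------------------

    def pack(self) -> dict:
        """Flat numpy arrays consumed by the jitted integrator."""
        a, s, h, pel = self.anchovy, self.sardine, self.halibut, self.pelican
        forc = np.array([[a.r_bar, a.A, a.p, a.s],
                         [s.r_bar, s.A, s.p, s.s]])
        fbio = np.array([[a.w_r, a.w_inf, a.kappa, a.M, a.eta],
                         [s.w_r, s.w_inf, s.kappa, s.M, s.eta]])
        hal = np.array([h.a, h.b, h.M_j, h.tau, h.kappa, h.w_r, h.w_inf0,
                        h.Cmax, h.alpha_a, h.alpha_s, h.Y, h.gamma_w, h.M,
                        h.f_base, 1.0 if h.kappa_in_numbers_loss else 0.0])
        pelv = np.array([pel.Mbar, pel.tau_bp, pel.Phi, pel.K_bp, pel.z,
                         *pel.theta_r, *pel.theta_s,
                         pel.Gamma_a, pel.Gamma_s, pel.Gamma_other,
                         pel.Xa_o, pel.Xs_o,
                         1.0 if pel.use_lagged_phi_r else 0.0, pel.phi_floor])
        econ = np.array([[e.p_tilde, e.q, e.c1, e.c2] for e in self.econ])
        pc = self.policy
        polc = np.array([pc.hcr_cutoff, pc.hcr_cap, pc.hcr_share, pc.hcr_f0,
                         pc.hcr_f1, pc.hs_lower, pc.hs_upper, pc.hs_fmax_mult,
                         s.M, pel.Xs_o])
        return {"forc": forc, "fbio": fbio, "hal": hal, "pel": pelv,
                "econ": econ, "polc": polc}
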