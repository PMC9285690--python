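"""Calibrations, recruitment forcings, management regimes and scenarios.

This module plays the data-generator role for the analysis: it produces the
complete stand-in calibration (:func:`default_parameters`), the
deterministic recruitment-forcing variants, the management-regime registry,
and the sensitivity-analysis suite.

STAND-IN calibration
--------------------
The shipped parameter values are a documented stand-in chosen by closure
rather than an estimate from assessments:

* target unfished biomasses ``Xa_o = 600,000 t`` (anchovy), ``Xs_o =
  800,000 t`` (sardine), ``Xh_o = 20,000 t`` (halibut) pin down the mean
  recruitment rates (``r_bar_i = M_i + P_i*`` so the constant-forcing
  unfished system sits exactly at equilibrium) and the halibut
  Beverton-Holt scale;
* halibut predation at the baseline is a few percent of forage natural
  mortality (weak top-down control);
* the pelican diet is sardine-dominant and the density exponent ``z`` and
  scale ``K_bp`` are solved so that (i) total net productivity at
  saturating prey peaks at 60% of ``K_bp`` and (ii) the unfished pelican
  equilibrium equals the index value 100.

Every number can be replaced field-by-field from a YAML config file
(:func:`load_config`), which is the supported path to an external
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields as dc_fields
from typing import Optional, Tuple, List

import numpy as np
import yaml
from scipy.optimize import brentq

from .params import (ForageParams, HalibutParams, PelicanParams, EconParams,
                     PolicyConstants, FullParameterSet, ValidationError,
                     SPECIES)

__all__ = [
    "default_parameters", "load_config", "make_recruitment_forcing",
    "RecruitmentForcing", "Regime", "Scenario", "ConstraintSpec",
    "REGIME_NAMES", "get_regime", "make_scenario", "get_scenario",
    "sensitivity_suite", "unfished_baselines", "solve_pelican_density_exponent",
]

# Forcing defaults shared by the variability scenarios.  The amplitude is
# chosen so unfished log-biomass cycles span roughly a factor of e^2 for
# anchovy (the sinusoid integrates into log biomass with gain r_bar A p /
# 2 pi); phases start mid-cycle so initial biomass sits near the cycle
# midpoint rather than an extreme.
BASE_AMPLITUDE = 0.3
BASE_PERIOD = 25.0      # yr; two-plus full cycles inside a 60-yr horizon
LONG_SARDINE_PERIOD = 50.0
BASE_PHASE = 90.0       # degrees; +180 for the anti-synchronous partner

# Unfished biomass targets (t) anchoring the stand-in calibration.
_XA_TARGET = 600_000.0
_XS_TARGET = 800_000.0
_XH_TARGET = 20_000.0


def solve_pelican_density_exponent(Mbar: float, tau_bp: float, Phi: float,
                                   peak_frac: float = 0.6) -> float:
    """Density exponent z such that total net productivity at saturating prey,
    G(N) = 0.5 e^{-Mbar tau} N [1 + (Phi-1)(1 - (N/K)^z)] - Mbar N,
    is maximized at ``N = peak_frac * K`` (for any K).

    G'(N) = 0 at peak_frac*K reduces to (1+z) * peak_frac**z = target with
    target = (Phi - Mbar/c) / (Phi - 1), c = 0.5 e^{-Mbar tau}.  The root on
    the branch with stronger compensation (z past the maximizer of the
    left-hand side) is returned.
    """
    c = 0.5 * np.exp(-Mbar * tau_bp)
    target = (Phi - Mbar / c) / (Phi - 1.0)
    z_peak = -1.0 / np.log(peak_frac) - 1.0  # maximizer of (1+z) f^z

    def h(z):
        return (1.0 + z) * peak_frac ** z - target

    if target <= 0.0 or h(z_peak) <= 0.0:
        raise ValidationError(
            "no density exponent places peak productivity at "
            f"{peak_frac:.0%} of K_bp: raise Phi or lower Mbar")
    return float(brentq(h, z_peak, 80.0, xtol=1e-12))


def _phi(d, th):
    """Pure-python prey-response scalar (mirrors the compiled kernel)."""
    t1, t2, t3 = th
    if d <= t1:
        return 0.0
    if t2 <= 0.0:
        return 1.0
    num = t3 * (1.0 - t1 - t2) * (d - t1)
    den = (1.0 - t1) * t2 * (1.0 - t3) + num
    return float(min(1.0, max(0.0, num / den)))


def default_parameters() -> FullParameterSet:
    """Complete, internally consistent stand-in calibration.

    Every value is STAND-IN unless noted; the control-rule constants
    (cutoff 150,000 t, cap 200,000 t, share 0.87, exploitation constants)
    and the pelican initial index 100 are fixed by the management model.
    """
    # --- halibut biology (STAND-IN; magnitudes typical of the stock) -------
    hal = dict(b=1e-4, M_j=0.5, tau=4.0, kappa=0.2, w_r=5e-4, w_inf0=1e-2,
               Cmax=2.0, alpha_a=3e-6, alpha_s=3e-6, Y=1.0, gamma_w=1.0,
               M=0.25)

    # Type-II predation at the target unfished biomasses
    den = hal["Cmax"] + hal["alpha_a"] * _XA_TARGET + hal["alpha_s"] * _XS_TARGET + hal["Y"]
    Pa = hal["Cmax"] * hal["alpha_a"] * _XH_TARGET / den
    Ps = hal["Cmax"] * hal["alpha_s"] * _XH_TARGET / den
    f_base = (hal["alpha_a"] * _XA_TARGET + hal["alpha_s"] * _XS_TARGET + hal["Y"]) / den

    # --- forage biology (STAND-IN); r_bar closes the unfished equilibrium --
    def forage(w_r, w_inf, kappa, M, eta, P, X_target):
        r_bar = M + P
        w_mean = (r_bar * w_r + kappa * w_inf) / (r_bar + kappa)
        return ForageParams(r_bar=r_bar, A=0.0, p=BASE_PERIOD, s=0.0,
                            w_r=w_r, w_inf=w_inf, kappa=kappa, M=M, eta=eta,
                            X0=X_target, N0=X_target / w_mean)

    anchovy = forage(w_r=1e-5, w_inf=3e-5, kappa=0.6, M=0.8, eta=1.0,
                     P=Pa, X_target=_XA_TARGET)
    sardine = forage(w_r=3e-5, w_inf=1.5e-4, kappa=0.4, M=0.4, eta=2.0,
                     P=Ps, X_target=_XS_TARGET)

    # Halibut Beverton-Holt scale from the equilibrium closure
    w_mean_h = (hal["M"] * hal["w_r"] + hal["kappa"] * hal["w_inf0"]) / (hal["M"] + hal["kappa"])
    Nh0 = _XH_TARGET / w_mean_h
    R_needed = hal["M"] * Nh0  # recruits/yr surviving the pre-recruit stage
    a_bh = R_needed * (1.0 + hal["b"] * _XH_TARGET) / (
        _XH_TARGET * np.exp(-hal["M_j"] * hal["tau"]))
    halibut = HalibutParams(a=a_bh, X0=_XH_TARGET, N0=Nh0, f_base=f_base, **hal)

    # --- pelican (STAND-IN; tightly prey-coupled base case) -----------------
    Mbar, tau_bp, Phi = 0.1, 4.0, 5.0
    # reproduction responds to prey more strongly than adult survival
    theta_r = (0.2, 0.25, 0.8)
    theta_s = (0.15, 0.2, 0.85)
    z = solve_pelican_density_exponent(Mbar, tau_bp, Phi)
    # K_bp so that the unfished (d = 1) pelican equilibrium is the index 100
    c = 0.5 * np.exp(-Mbar * tau_bp)
    phi_r1 = _phi(1.0, theta_r)
    Mbp1 = Mbar - np.log(_phi(1.0, theta_s))
    x_eq = (Phi - Mbp1 / (c * phi_r1)) / (Phi - 1.0)  # (N*/K)^z at d = 1
    if x_eq <= 0:
        raise ValidationError("pelican baseline mortality exceeds maximum "
                              "productivity; no positive equilibrium")
    K_bp = 100.0 / x_eq ** (1.0 / z)
    pelican = PelicanParams(Mbar=Mbar, tau_bp=tau_bp, Phi=Phi, K_bp=K_bp,
                            z=z, theta_r=theta_r, theta_s=theta_s,
                            Gamma_a=0.3, Gamma_s=0.5, Gamma_other=0.2,
                            Xa_o=_XA_TARGET, Xs_o=_XS_TARGET, N0=100.0)

    # --- economics (STAND-IN; currency arbitrary, outputs reported as ratios)
    econ_a = EconParams(p_tilde=100.0, q=0.01, c1=180_000.0, c2=5_000.0)
    econ_s = EconParams(p_tilde=120.0, q=0.01, c1=240_000.0, c2=10_000.0)
    econ_h = EconParams(p_tilde=8_000.0, q=0.01, c1=640_000.0, c2=25_000.0)

    ps = FullParameterSet(anchovy=anchovy, sardine=sardine, halibut=halibut,
                          pelican=pelican, econ_anchovy=econ_a,
                          econ_sardine=econ_s, econ_halibut=econ_h,
                          policy=PolicyConstants(), delta=0.05)
    return ps.validate()


# ---------------------------------------------------------------------------
# recruitment forcing
# ---------------------------------------------------------------------------

FORCING_MODES = ("constant", "synchronous", "anti_synchronous",
                 "anti_synchronous_long_sardine")


@dataclass
class RecruitmentForcing:
    """Deterministic sinusoidal recruitment specification per forage species.

    ``anchovy``/``sardine`` hold (A, p, s): amplitude, period (yr) and phase
    start (degrees) of r(t) = r_bar exp(A sin(2 pi t/p + s pi/180 + pi) -
    A^2/4).
    """

    mode: str
    anchovy: Tuple[float, float, float]
    sardine: Tuple[float, float, float]

    def apply(self, ps: FullParameterSet) -> FullParameterSet:
        """Parameter set with this forcing written into the forage species."""
        new = ps.copy()
        for sp, (A, p, s) in (("anchovy", self.anchovy), ("sardine", self.sardine)):
            fp = getattr(new, sp)
            fp.A, fp.p, fp.s = A, p, s
        return new.validate()

    def rates(self, t, ps: FullParameterSet):
        """(r_a(t), r_s(t)) on a scalar or array t."""
        from .ecology import recruitment_rate
        applied = self.apply(ps)
        return (recruitment_rate(t, applied.anchovy),
                recruitment_rate(t, applied.sardine))


def make_recruitment_forcing(mode: str,
                             params: Optional[FullParameterSet] = None,
                             amplitude: float = BASE_AMPLITUDE,
                             period: float = BASE_PERIOD) -> RecruitmentForcing:
    """Forcing for one of the study's variability scenarios.

    constant: no variability; synchronous: equal amplitude/period/phase;
    anti_synchronous: phases half a period apart; the long-sardine variant
    additionally doubles the sardine period.
    """
    s0 = BASE_PHASE
    if mode == "constant":
        return RecruitmentForcing(mode, (0.0, period, s0), (0.0, period, s0))
    if mode == "synchronous":
        return RecruitmentForcing(mode, (amplitude, period, s0),
                                  (amplitude, period, s0))
    if mode == "anti_synchronous":
        return RecruitmentForcing(mode, (amplitude, period, s0),
                                  (amplitude, period, s0 + 180.0))
    if mode == "anti_synchronous_long_sardine":
        return RecruitmentForcing(mode, (amplitude, period, s0),
                                  (amplitude, LONG_SARDINE_PERIOD, s0 + 180.0))
    raise ValidationError(f"unknown forcing mode {mode!r}; "
                          f"expected one of {FORCING_MODES}")


# ---------------------------------------------------------------------------
# regimes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Regime:
    """Partition of the fished species into optimized / open-access / closed."""

    name: str
    optimized: Tuple[str, ...]
    open_access: Tuple[str, ...]
    closed: Tuple[str, ...]

    def __post_init__(self):
        members = sorted(self.optimized + self.open_access + self.closed)
        if members != sorted(SPECIES):
            raise ValidationError(
                f"regime {self.name!r} must partition {SPECIES}, got {members}")


_A, _S, _H = SPECIES

_REGIMES = {
    "OA_all": Regime("OA_all", (), (_A, _S, _H), ()),
    "H": Regime("H", (_H,), (_A, _S), ()),
    "S": Regime("S", (_S,), (_A, _H), ()),
    "A": Regime("A", (_A,), (_S, _H), ()),
    "H+S": Regime("H+S", (_S, _H), (_A,), ()),
    "H+A": Regime("H+A", (_A, _H), (_S,), ()),
    "A+S": Regime("A+S", (_A, _S), (_H,), ()),
    "A+S+H": Regime("A+S+H", (_A, _S, _H), (), ()),
    "Moratorium_all": Regime("Moratorium_all", (), (), (_A, _S, _H)),
}

REGIME_NAMES = tuple(_REGIMES)
#: the seven optimization regimes
OPTIMIZATION_REGIMES = ("H", "S", "A", "H+S", "H+A", "A+S", "A+S+H")

_LETTER = {"A": _A, "S": _S, "H": _H}


def get_regime(name: str) -> Regime:
    """Regime by name; ``"Moratorium:A+S"`` closes the listed species and
    leaves the rest under open access."""
    if name in _REGIMES:
        return _REGIMES[name]
    if name.startswith("Moratorium:"):
        letters = name.split(":", 1)[1].split("+")
        try:
            closed = tuple(_LETTER[c.strip()] for c in letters)
        except KeyError as e:
            raise ValidationError(f"unknown species letter in {name!r}") from e
        rest = tuple(s for s in SPECIES if s not in closed)
        return Regime(name, (), rest, closed)
    raise ValidationError(f"unknown regime {name!r}")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSpec:
    """Pelican-floor constraint: floor = Nbp_opt(T) + psi (Nbp_nofish(T) -
    Nbp_opt(T)); the threshold is filled in once the reference runs exist."""

    psi: float
    threshold: Optional[float] = None

    def __post_init__(self):
        if not 0.05 <= self.psi <= 0.2:
            raise ValidationError(f"psi must be in [0.05, 0.2], got {self.psi}")


@dataclass
class Scenario:
    name: str
    params: FullParameterSet          # forcing applied, baselines closed
    forcing: RecruitmentForcing
    regime: Regime
    constraint: Optional[ConstraintSpec] = None
    T: float = 60.0                   # optimization horizon (yr)
    longrun_T: float = 200.0          # unfished-average horizon (yr)


def unfished_baselines(params: FullParameterSet, T: float = 200.0,
                       dt: float = 0.05) -> Tuple[float, float]:
    """Long-run average unfished forage biomasses (Xa_o, Xs_o) over T years.

    These close the depletion index: d evaluated at the returned means is
    exactly 1 for the matching forcing.
    """
    from .ecology import simulate
    from .policies import PolicyPath
    traj = simulate(params, PolicyPath.moratorium(), T=T, dt=dt)
    return float(np.mean(traj.states[:, 0])), float(np.mean(traj.states[:, 2]))


def make_scenario(regime: str = "A+S+H", forcing: str = "constant",
                  params: Optional[FullParameterSet] = None,
                  T: float = 60.0, longrun_T: float = 200.0,
                  psi: Optional[float] = None,
                  close_baselines: bool = True) -> Scenario:
    """Assemble a named scenario: calibration + forcing + regime.

    With ``close_baselines`` the pelican baselines Xa_o, Xs_o are replaced
    by the 200-yr unfished means under the requested forcing.
    """
    ps = (params or default_parameters())
    fo = make_recruitment_forcing(forcing, ps)
    ps = fo.apply(ps)
    if close_baselines:
        xao, xso = unfished_baselines(ps, T=longrun_T)
        ps.pelican.Xa_o = xao
        ps.pelican.Xs_o = xso
        ps.validate()
    constraint = ConstraintSpec(psi) if psi is not None else None
    reg = get_regime(regime)
    return Scenario(name=f"{regime}/{forcing}", params=ps, forcing=fo,
                    regime=reg, constraint=constraint, T=T,
                    longrun_T=longrun_T)


def get_scenario(name: str, **kw) -> Scenario:
    """Scenario from a registry-style name ``"<regime>/<forcing>"``."""
    try:
        regime, forcing = name.rsplit("/", 1)
    except ValueError:
        raise ValidationError(
            f"scenario name {name!r} must look like 'A+S+H/synchronous'")
    return make_scenario(regime=regime, forcing=forcing, **kw)


def sensitivity_suite(base: Scenario) -> List[Scenario]:
    """The six robustness variants of a base scenario.

    higher discount (10%), forage prices +25%, pelican survival decoupled
    from prey (theta_s2 = 0), pelican recruitment decoupled (theta_2 = 0),
    initial stocks halved, and anti-synchronous forcing with a longer
    sardine period.
    """
    out: List[Scenario] = []

    def variant(name: str, ps: FullParameterSet,
                forcing: Optional[RecruitmentForcing] = None,
                reclose: bool = False) -> Scenario:
        fo = forcing or base.forcing
        ps = fo.apply(ps)
        if reclose:
            xao, xso = unfished_baselines(ps, T=base.longrun_T)
            ps.pelican.Xa_o = xao
            ps.pelican.Xs_o = xso
        ps.validate()
        return Scenario(name=f"{base.name}#{name}", params=ps, forcing=fo,
                        regime=base.regime, constraint=base.constraint,
                        T=base.T, longrun_T=base.longrun_T)

    ps = base.params.copy()
    ps.delta = 0.10
    out.append(variant("high_discount", ps))

    ps = base.params.copy()
    ps.econ_anchovy.p_tilde *= 1.25
    ps.econ_sardine.p_tilde *= 1.25
    out.append(variant("high_forage_price", ps))

    ps = base.params.copy()
    t1, _, t3 = ps.pelican.theta_s
    ps.pelican.theta_s = (t1, 0.0, t3)
    out.append(variant("decoupled_survival", ps))

    ps = base.params.copy()
    t1, _, t3 = ps.pelican.theta_r
    ps.pelican.theta_r = (t1, 0.0, t3)
    out.append(variant("decoupled_recruitment", ps))

    ps = base.params.copy()
    for sp in (ps.anchovy, ps.sardine, ps.halibut):
        sp.X0 *= 0.5
        sp.N0 *= 0.5
    # baselines stay those of the standard unfished system: the depleted
    # start is a perturbation to recover from, not a new baseline
    out.append(variant("half_initial", ps))

    fo = make_recruitment_forcing("anti_synchronous_long_sardine", base.params)
    out.append(variant("long_sardine_anti_synchronous", base.params.copy(),
                       forcing=fo, reclose=True))
    return out


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

_SECTIONS = {
    "anchovy": ForageParams, "sardine": ForageParams, "halibut": HalibutParams,
    "pelican": PelicanParams, "econ_anchovy": EconParams,
    "econ_sardine": EconParams, "econ_halibut": EconParams,
    "policy": PolicyConstants,
}
_TUPLE_FIELDS = {"theta_r", "theta_s"}


def load_config(path) -> FullParameterSet:
    """Defaults overridden field-by-field from a YAML file.

    Sections are the sub-parameter blocks (``anchovy``, ``sardine``,
    ``halibut``, ``pelican``, ``econ_*``, ``policy``) plus a top-level
    ``delta``.  Unknown sections or keys are rejected; the merged set must
    pass all invariants.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    ps = default_parameters()
    for section, payload in raw.items():
        if section == "delta":
            ps.delta = float(payload)
            continue
        if section not in _SECTIONS:
            raise ValidationError(f"unknown config section {section!r}")
        cls = _SECTIONS[section]
        valid = {f.name for f in dc_fields(cls)}
        target = getattr(ps, section)
        if not isinstance(payload, dict):
            raise ValidationError(f"config section {section!r} must be a mapping")
        for key, value in payload.items():
            if key not in valid:
                raise ValidationError(
                    f"unknown key {key!r} in config section {section!r}")
            if key in _TUPLE_FIELDS:
                value = tuple(float(v) for v in value)
            elif isinstance(getattr(target, key), bool):
                value = bool(value)
            else:
                value = float(value)
            setattr(target, key, value)
    return ps.validate()
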