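"""Harvest rules and fixed fishing policies.

Two stylized sardine rules are implemented alongside moratorium,
open-access and constant-F policies:

* the current-harvest-guideline approximation (catch-based): zero below a
  150,000 t cutoff, then ``0.87 (Xs - 150,000) Fs(t)`` capped at 200,000
  t/yr, where the exploitation fraction ``Fs(t) = 0.0465824 + 0.06224328
  r_s(t)/r_bar_s`` tracks the recruitment deviation;
* a hockey-stick rule: no fishing below 40% of unfished sardine biomass, a
  linear ramp, and a plateau at half the sardine natural mortality above
  80%.

Rules are applied to model biomass directly (no assessment error), and a
catch-based rule is converted to an instantaneous fishing mortality
``F = C / X`` at each instant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple, Union

import numpy as np

from .params import (EconParams, ForageParams, PolicyConstants,
                     FullParameterSet, ValidationError, SPECIES)
from . import _kernel as K

__all__ = ["hcr_catch", "hockey_stick_F", "rule_to_effort", "PolicyPath",
           "fixed_policies", "get_policy"]


def hcr_catch(Xs: float, r_s_t: float, r_s_bar: float,
              pc: PolicyConstants) -> float:
    """Stylized current sardine harvest guideline: catch in t/yr.

    Zero at or below the cutoff biomass, otherwise the allocated share of
    biomass above the cutoff times the recruitment-dependent exploitation
    fraction, capped.
    """
    if r_s_bar <= 0:
        raise ValidationError("r_s_bar must be > 0")
    Xs = float(Xs)
    if Xs <= pc.hcr_cutoff:
        return 0.0
    fexp = pc.hcr_f0 + pc.hcr_f1 * r_s_t / r_s_bar
    return float(min(pc.hcr_share * (Xs - pc.hcr_cutoff) * fexp, pc.hcr_cap))


def hockey_stick_F(Xs: float, Xs_o: float, M_s: float,
                   pc: PolicyConstants) -> float:
    """Hockey-stick fishing mortality (1/yr): 0 below the lower knot,
    linear ramp, plateau at ``hs_fmax_mult * M_s`` above the upper knot."""
    if Xs_o <= 0:
        raise ValidationError("Xs_o must be > 0")
    x = float(Xs) / Xs_o
    if x <= pc.hs_lower:
        return 0.0
    if x >= pc.hs_upper:
        return pc.hs_fmax_mult * M_s
    return pc.hs_fmax_mult * M_s * (x - pc.hs_lower) / (pc.hs_upper - pc.hs_lower)


def rule_to_effort(value: float, X: float, ec: EconParams,
                   kind: str = "catch") -> float:
    """Effort consistent with a rule's instantaneous catch (t/yr) or
    fishing-mortality rate (1/yr).  Zero biomass maps to zero effort."""
    if kind == "catch":
        F = value / X if X > 0 else 0.0
    elif kind == "F":
        F = value
    else:
        raise ValidationError(f"kind must be 'catch' or 'F', got {kind!r}")
    if ec.q <= 0:
        raise ValidationError("catchability q must be > 0 to convert to effort")
    return F / ec.q


# ---------------------------------------------------------------------------
# policy paths
# ---------------------------------------------------------------------------

# per-species policy spec: a tag string, ("constant_F", f), or
# ("open_loop", times, efforts) with piecewise-constant effort between times
_SpecT = Union[str, Tuple]

_CODE = {"closed": K.CLOSED, "open_access": K.OPEN_ACCESS,
         "myopic": K.MYOPIC, "hcr": K.HCR, "hockey_stick": K.HOCKEY}


@dataclass
class PolicyPath:
    """Per-species fishing policy: feedback rules or open-loop effort.

    ``specs`` maps each of ('anchovy', 'sardine', 'halibut') to one of
    'closed', 'open_access', 'myopic', 'hcr', 'hockey_stick' (sardine only),
    ('constant_F', f), ('open_loop', times, efforts), or a callable E(t).
    """

    specs: Dict[str, _SpecT]
    kind: str = "feedback"

    def __post_init__(self):
        missing = set(SPECIES) - set(self.specs)
        if missing:
            raise ValidationError(f"policy missing species {sorted(missing)}")
        for sp, spec in self.specs.items():
            if isinstance(spec, str) and spec in ("hcr", "hockey_stick") \
                    and sp != "sardine":
                raise ValidationError(f"rule {spec!r} applies to sardine only")

    # -- constructors --------------------------------------------------------

    @classmethod
    def moratorium(cls, species=None) -> "PolicyPath":
        """No fishing on the listed species (all by default); the rest
        under open access."""
        closed = set(species or SPECIES)
        return cls({sp: ("closed" if sp in closed else "open_access")
                    for sp in SPECIES}, kind="closed" if closed == set(SPECIES)
                   else "feedback")

    @classmethod
    def open_access(cls) -> "PolicyPath":
        return cls({sp: "open_access" for sp in SPECIES}, kind="open_access")

    @classmethod
    def constant_F(cls, F: Union[float, Dict[str, float]]) -> "PolicyPath":
        if not isinstance(F, dict):
            F = {sp: F for sp in SPECIES}
        return cls({sp: ("constant_F", float(F.get(sp, 0.0))) for sp in SPECIES},
                   kind="open_loop")

    @classmethod
    def sardine_rule(cls, rule: str, others: str = "open_access") -> "PolicyPath":
        """Sardine under 'hcr' or 'hockey_stick'; anchovy and halibut under
        ``others`` (open access by default, the status-quo comparison)."""
        return cls({"anchovy": others, "sardine": rule, "halibut": others})

    @classmethod
    def open_loop(cls, times: np.ndarray, efforts: Dict[str, np.ndarray],
                  others: str = "closed") -> "PolicyPath":
        """Piecewise-constant effort paths for the listed species."""
        specs: Dict[str, _SpecT] = {}
        for sp in SPECIES:
            if sp in efforts:
                specs[sp] = ("open_loop", np.asarray(times, float),
                             np.asarray(efforts[sp], float))
            else:
                specs[sp] = others
        return cls(specs, kind="open_loop")

    # -- kernel lowering -----------------------------------------------------

    def lower(self, nsteps: int, dt: float):
        """(codes, effort_grid, constF) arrays for the compiled simulator."""
        codes = np.zeros(3, dtype=np.int64)
        eol = np.zeros((3, max(nsteps, 1)))
        constF = np.zeros(3)
        tgrid = np.arange(nsteps) * dt
        for i, sp in enumerate(SPECIES):
            spec = self.specs[sp]
            if isinstance(spec, str):
                try:
                    codes[i] = _CODE[spec]
                except KeyError:
                    raise ValidationError(f"unknown policy spec {spec!r}")
            elif callable(spec):
                codes[i] = K.OPEN_LOOP
                eol[i] = np.maximum([float(spec(t)) for t in tgrid], 0.0)
            elif spec[0] == "constant_F":
                codes[i] = K.CONST_F
                constF[i] = spec[1]
            elif spec[0] == "open_loop":
                codes[i] = K.OPEN_LOOP
                times, efforts = spec[1], spec[2]
                idx = np.clip(np.searchsorted(times, tgrid, side="right") - 1,
                              0, len(efforts) - 1)
                eol[i] = np.maximum(efforts[idx], 0.0)
            else:
                raise ValidationError(f"unknown policy spec {spec!r}")
        return codes, eol, constF


def fixed_policies() -> Dict[str, Callable[..., PolicyPath]]:
    """Registry of named policy builders."""
    return {
        "moratorium": PolicyPath.moratorium,
        "open_access": PolicyPath.open_access,
        "constant_F": PolicyPath.constant_F,
        "HCR": lambda: PolicyPath.sardine_rule("hcr"),
        "hockey_stick": lambda: PolicyPath.sardine_rule("hockey_stick"),
    }


def get_policy(name: str) -> PolicyPath:
    """Policy by registry name, e.g. 'HCR' or 'constant_F:0.2'."""
    reg = fixed_policies()
    if name in reg:
        return reg[name]()
    if name.startswith("constant_F:"):
        return PolicyPath.constant_F(float(name.split(":", 1)[1]))
    raise ValidationError(f"unknown policy {name!r}")
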