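"""Kinetic scheme, free energies and strain-dependent transition rates.

The model describes one myosin head interacting with an actin filament as a
cyclic sequence of biochemical states.  Two states are detached (MT, the
myosin.ATP state, and MDP, the myosin.ADP.Pi state) and five are attached
(AMDP_PP pre-power-stroke, AMDP_PiR Pi-release, AMD_L low-force, AMD_H
high-force, and AM rigor).  Each attached state has a parabolic (or
piecewise-parabolic, in nonlinear mode) elastic free energy centred on its
own strain minimum: x1 for AMDP_PP, x11 for AMDP_PiR and AMD_L, x2 for
AMD_H, and 0 for AM.  The strain coordinate x is the axial distance between
a head's thick-filament anchor and the centre of the actin site it binds,
with x = 0 where the rigor (AM) free energy is minimal and shortening
carrying attached heads toward decreasing x.

Strain-dependent rates are built from the free-energy gap so that detailed
balance, k_forward(x) / k_reverse(x) = exp(dG(x) / kBT), holds exactly at
every strain, including where the numerical rate cap engages (the cap
rescales a reversible pair jointly).  One full cycle dissipates the free
energy of MgATP turnover (25 kBT by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml


class StateId(str, Enum):
    """Biochemical states of the actomyosin ATPase cycle."""

    MT = "MT"              # detached, ATP at the active site
    MDP = "MDP"            # detached, ADP + Pi at the active site
    AMDP_PP = "AMDP_PP"    # attached, pre-power-stroke
    AMDP_PIR = "AMDP_PiR"  # attached, Pi-release state
    AMD_L = "AMD_L"        # attached, low-force strongly bound
    AMD_H = "AMD_H"        # attached, high-force strongly bound
    AM = "AM"              # attached, rigor

    @property
    def attached(self) -> bool:
        return self in _ATTACHED

    @classmethod
    def parse(cls, name: str) -> "StateId":
        """Resolve a state name, accepting published alias spellings."""
        key = _ALIASES.get(name, name)
        for s in cls:
            if s.value == key:
                return s
        raise ValueError(f"unknown state identifier: {name!r}")


_ATTACHED = frozenset(
    {StateId.AMDP_PP, StateId.AMDP_PIR, StateId.AMD_L, StateId.AMD_H, StateId.AM}
)

# Alias table: the pre-power-stroke state appears in the literature both as
# AMD_PP and AMDP_PP; canonical identifier here is AMDP_PP.
_ALIASES: dict[str, str] = {
    "AMD_PP": "AMDP_PP",
    "AMDPPP": "AMDP_PP",
    "AMDP_PIR": "AMDP_PiR",
    "AMD_PiR": "AMDP_PiR",
}

#: cycle order used for validation and for reporting occupancies
CYCLE_ORDER: tuple[StateId, ...] = (
    StateId.MT,
    StateId.MDP,
    StateId.AMDP_PP,
    StateId.AMDP_PIR,
    StateId.AMD_L,
    StateId.AMD_H,
    StateId.AM,
)

STATE_INDEX: dict[StateId, int] = {s: i for i, s in enumerate(CYCLE_ORDER)}
N_STATES = len(CYCLE_ORDER)


@dataclass(frozen=True)
class Transition:
    """One directed edge of the kinetic scheme.

    Parameters
    ----------
    frm, to
        Source and destination states.
    k0
        Rate constant (1/s) at the reference strain where the elastic
        contribution to the forward log-rate vanishes.  For an attachment
        step with ``split = 1`` this is the rate at the strain minimum of
        the destination state; for a stroke with ``split = 0.5`` it is the
        rate where the two elastic energies are equal.
    reversible
        Whether a reverse rate is synthesised by detailed balance.
    split
        Fraction of the elastic free-energy difference assigned to the
        forward rate (0..1).  The reverse rate carries the complement, so
        detailed balance is exact for any split.
    window
        Optional ``(lo, hi)`` strain window outside which the forward rate
        is zero.  Only allowed on irreversible transitions (a one-sided
        window on a reversible pair would violate detailed balance).
    """

    frm: StateId
    to: StateId
    k0: float
    reversible: bool = True
    split: float = 0.5
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ValueError(f"negative rate constant for {self.frm}->{self.to}")
        if not 0.0 <= self.split <= 1.0:
            raise ValueError("split must lie in [0, 1]")
        if self.window is not None and self.reversible:
            raise ValueError(
                "a strain window is only allowed on irreversible transitions"
            )


@dataclass
class ModelParameters:
    """Full parameterization of kinetics, elasticity, energetics, geometry.

    Energies are expressed in kBT for basal (chemical) levels and pN*nm for
    elastic terms; lengths in nm; rates in 1/s.
    """

    # --- energetics / elasticity ---
    kbt: float = 4.0                  # thermal energy, pN*nm
    ks: float = 2.8                   # cross-bridge stiffness, pN/nm
    ks_compliant: float = 0.28        # nonlinear mode: slope at negative strain, pN/nm
    elasticity: str = "linear"        # "linear" | "nonlinear"
    dg_atp: float = 25.0              # free energy of MgATP turnover, kBT

    # --- free-energy minima (nm) ---
    x1: float = 5.5                   # AMDP_PP minimum
    x11: float = 5.0                  # AMDP_PiR / AMD_L minimum
    x2: float = 1.0                   # AMD_H minimum (AM minimum defines x = 0)

    # --- geometry ---
    site_spacing: float = 36.0        # target-zone repeat along actin, nm
    sites_per_zone: int = 1           # 1 or 3 binding sites per target zone
    intra_zone_spacing: float = 5.5   # separation of neighbouring sites, nm

    # --- numerics ---
    rate_cap: float = 1.0e6           # maximum allowed rate, 1/s

    # --- scheme ---
    basal_energy: dict[StateId, float] = field(default_factory=dict)
    transitions: list[Transition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.basal_energy:
            self.basal_energy = dict(_DEFAULT_BASAL)
        if not self.transitions:
            self.transitions = list(_DEFAULT_TRANSITIONS)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.ks <= 0 or self.kbt <= 0 or self.site_spacing <= 0:
            raise ValueError("ks, kBT and site spacing must be positive")
        if self.ks_compliant <= 0:
            raise ValueError("compliant-limb stiffness must be positive")
        if self.elasticity not in ("linear", "nonlinear"):
            raise ValueError(f"unknown elasticity mode {self.elasticity!r}")
        if not (self.x2 < self.x11 < self.x1):
            raise ValueError("free-energy minima must satisfy x2 < x11 < x1")
        if self.x1 <= 0:
            raise ValueError("x1 must be positive in the shortening convention")
        if self.sites_per_zone not in (1, 3):
            raise ValueError("sites_per_zone must be 1 or 3")
        if self.rate_cap <= 0:
            raise ValueError("rate cap must be positive")
        if abs(self.basal_energy.get(StateId.MT, 0.0)) > 1e-12:
            raise ValueError("basal energies are referenced to MT = 0")
        if self.detachment_drop <= 0:
            raise ValueError(
                "cycle closure (ATP-induced detachment) must dissipate energy: "
                f"got {self.detachment_drop:.3f} kBT"
            )
        seen = set()
        for tr in self.transitions:
            if (tr.frm, tr.to) in seen:
                raise ValueError(f"duplicate transition {tr.frm}->{tr.to}")
            seen.add((tr.frm, tr.to))

    # ------------------------------------------------------------------
    @property
    def detachment_drop(self) -> float:
        """Basal free-energy drop (kBT) of the AM -> MT closure step.

        Defined so the basal levels around one full cycle drop by exactly
        ``dg_atp``.
        """
        return self.dg_atp + self.basal_energy[StateId.AM] - self.basal_energy[StateId.MT]

    def basal_drop(self, frm: StateId, to: StateId) -> float:
        """Basal free-energy drop (kBT) of a directed transition."""
        if frm is StateId.AM and to is StateId.MT:
            return self.detachment_drop
        return self.basal_energy[frm] - self.basal_energy[to]

    def cycle_equilibrium_log(self) -> float:
        """ln of the product of equilibrium constants around the full cycle.

        Equals ``dg_atp`` by thermodynamic consistency.
        """
        total = 0.0
        for frm, to in zip(CYCLE_ORDER, CYCLE_ORDER[1:] + (CYCLE_ORDER[0],)):
            total += self.basal_drop(frm, to)
        return total

    def minimum_position(self, state: StateId) -> float:
        """Strain x_i (nm) at which the state's free energy is minimal."""
        if not state.attached:
            raise ValueError(f"{state.value} is detached: no elastic minimum")
        return {
            StateId.AMDP_PP: self.x1,
            StateId.AMDP_PIR: self.x11,
            StateId.AMD_L: self.x11,
            StateId.AMD_H: self.x2,
            StateId.AM: 0.0,
        }[state]

    @property
    def site_offsets(self) -> np.ndarray:
        """Site positions (nm) within one target zone, relative to its centre."""
        if self.sites_per_zone == 1:
            return np.array([0.0])
        return np.array([-self.intra_zone_spacing, 0.0, self.intra_zone_spacing])

    def with_x1(self, x1: float, coupling_nm: float = -0.5) -> "ModelParameters":
        """Copy with a new ``x1``, moving ``x11`` in parallel (x11 = x1 + coupling)."""
        return self.copy_with(x1=x1, x11=x1 + coupling_nm)

    def copy_with(self, **kw) -> "ModelParameters":
        out = replace(self, **kw)
        out.validate()
        return out

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "kbt": self.kbt,
            "ks": self.ks,
            "ks_compliant": self.ks_compliant,
            "elasticity": self.elasticity,
            "dg_atp": self.dg_atp,
            "x1": self.x1,
            "x11": self.x11,
            "x2": self.x2,
            "site_spacing": self.site_spacing,
            "sites_per_zone": self.sites_per_zone,
            "intra_zone_spacing": self.intra_zone_spacing,
            "rate_cap": self.rate_cap,
            "basal_energy": {s.value: float(e) for s, e in self.basal_energy.items()},
            "transitions": [
                {
                    "from": tr.frm.value,
                    "to": tr.to.value,
                    "k0": tr.k0,
                    "reversible": tr.reversible,
                    "split": tr.split,
                    **({"window": list(tr.window)} if tr.window else {}),
                }
                for tr in self.transitions
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        d = dict(d)
        basal = {
            StateId.parse(k): float(v) for k, v in d.pop("basal_energy", {}).items()
        }
        transitions = [
            Transition(
                frm=StateId.parse(t["from"]),
                to=StateId.parse(t["to"]),
                k0=float(t["k0"]),
                reversible=bool(t.get("reversible", True)),
                split=float(t.get("split", 0.5)),
                window=tuple(t["window"]) if t.get("window") else None,
            )
            for t in d.pop("transitions", [])
        ]
        for key, val in d.items():
            if key == "sites_per_zone":
                d[key] = int(val)
            elif key != "elasticity":
                d[key] = float(val)
        return cls(basal_energy=basal, transitions=transitions, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "ModelParameters":
        """The packaged default parameter set (data/default_params.yaml)."""
        from importlib.resources import files

        text = files("xbridge.data").joinpath("default_params.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


# ----------------------------------------------------------------------
# default scheme (used when a ModelParameters is built without an explicit
# transition table; the packaged YAML file carries the same values)
# ----------------------------------------------------------------------
_DEFAULT_BASAL: dict[StateId, float] = {
    StateId.MT: 0.0,
    StateId.MDP: -1.0,
    StateId.AMDP_PP: -2.5,
    StateId.AMDP_PIR: -3.5,
    StateId.AMD_L: -6.5,
    StateId.AMD_H: -17.0,
    StateId.AM: -21.0,
}

_DEFAULT_TRANSITIONS: tuple[Transition, ...] = (
    # ATP hydrolysis on the detached head; treated one-way at the resolution
    # of this scheme.
    Transition(StateId.MT, StateId.MDP, k0=100.0, reversible=False, split=0.5),
    # Attachment: Gaussian-weighted around the AMDP_PP minimum (split = 1
    # puts the whole elastic penalty on the forward rate, which makes the
    # reverse, early-detachment rate strain-independent).
    Transition(StateId.MDP, StateId.AMDP_PP, k0=400.0, reversible=True, split=1.0),
    # First (small) stroke: 0.5 nm shift of the minimum.
    Transition(StateId.AMDP_PP, StateId.AMDP_PIR, k0=5000.0, reversible=True, split=0.5),
    # Pi release; both states share the x11 minimum so the rate is
    # strain-independent.
    Transition(StateId.AMDP_PIR, StateId.AMD_L, k0=3000.0, reversible=True, split=0.5),
    # Main power stroke: x11 -> x2.
    Transition(StateId.AMD_L, StateId.AMD_H, k0=1.0e4, reversible=True, split=0.5),
    # ADP release with the final ~1 nm swing; strain-gated (accelerated at
    # negative strain) through the elastic term.
    Transition(StateId.AMD_H, StateId.AM, k0=800.0, reversible=True, split=0.8),
    # ATP-induced detachment at mM MgATP; effectively irreversible.
    Transition(StateId.AM, StateId.MT, k0=1.0e4, reversible=False, split=0.5),
)


# ----------------------------------------------------------------------
# energetics
# ----------------------------------------------------------------------
def elastic_energy(params: ModelParameters, state: StateId, x) -> np.ndarray | float:
    """Elastic free energy (pN*nm) of an attached state at strain x (nm).

    Linear mode: ks (x - x_i)^2 / 2.  Nonlinear mode: the integral of the
    piecewise-linear force law (stiffness ``ks`` for extension beyond the
    minimum, ``ks_compliant`` below it), which reduces bit-for-bit to the
    linear expression when ``ks_compliant == ks``.
    """
    if not state.attached:
        raise ValueError(f"elastic energy undefined for detached state {state.value}")
    xi = params.minimum_position(state)
    s = np.asarray(x, dtype=float) - xi
    if params.elasticity == "linear":
        e = 0.5 * params.ks * s * s
    else:
        k = np.where(s >= 0.0, params.ks, params.ks_compliant)
        e = 0.5 * k * s * s
    return e if e.ndim else float(e)


def cross_bridge_force(params: ModelParameters, state: StateId, x) -> np.ndarray | float:
    """Force (pN) exerted by an attached head at strain x; d(elastic_energy)/dx."""
    if not state.attached:
        raise ValueError(f"no cross-bridge force for detached state {state.value}")
    xi = params.minimum_position(state)
    s = np.asarray(x, dtype=float) - xi
    if params.elasticity == "linear":
        f = params.ks * s
    else:
        f = np.where(s >= 0.0, params.ks, params.ks_compliant) * s
    return f if f.ndim else float(f)


def free_energy(params: ModelParameters, state: StateId, x=0.0) -> np.ndarray | float:
    """Total free energy (kBT): basal chemical level plus elastic term."""
    base = params.basal_energy[state]
    if not state.attached:
        out = np.full_like(np.asarray(x, dtype=float), base)
        return out if out.ndim else float(out)
    g = base + np.asarray(elastic_energy(params, state, x)) / params.kbt
    return g if np.ndim(g) else float(g)


# ----------------------------------------------------------------------
# strain-dependent rates
# ----------------------------------------------------------------------
def _pair_log_rates(params: ModelParameters, tr: Transition, x) -> tuple[np.ndarray, np.ndarray]:
    """log forward / reverse rates before exponentiation, cap applied jointly."""
    x = np.asarray(x, dtype=float)
    e_from = (
        np.asarray(elastic_energy(params, tr.frm, x))
        if tr.frm.attached
        else np.zeros_like(x)
    )
    e_to = (
        np.asarray(elastic_energy(params, tr.to, x))
        if tr.to.attached
        else np.zeros_like(x)
    )
    dge = (e_from - e_to) / params.kbt          # elastic part of dG, kBT
    log_cap = math.log(params.rate_cap)
    with np.errstate(divide="ignore"):
        log_k0 = math.log(tr.k0) if tr.k0 > 0 else -np.inf
    log_f = log_k0 + tr.split * dge
    if tr.reversible:
        log_r = log_k0 + (tr.split - 1.0) * dge - params.basal_drop(tr.frm, tr.to)
        # joint cap keeps kf/kr — and therefore detailed balance — exact
        shift = np.minimum(0.0, np.minimum(log_cap - log_f, log_cap - log_r))
        return log_f + shift, log_r + shift
    log_f = np.minimum(log_f, log_cap)
    if tr.window is not None:
        lo, hi = tr.window
        log_f = np.where((x >= lo) & (x < hi), log_f, -np.inf)
    return log_f, np.full_like(x, -np.inf)


def pair_rates(params: ModelParameters, tr: Transition, x) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse rates (1/s) of a transition at strain(s) x."""
    log_f, log_r = _pair_log_rates(params, tr, x)
    return np.exp(log_f), np.exp(log_r)


def find_transition(params: ModelParameters, frm: StateId, to: StateId) -> tuple[Transition, bool]:
    """Locate the scheme edge carrying the directed pair; returns (edge, is_forward)."""
    for tr in params.transitions:
        if tr.frm is frm and tr.to is to:
            return tr, True
        if tr.reversible and tr.frm is to and tr.to is frm:
            return tr, False
    raise KeyError(f"transition {frm.value}->{to.value} is not in the scheme")


def transition_rate(params: ModelParameters, frm: StateId, to: StateId, x) -> np.ndarray | float:
    """Rate (1/s) of the directed transition ``frm -> to`` at strain(s) x."""
    tr, forward = find_transition(params, frm, to)
    kf, kr = pair_rates(params, tr, x)
    out = kf if forward else kr
    return out if np.ndim(out) else float(out)


def rate_matrix(params: ModelParameters, x: float) -> np.ndarray:
    """Generator matrix K (columns sum to zero) over the 7 states at strain x.

    Entry ``K[i, j]`` is the rate from state ``j`` to state ``i``; attachment
    is evaluated at the given strain directly (single-site view).  The
    steady-state solver expands this over binding-site channels itself.
    """
    k = np.zeros((N_STATES, N_STATES))
    for tr in params.transitions:
        kf, kr = pair_rates(params, tr, x)
        i, j = STATE_INDEX[tr.to], STATE_INDEX[tr.frm]
        k[i, j] += float(kf)
        if tr.reversible:
            k[j, i] += float(kr)
    np.fill_diagonal(k, k.diagonal() - k.sum(axis=0))
    return k
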