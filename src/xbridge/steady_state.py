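"""Steady-state state probabilities vs strain and force-velocity curves.

At constant sliding velocity v the strain of every head advects toward
decreasing x while the biochemical state evolves under the strain-dependent
kinetics: the steady state solves the transport balance

    -v dp/dx = K(x) p

over one 36 nm target-zone period with periodic closure, where K(x) is the
generator of the kinetic scheme expanded over binding-site channels (one
channel per attached state per site in the zone, plus the two detached
states).  The solver propagates cell-by-cell with matrix exponentials, so
the discrete solution is exact for rates piecewise-constant on cells; the
periodic solution is the eigenvector of the one-period monodromy matrix for
eigenvalue 1.  At v = 0 the stationary distribution of K(x) is solved
algebraically at every x.

Ensemble force follows by averaging the attached-channel elastic forces
over the (uniform) head-offset distribution, and the force-velocity,
power and Hill-fit quantities are derived from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .core import (
    ModelParameters,
    StateId,
    cross_bridge_force,
    pair_rates,
)

_DETACHED = (StateId.MT, StateId.MDP)
_ATTACHED = (StateId.AMDP_PP, StateId.AMDP_PIR, StateId.AMD_L, StateId.AMD_H, StateId.AM)


@dataclass(frozen=True)
class Channel:
    """One probability channel: a biochemical state, bound to a given site."""

    state: StateId
    site: int | None          # index into params.site_offsets, None if detached

    def label(self) -> str:
        return self.state.value if self.site is None else f"{self.state.value}@{self.site}"


def _channels(params: ModelParameters) -> list[Channel]:
    ch = [Channel(s, None) for s in _DETACHED]
    for si in range(len(params.site_offsets)):
        ch.extend(Channel(s, si) for s in _ATTACHED)
    return ch


class _ChannelScheme:
    """Generator matrices of the site-expanded scheme on a strain grid."""

    def __init__(self, params: ModelParameters, dx: float = 0.1):
        self.params = params
        self.dx = dx
        half = params.site_spacing / 2.0
        self.n_cells = int(round(params.site_spacing / dx))
        edges = -half + dx * np.arange(self.n_cells + 1)
        self.x_edges = edges
        self.x_mid = 0.5 * (edges[:-1] + edges[1:])
        self.channels = _channels(params)
        self.index = {(c.state, c.site): i for i, c in enumerate(self.channels)}
        self.n_ch = len(self.channels)
        self.K = self._build()
        self.active = self._active_channels()

    def _build(self) -> np.ndarray:
        p = self.params
        offs = p.site_offsets
        n, m = self.n_cells, self.n_ch
        K = np.zeros((n, m, m))
        for tr in p.transitions:
            fa, ta = tr.frm.attached, tr.to.attached
            if not fa and not ta:          # detached <-> detached
                kf, kr = pair_rates(p, tr, self.x_mid)
                i, j = self.index[(tr.to, None)], self.index[(tr.frm, None)]
                K[:, i, j] += kf
                if tr.reversible:
                    K[:, j, i] += kr
                continue
            for si, d in enumerate(offs):
                x = self.x_mid - d
                kf, kr = pair_rates(p, tr, x)
                j = self.index[(tr.frm, si if fa else None)]
                i = self.index[(tr.to, si if ta else None)]
                K[:, i, j] += kf
                if tr.reversible:
                    K[:, j, i] += kr
        diag = -K.sum(axis=1)
        idx = np.arange(m)
        K[:, idx, idx] += diag
        return K

    def _active_channels(self) -> np.ndarray:
        """Channels touched by any transition (isolated ones stay at p = 0)."""
        touched = np.zeros(self.n_ch, dtype=bool)
        off = self.K.copy()
        idx = np.arange(self.n_ch)
        off[:, idx, idx] = 0.0
        moved = off.max(axis=0)
        touched |= moved.any(axis=0)
        touched |= moved.any(axis=1)
        return np.nonzero(touched)[0]

    # -- force weights -------------------------------------------------
    def force_weights(self) -> np.ndarray:
        """Per-cell, per-channel cross-bridge force (pN); zero for detached."""
        p = self.params
        w = np.zeros((self.n_cells, self.n_ch))
        for ci, c in enumerate(self.channels):
            if c.site is None:
                continue
            x = self.x_mid - p.site_offsets[c.site]
            w[:, ci] = cross_bridge_force(p, c.state, x)
        return w

    def attached_mask(self) -> np.ndarray:
        return np.array([c.site is not None for c in self.channels])


@dataclass
class StateProbabilities:
    """Solution of the transport balance on the offset grid."""

    params: ModelParameters
    velocity: float                 # nm/s
    x: np.ndarray                   # cell midpoints, nm (head offset to zone centre)
    p: np.ndarray                   # (n_cells, n_channels)
    channels: list[Channel]
    _scheme: _ChannelScheme = field(repr=False, default=None)

    def occupancy(self, state: StateId) -> np.ndarray:
        """p(state, x) summed over binding-site channels."""
        cols = [i for i, c in enumerate(self.channels) if c.state is state]
        return self.p[:, cols].sum(axis=1)

    @property
    def attached_fraction(self) -> float:
        mask = self._scheme.attached_mask()
        return float(self.p[:, mask].sum(axis=1).mean())

    def force_per_head(self) -> float:
        """Period-averaged elastic force per head, pN."""
        w = self._scheme.force_weights()
        return float((self.p * w).sum(axis=1).mean())


def _stationary(K: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Normalized null vector of a generator, restricted to active channels."""
    n = K.shape[0]
    sub = K[np.ix_(active, active)]
    a = np.vstack([sub, np.ones(len(active))])
    b = np.zeros(len(active) + 1)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.zeros(n)
    p[active] = np.clip(sol, 0.0, None)
    return p / p.sum()


def solve_state_probabilities(
    params: ModelParameters,
    velocity: float,
    dx: float = 0.1,
    _scheme: _ChannelScheme | None = None,
) -> StateProbabilities:
    """Solve state probabilities over one spatial period at a sliding velocity.

    ``velocity`` is the shortening rate in nm/s per half sarcomere; 0 gives
    the isometric (algebraic) solution.  Probabilities sum to one at every
    grid point and are non-negative.
    """
    if velocity < 0:
        raise ValueError("eccentric (negative) velocities are out of scope")
    sch = _scheme if _scheme is not None else _ChannelScheme(params, dx)
    n, m = sch.n_cells, sch.n_ch

    if velocity == 0.0:
        p = np.zeros((n, m))
        for c in range(n):
            p[c] = _stationary(sch.K[c], sch.active)
        return StateProbabilities(params, 0.0, sch.x_mid.copy(), p, sch.channels, sch)

    act = sch.active
    Ksub = sch.K[np.ix_(np.arange(n), act, act)]
    dt = sch.dx / velocity
    E = linalg.expm(Ksub * dt)              # cell propagators, exact per cell
    Eh = linalg.expm(Ksub * (0.5 * dt))     # half-cell, for midpoint values

    mono = E[0]                             # M = E_0 E_1 ... E_{n-1}
    for c in range(1, n):
        mono = mono @ E[c]

    # Closure over the period: detached probability re-enters periodically
    # (the offset wraps to the next zone), while attached probability that
    # reaches the trailing boundary is handed to the detached pool — its
    # actual survival distance beyond the boundary is negligible because
    # detachment rates are capped-fast at such strains, and wrapping it
    # back as attached would spuriously re-enter it at large positive
    # strain.
    att_mask = sch.attached_mask()[act]
    mdp_hits = np.nonzero(act == sch.index[(StateId.MDP, None)])[0]
    if att_mask.any() and mdp_hits.size:
        mdp_pos = int(mdp_hits[0])
        wrap_op = np.eye(len(act))
        for ci in np.nonzero(att_mask)[0]:
            wrap_op[ci, ci] = 0.0
            wrap_op[mdp_pos, ci] = 1.0
        mono = wrap_op @ mono

    # periodic fixed point: (M - I) p = 0 with sum(p) = 1
    a = np.vstack([mono - np.eye(len(act)), np.ones(len(act))])
    b = np.zeros(len(act) + 1)
    b[-1] = 1.0
    sol, res, *_ = np.linalg.lstsq(a, b, rcond=None)
    p_edge_top = np.clip(sol, 0.0, None)
    tot = p_edge_top.sum()
    if not np.isfinite(tot) or tot <= 0:
        raise RuntimeError(
            f"periodic steady state did not converge at v={velocity}; "
            f"residual={res}"
        )
    p_edge_top /= tot

    p_mid = np.zeros((n, m))
    p_edge = p_edge_top
    for c in range(n - 1, -1, -1):          # march downward in x
        p_mid[c, act] = Eh[c] @ p_edge
        p_edge = E[c] @ p_edge
    return StateProbabilities(params, velocity, sch.x_mid.copy(), p_mid, sch.channels, sch)


def sample_stationary(
    params: ModelParameters,
    offsets: np.ndarray,
    seed: int | None = None,
    dx: float = 0.1,
    velocity: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-head states from the steady-state distribution at a velocity.

    For warm-starting a Monte Carlo run at its statistical steady state
    (isometric by default, or steadily shortening): returns
    ``(state_indices, anchors)`` where anchors are the bound-site
    coordinates (strain + filament position, with z = 0) for attached heads
    and NaN otherwise.
    """
    from .core import STATE_INDEX

    sol = solve_state_probabilities(params, velocity, dx)
    rng = np.random.default_rng(seed)
    offsets = np.asarray(offsets, dtype=float)
    cells = np.clip(
        np.searchsorted(sol._scheme.x_edges, offsets, side="right") - 1,
        0,
        sol.p.shape[0] - 1,
    )
    states = np.empty(offsets.size, dtype=np.int64)
    anchors = np.full(offsets.size, np.nan)
    site_offs = params.site_offsets
    for i, cell in enumerate(cells):
        probs = np.clip(sol.p[cell], 0.0, None)
        ch = sol.channels[rng.choice(probs.size, p=probs / probs.sum())]
        states[i] = STATE_INDEX[ch.state]
        if ch.site is not None:
            anchors[i] = offsets[i] - site_offs[ch.site]
    return states, anchors


def force_at_velocity(
    params: ModelParameters,
    velocity: float,
    n_heads: int = 1,
    dx: float = 0.1,
    _scheme: _ChannelScheme | None = None,
) -> float:
    """Ensemble force (pN) at a sliding velocity: n_heads x mean head force."""
    sol = solve_state_probabilities(params, velocity, dx, _scheme=_scheme)
    return n_heads * sol.force_per_head()


# ----------------------------------------------------------------------
# force-velocity curves
# ----------------------------------------------------------------------
@dataclass
class FVCurve:
    """Sampled force-velocity relation with derived summary quantities."""

    velocities: np.ndarray        # nm/s
    forces: np.ndarray            # pN
    attached_fractions: np.ndarray
    n_heads: int
    f0: float                     # isometric force, pN
    vmax: float                   # unloaded shortening velocity, nm/s
    pmax: float                   # maximum power, pN*nm/s
    v_at_pmax: float
    hill_a: float
    hill_b: float
    hill_f0: float

    @property
    def powers(self) -> np.ndarray:
        return self.forces * self.velocities

    def normalized(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_norm": self.velocities / self.vmax,
                "f_norm": self.forces / self.f0,
                "power_norm": self.powers / (self.f0 * self.vmax),
                "attached_fraction": self.attached_fractions,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "velocity_nm_per_s": self.velocities,
                "force_pn": self.forces,
                "power_pn_nm_per_s": self.powers,
                "attached_fraction": self.attached_fractions,
            }
        )


def hill_fit(
    velocities: np.ndarray, forces: np.ndarray, f0: float, vmax: float
) -> tuple[float, float, float]:
    """Fit the Hill hyperbola (F + a)(v + b) = (F0 + a) b to FV samples.

    Returns (a, b, F0_fit) from least squares on F(v) = (F0 b - a v)/(v + b).
    """
    v = np.asarray(velocities, dtype=float)
    f = np.asarray(forces, dtype=float)
    sel = f >= 0
    v, f = v[sel], f[sel]

    def model(vv, a, b, f0f):
        return (f0f * b - a * vv) / (vv + b)

    popt, _ = optimize.curve_fit(
        model, v, f, p0=[0.25 * f0, 0.25 * max(vmax, 1.0), f0], maxfev=20000
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def fv_curve(
    params: ModelParameters,
    velocities: np.ndarray | None = None,
    n_heads: int = 1,
    dx: float = 0.1,
) -> FVCurve:
    """Compute the force-velocity curve and its summary quantities.

    The velocity grid must span from 0 past the force zero-crossing; Vmax
    is then located by root finding and the maximum power by bounded
    maximization of F(v) * v.
    """
    if velocities is None:
        velocities = np.concatenate([[0.0], np.geomspace(50.0, 20000.0, 25)])
    v_grid = np.asarray(velocities, dtype=float)
    if v_grid[0] != 0.0:
        v_grid = np.concatenate([[0.0], v_grid])
    sch = _ChannelScheme(params, dx)

    forces = np.empty_like(v_grid)
    att = np.empty_like(v_grid)
    for i, v in enumerate(v_grid):
        sol = solve_state_probabilities(params, v, dx, _scheme=sch)
        forces[i] = n_heads * sol.force_per_head()
        att[i] = sol.attached_fraction
    f0 = forces[0]

    neg = np.nonzero(forces < 0)[0]
    if neg.size == 0:
        raise ValueError(
            "force does not cross zero on the velocity grid; extend the grid "
            f"beyond {v_grid[-1]:.0f} nm/s"
        )
    i1 = neg[0]
    i0 = i1 - 1
    f_of_v = lambda v: force_at_velocity(params, v, n_heads, dx, _scheme=sch)
    vmax = float(
        optimize.brentq(f_of_v, v_grid[i0], v_grid[i1], xtol=0.5, rtol=1e-6)
    )

    # maximum power on the positive-force branch
    powers = forces * v_grid
    k = int(np.argmax(powers[: i1 + 1]))
    lo = v_grid[max(k - 1, 0)]
    hi = v_grid[min(k + 1, i1)]
    res = optimize.minimize_scalar(
        lambda v: -v * f_of_v(v), bounds=(lo, hi), method="bounded",
        options={"xatol": max(0.5, 1e-4 * vmax)},
    )
    pmax = float(-res.fun)
    v_at_pmax = float(res.x)

    a, b, f0_fit = hill_fit(v_grid, forces, f0, vmax)
    return FVCurve(
        velocities=v_grid,
        forces=forces,
        attached_fractions=att,
        n_heads=n_heads,
        f0=float(f0),
        vmax=vmax,
        pmax=pmax,
        v_at_pmax=v_at_pmax,
        hill_a=a,
        hill_b=b,
        hill_f0=f0_fit,
    )


def max_power(
    params: ModelParameters,
    n_heads: int = 1,
    dx: float = 0.1,
    velocities: np.ndarray | None = None,
) -> tuple[float, float]:
    """Maximum power (pN*nm/s) and the velocity at which it occurs."""
    curve = fv_curve(params, velocities, n_heads, dx)
    return curve.pmax, curve.v_at_pmax
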