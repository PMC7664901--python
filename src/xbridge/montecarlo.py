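"""Event-driven (Gillespie) stochastic simulation of motor ensembles.

Heads are independent mechanokinetic units coupled only through the shared
filament coordinate z (nm, increasing in the shortening direction).  The
filament is rigid and inertia-free: after every stochastic event its
position is re-equilibrated so that the summed cross-bridge force equals
the external load (quasi-static mechanics).  Between events the
configuration — and therefore every propensity — is constant, which makes
the Gillespie algorithm exact here.

Three modes are supported: ``zero_load`` and ``constant_load`` (load clamp,
filament re-equilibrated after every mechanically relevant event) and
``isometric`` (filament held fixed, force recorded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    CYCLE_ORDER,
    N_STATES,
    STATE_INDEX,
    ModelParameters,
    StateId,
    cross_bridge_force,
    pair_rates,
)
from .geometry import Ensemble, place_heads

_MODES = ("zero_load", "constant_load", "isometric")


@dataclass
class SimulationConfig:
    """Run specification for one Monte Carlo simulation."""

    mode: str = "zero_load"
    n_heads: int = 18
    duration: float = 0.1              # s
    seed: int | None = None
    load: float = 0.0                  # pN, constant_load mode
    initial_state: str = "MDP"         # "MDP" (detached) or "AMDP_PP" (bound)
    placement: str = "random_binned"
    max_displacement_nm: float = 20000.0
    max_events: int = 5_000_000
    # advanced initialisation (e.g. warm start from a stationary solution):
    # explicit offsets, per-head state indices and attached-head anchors
    offsets: np.ndarray | None = None
    initial_states: np.ndarray | None = None
    initial_anchors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.n_heads <= 0:
            raise ValueError("n_heads must be positive")
        if self.mode != "constant_load" and self.load:
            raise ValueError("a nonzero load requires constant_load mode")
        if StateId.parse(self.initial_state) not in (StateId.MDP, StateId.AMDP_PP):
            raise ValueError("initial_state must be MDP or AMDP_PP")


@dataclass
class Trace:
    """Event-by-event record of one simulation."""

    times: np.ndarray                  # s, strictly increasing
    positions: np.ndarray              # filament position z, nm
    forces: np.ndarray                 # total cross-bridge force, pN
    counts: np.ndarray                 # (n_events, n_states) occupancies
    seed: int | None
    config: dict
    params: dict
    stopped_early: bool = False
    zero_attachment_episodes: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_s": self.times, "position_nm": self.positions, "force_pn": self.forces}
        )
        for i, s in enumerate(CYCLE_ORDER):
            df[f"n_{s.value}"] = self.counts[:, i]
        return df

    def mean_force(self, t_min: float = 0.0) -> float:
        """Time-weighted mean force (pN) over events after ``t_min``.

        Force is piecewise constant between events, so the average weights
        each recorded value by the waiting time that follows it.
        """
        sel = np.nonzero(self.times >= t_min)[0]
        if sel.size < 2:
            return float(self.forces[-1])
        dt = np.diff(self.times[sel])
        return float(np.sum(self.forces[sel][:-1] * dt) / np.sum(dt))

    def velocity(self, trailing_fraction: float = 0.8, n_samples: int = 400) -> float:
        """Sliding velocity (nm/s) from a least-squares slope of z(t).

        Fitted over the trailing fraction of the record.  The position is
        resampled onto a uniform time grid first: event times are denser
        when more heads are attached, so an unweighted fit over raw events
        would weight high-attachment (slower) episodes more heavily and
        bias the slope.
        """
        if self.times.size < 2:
            return 0.0
        t0 = self.times[0] + (1.0 - trailing_fraction) * (
            self.times[-1] - self.times[0]
        )
        t1 = self.times[-1]
        if t1 <= t0:
            return 0.0
        grid = np.linspace(t0, t1, n_samples)
        idx = np.clip(np.searchsorted(self.times, grid, side="right") - 1, 0, None)
        z = self.positions[idx]
        slope = np.polyfit(grid, z, 1)[0]
        return float(slope)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.tsv`` (events) and ``<prefix>.meta.json``."""
        prefix = Path(prefix)
        self.to_dataframe().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        meta = {
            "seed": self.seed,
            "config": self.config,
            "params": self.params,
            "stopped_early": self.stopped_early,
            "zero_attachment_episodes": self.zero_attachment_episodes,
        }
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


# ----------------------------------------------------------------------
# directed-edge table
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class _Edge:
    frm: int                  # state index
    to: int
    tr: object                # core.Transition
    forward: bool
    site_delta: float | None  # set on attachment edges (detached -> attached)


def _directed_edges(params: ModelParameters) -> list[_Edge]:
    edges: list[_Edge] = []
    for tr in params.transitions:
        i, j = STATE_INDEX[tr.frm], STATE_INDEX[tr.to]
        if not tr.frm.attached and tr.to.attached:
            for d in params.site_offsets:
                edges.append(_Edge(i, j, tr, True, float(d)))
        else:
            edges.append(_Edge(i, j, tr, True, None))
        if tr.reversible:
            edges.append(_Edge(j, i, tr, False, None))
    return edges


def _wrap(u: np.ndarray, period: float) -> np.ndarray:
    half = period / 2.0
    return (u + half) % period - half


# ----------------------------------------------------------------------
# quasi-static force balance
# ----------------------------------------------------------------------
def _balance_position(
    params: ModelParameters,
    anchors: np.ndarray,       # c = x_bind + z_bind for attached heads
    minima: np.ndarray,        # x_i of each attached head's state
    load: float,
    z_guess: float,
) -> float:
    """Filament position solving sum of cross-bridge forces = load."""
    if anchors.size == 0:
        return z_guess
    centers = anchors - minima
    if params.elasticity == "linear":
        return float(centers.mean() - load / (params.ks * anchors.size))

    def residual(z: float) -> float:
        s = centers - z
        k = np.where(s >= 0.0, params.ks, params.ks_compliant)
        return float(np.sum(k * s) - load)

    z0 = float(centers.mean() - load / (params.ks * anchors.size))
    lo, hi, span = z0 - 50.0, z0 + 50.0, 50.0
    while residual(lo) < 0:
        span *= 2.0
        lo -= span
    while residual(hi) > 0:
        span *= 2.0
        hi += span
    return float(optimize.brentq(residual, lo, hi, xtol=1e-9))


def rebalance_filament(ensemble: Ensemble, external_load: float | None = None) -> float:
    """Re-equilibrate the shared filament position of an Ensemble.

    Returns the new position; with no attached heads under load the
    position is left unchanged (the load is unsupported).  The residual
    force imbalance of the returned position is below 1e-6 pN.
    """
    params = ensemble.params
    load = ensemble.external_load if external_load is None else external_load
    anchors, minima = [], []
    for h in ensemble.heads:
        if h.state.attached:
            anchors.append(h.bound_site)
            minima.append(params.minimum_position(h.state))
    z = _balance_position(
        params, np.asarray(anchors), np.asarray(minima), load, ensemble.filament_position
    )
    ensemble.filament_position = z
    return z


# ----------------------------------------------------------------------
# reference propensity computation on Ensemble objects
# ----------------------------------------------------------------------
def propensity_table(ensemble: Ensemble) -> pd.DataFrame:
    """Per-head, per-edge propensities of an Ensemble configuration.

    A readable reference enumeration (head by head, edge by edge) used to
    validate the vectorized engine; columns: head, from, to, site_delta,
    rate.
    """
    params = ensemble.params
    z = ensemble.filament_position
    edges = _directed_edges(params)
    rows = []
    for h in ensemble.heads:
        for e in edges:
            if STATE_INDEX[h.state] != e.frm:
                continue
            if h.state.attached:
                x = h.bound_site - z
            elif e.site_delta is not None:
                u = float(_wrap(np.asarray(h.offset_nm - z), params.site_spacing))
                x = u - e.site_delta
            else:
                x = 0.0
            kf, kr = pair_rates(params, e.tr, x)
            rows.append(
                {
                    "head": h.id,
                    "from": CYCLE_ORDER[e.frm].value,
                    "to": CYCLE_ORDER[e.to].value,
                    "site_delta": e.site_delta,
                    "rate": float(kf if e.forward else kr),
                }
            )
    return pd.DataFrame(rows)


def gillespie_step(
    ensemble: Ensemble, rng: np.random.Generator
) -> tuple[dict, float] | None:
    """Execute one exact stochastic event on an Ensemble (reference path).

    Returns ``(event, waiting_time)`` or None when all propensities vanish
    (absorbing configuration).  The waiting time is exponential with the
    total propensity as rate; the event is chosen proportionally to the
    individual propensities; the filament is re-equilibrated afterwards.
    """
    table = propensity_table(ensemble)
    total = table["rate"].sum()
    if total <= 0.0:
        return None
    wait = rng.exponential(1.0 / total)
    pick = np.searchsorted(np.cumsum(table["rate"].to_numpy()), rng.uniform(0, total))
    row = table.iloc[int(pick)]
    head = ensemble.heads[int(row["head"])]
    params = ensemble.params
    z = ensemble.filament_position
    new_state = StateId.parse(row["to"])
    if new_state.attached and not head.state.attached:
        u = float(_wrap(np.asarray(head.offset_nm - z), params.site_spacing))
        head.bound_site = (u - float(row["site_delta"])) + z
    elif not new_state.attached:
        head.bound_site = None
    head.state = new_state
    rebalance_filament(ensemble)
    return dict(row), float(wait)


# ----------------------------------------------------------------------
# vectorized simulation engine
# ----------------------------------------------------------------------
class _Engine:
    """Array-based Gillespie loop over independent heads.

    Per-head propensity rows are cached; after an event that leaves the
    filament in place only the event head's row is recomputed, otherwise
    (position moved, so every strain changed) all rows are rebuilt.
    """

    def __init__(self, params: ModelParameters, config: SimulationConfig):
        self.params = params
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.edges = _directed_edges(params)
        self.n_edges = len(self.edges)
        n = config.n_heads

        if config.offsets is not None:
            self.u0 = np.asarray(config.offsets, dtype=float).copy()
            if self.u0.size != n:
                raise ValueError("offsets length must equal n_heads")
        else:
            heads = place_heads(
                n,
                mode=config.placement,
                seed=None if config.seed is None else config.seed + 1,
                half_period_nm=params.site_spacing / 2.0,
            )
            self.u0 = np.array([h.offset_nm for h in heads])
        self.state = np.full(n, STATE_INDEX[StateId.MDP], dtype=np.int64)
        self.c = np.full(n, np.nan)
        self.z = 0.0

        self.x_min = np.full(N_STATES, np.nan)
        for s in CYCLE_ORDER:
            if s.attached:
                self.x_min[STATE_INDEX[s]] = params.minimum_position(s)

        if config.initial_states is not None:
            self.state = np.asarray(config.initial_states, dtype=np.int64).copy()
            anchors = np.asarray(config.initial_anchors, dtype=float)
            self.c = anchors.copy()
            attached = np.array([CYCLE_ORDER[s].attached for s in self.state])
            if not np.array_equal(attached, np.isfinite(self.c)):
                raise ValueError("anchors must be finite exactly for attached states")
        elif StateId.parse(config.initial_state) is StateId.AMDP_PP:
            # bound at the nearest site of the nearest zone, strain = offset
            deltas = params.site_offsets
            nearest = deltas[np.argmin(np.abs(self.u0[:, None] - deltas[None, :]), axis=1)]
            self.state[:] = STATE_INDEX[StateId.AMDP_PP]
            self.c = (self.u0 - nearest) + self.z

        self.R = np.zeros((n, self.n_edges))
        self._recompute_rows(np.arange(n))
        self.counts = np.bincount(self.state, minlength=N_STATES).astype(np.int32)
        self.zero_attachment_episodes = 0
        if config.mode != "isometric":
            self._rebalance()

    # -- propensities ---------------------------------------------------
    def _recompute_rows(self, idx: np.ndarray) -> None:
        params = self.params
        R = self.R
        R[idx, :] = 0.0
        st = self.state[idx]
        x_att = self.c[idx] - self.z
        u = _wrap(self.u0[idx] - self.z, params.site_spacing)
        for e_i, e in enumerate(self.edges):
            mask = st == e.frm
            if not mask.any():
                continue
            rows = idx[mask]
            if e.site_delta is not None:
                x = u[mask] - e.site_delta
            elif CYCLE_ORDER[e.frm].attached:
                x = x_att[mask]
            else:
                x = np.zeros(rows.size)
            kf, kr = pair_rates(params, e.tr, x)
            R[rows, e_i] = kf if e.forward else kr

    # -- mechanics ------------------------------------------------------
    def _attached_mask(self) -> np.ndarray:
        return np.isfinite(self.c)

    def _rebalance(self) -> bool:
        att = self._attached_mask()
        if not att.any():
            if self.config.load > 0:
                self.zero_attachment_episodes += 1
            return False
        z_new = _balance_position(
            self.params,
            self.c[att],
            self.x_min[self.state[att]],
            self.config.load,
            self.z,
        )
        moved = z_new != self.z
        self.z = z_new
        return moved

    def total_force(self) -> float:
        att = self._attached_mask()
        if not att.any():
            return 0.0
        s = (self.c[att] - self.z) - self.x_min[self.state[att]]
        if self.params.elasticity == "linear":
            return float(self.params.ks * s.sum())
        k = np.where(s >= 0.0, self.params.ks, self.params.ks_compliant)
        return float(np.sum(k * s))

    # -- event loop -----------------------------------------------------
    def step(self) -> float | None:
        """One Gillespie event; returns the waiting time or None if absorbed."""
        tot = self.R.sum(axis=1)
        grand = tot.sum()
        if grand <= 0.0:
            return None
        wait = self.rng.exponential(1.0 / grand)
        head = int(np.searchsorted(np.cumsum(tot), self.rng.uniform(0.0, grand)))
        head = min(head, tot.size - 1)
        row = self.R[head]
        e_i = int(np.searchsorted(np.cumsum(row), self.rng.uniform(0.0, row.sum())))
        e_i = min(e_i, self.n_edges - 1)
        edge = self.edges[e_i]

        was_attached = CYCLE_ORDER[edge.frm].attached
        now_attached = CYCLE_ORDER[edge.to].attached
        if now_attached and not was_attached:
            u = float(_wrap(np.asarray(self.u0[head] - self.z), self.params.site_spacing))
            self.c[head] = (u - edge.site_delta) + self.z
        elif not now_attached:
            self.c[head] = np.nan
        self.counts[edge.frm] -= 1
        self.counts[edge.to] += 1
        self.state[head] = edge.to

        moved = False
        if self.config.mode != "isometric" and (was_attached or now_attached):
            moved = self._rebalance()
        if moved:
            self._recompute_rows(np.arange(self.state.size))
        else:
            self._recompute_rows(np.array([head]))
        return float(wait)


def run_simulation(config: SimulationConfig, params: ModelParameters) -> Trace:
    """Run one Monte Carlo simulation and record every event.

    Deterministic for a fixed seed.  The run stops early (flagged, not an
    error) if the filament runs beyond ``config.max_displacement_nm`` or
    the event budget is exhausted; an all-zero propensity configuration
    ends the run cleanly.
    """
    eng = _Engine(params, config)
    times = [0.0]
    positions = [eng.z]
    forces = [config.load if config.mode == "constant_load" else eng.total_force()]
    counts = [eng.counts.copy()]
    t = 0.0
    stopped = False
    while t < config.duration and len(times) <= config.max_events:
        wait = eng.step()
        if wait is None:
            break
        t += wait
        if t > config.duration:
            break
        times.append(t)
        positions.append(eng.z)
        if config.mode == "isometric":
            forces.append(eng.total_force())
        else:
            forces.append(config.load if config.mode == "constant_load" else 0.0)
        counts.append(eng.counts.copy())
        if abs(eng.z) > config.max_displacement_nm:
            stopped = True
            break
    return Trace(
        times=np.asarray(times),
        positions=np.asarray(positions),
        forces=np.asarray(forces),
        counts=np.asarray(counts),
        seed=config.seed,
        config={
            "mode": config.mode,
            "n_heads": config.n_heads,
            "duration": config.duration,
            "load": config.load,
            "initial_state": config.initial_state,
            "placement": config.placement,
        },
        params=params.to_dict(),
        stopped_early=stopped,
        zero_attachment_episodes=eng.zero_attachment_episodes,
    )
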