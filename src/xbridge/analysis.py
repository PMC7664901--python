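"""Post-processing of simulation output.

Step detection and clustering of displacement records, mechanical work per
step, exponential fits to isometric force development, and rank
correlations (with exact small-sample permutation p-values) for parameter
sweeps.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class StepEvent:
    """A step change in filament displacement."""

    time: float          # s
    amplitude: float     # signed, nm
    cluster: int | None = None


def detect_steps(
    times: np.ndarray,
    positions: np.ndarray,
    min_amplitude_nm: float = 0.5,
) -> list[StepEvent]:
    """Emit every event-to-event displacement change of at least the threshold.

    The simulation advances the filament in discrete jumps (the position is
    re-equilibrated after each stochastic event), so steps are simply the
    between-event increments; amplitudes are signed, shortening positive.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if times.size == 0:
        raise ValueError("empty trace")
    if times.size != positions.size:
        raise ValueError("times and positions must have equal length")
    dd = np.diff(positions)
    keep = np.abs(dd) >= min_amplitude_nm
    return [
        StepEvent(time=float(times[i + 1]), amplitude=float(dd[i]))
        for i in np.nonzero(keep)[0]
    ]


def cluster_steps(steps: list[StepEvent], window_ms: float = 0.4) -> list[StepEvent]:
    """Greedy windowing: group consecutive steps spanning at most one window.

    A cluster is a maximal run of time-ordered steps whose first-to-last
    spread stays within ``window_ms``; each step is labelled with its
    cluster id (0-based).
    """
    if any(
        steps[i].time > steps[i + 1].time for i in range(len(steps) - 1)
    ):
        raise ValueError("steps must be time-sorted")
    window_s = window_ms * 1e-3
    out: list[StepEvent] = []
    cluster = -1
    start_t = -math.inf
    for s in steps:
        if s.time - start_t > window_s:
            cluster += 1
            start_t = s.time
        out.append(StepEvent(time=s.time, amplitude=s.amplitude, cluster=cluster))
    return out


def cluster_sizes(steps: list[StepEvent]) -> dict[int, int]:
    """Number of steps in each cluster (cluster id -> count)."""
    sizes: dict[int, int] = {}
    for s in steps:
        if s.cluster is None:
            raise ValueError("steps are not clustered")
        sizes[s.cluster] = sizes.get(s.cluster, 0) + 1
    return sizes


def mechanical_work(
    step_nm: float, load_pn: float, kbt_pn_nm: float = 4.0, dg_atp_kbt: float = 25.0
) -> tuple[float, float, bool]:
    """Work done in one step against a load, in pN*nm and kBT.

    Returns ``(work_pn_nm, work_kbt, exceeds_atp)`` where the flag marks
    steps whose work exceeds the free energy of one MgATP turnover — the
    signature that a displacement cannot come from a single motor's stroke
    alone (a 4 nm step against 30 pN is 120 pN*nm = 30 kBT > 25 kBT).
    """
    w = step_nm * load_pn
    w_kbt = w / kbt_pn_nm
    return w, w_kbt, w_kbt > dg_atp_kbt


@dataclass(frozen=True)
class ForceRiseFit:
    """Saturating-exponential fit F(t) = F_inf (1 - exp(-k t))."""

    rate: float           # k, 1/s
    rate_stderr: float
    f_inf: float          # plateau force, pN
    f_inf_stderr: float


def fit_force_rise(
    times: np.ndarray,
    forces: np.ndarray,
    t_start: float = 0.0,
    upper_fraction: float | None = None,
) -> ForceRiseFit:
    """Least-squares fit of isometric force development to a single exponential.

    ``t_start`` discards an initial transient; ``upper_fraction`` (e.g. 0.5)
    restricts the fit to the part of the rise above that fraction of the
    plateau, the regime where a single-exponential description of force
    development is most defensible.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(forces, dtype=float)
    sel = t >= t_start
    t, f = t[sel], f[sel]
    if t.size < 4:
        raise ValueError("too few samples for an exponential fit")
    f_inf0 = float(np.mean(f[int(0.8 * f.size):])) or 1.0
    if upper_fraction is not None:
        sel = f >= upper_fraction * f_inf0
        # keep the contiguous tail from the first crossing
        idx = np.nonzero(sel)[0]
        if idx.size < 4:
            raise ValueError("too few samples above the fit threshold")
        t, f = t[idx[0]:], f[idx[0]:]
    crossed = np.nonzero(f >= 0.5 * f_inf0)[0]
    half = t[crossed[0]] if crossed.size else t[-1]
    k0 = math.log(2.0) / max(half, t[1] - t[0], 1e-6)

    def model(tt, f_inf, k):
        return f_inf * (1.0 - np.exp(-k * tt))

    try:
        popt, pcov = optimize.curve_fit(
            model, t, f, p0=[f_inf0, k0], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"force-rise fit did not converge (n={t.size}, "
            f"p0=({f_inf0:.3g}, {k0:.3g}))"
        ) from exc
    err = np.sqrt(np.diag(pcov))
    return ForceRiseFit(
        rate=float(popt[1]),
        rate_stderr=float(err[1]),
        f_inf=float(popt[0]),
        f_inf_stderr=float(err[0]),
    )


# ----------------------------------------------------------------------
# Spearman rank correlation with exact small-sample p-values
# ----------------------------------------------------------------------
def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def spearman(xs, ys, exact_n_max: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    For ``n <= exact_n_max`` the p-value is computed by full enumeration of
    the n! rank permutations (the null distribution of r under exchange of
    one variable's ranks, ties kept as mid-ranks); for larger samples the
    t-approximation is used.  Five points in perfect rank order give
    r = 1 with p = 2/120 ~ 0.0167.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rx, ry = _rank(x), _rank(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    r = float(rx_c @ ry_c) / denom

    if n <= exact_n_max:
        # enumerate permutations of one rank vector in vectorized batches
        obs = abs(float(rx_c @ ry_c))
        count = 0
        total = 0
        batch: list[tuple[float, ...]] = []

        def flush(batch_arr: list[tuple[float, ...]]) -> int:
            perms = np.asarray(batch_arr)
            vals = np.abs(perms @ rx_c)
            return int(np.sum(vals >= obs - 1e-9))

        for perm in itertools.permutations(ry_c):
            batch.append(perm)
            total += 1
            if len(batch) == 50000:
                count += flush(batch)
                batch = []
        if batch:
            count += flush(batch)
        p = count / total
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            tstat = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    return r, float(p)
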