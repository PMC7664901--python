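"""Ensemble geometry: actin site lattice and myosin head placement.

The simulated system approximates a muscle half-sarcomere by an in vitro
motility configuration: a long actin filament (default 20 um) presenting
myosin-binding target zones every 36 nm, each zone containing one or three
binding sites, swept by surface-anchored myosin heads whose axial offsets
relative to the nearest zone centre are uniformly distributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ModelParameters, StateId


@dataclass(frozen=True)
class SiteLattice:
    """Ordered actin binding-site positions along the filament.

    Each (possibly partial) 36 nm helical repeat contributes one target
    zone, so ``n_zones = ceil(length / spacing)``: a 20 um filament at
    36 nm spacing carries 556 zones (20000/36 = 555.6), i.e. 556 sites in
    the single-site configuration and 1668 with three-site target zones.
    """

    length_um: float
    spacing_nm: float = 36.0
    sites_per_zone: int = 1
    intra_zone_spacing_nm: float = 5.5

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.spacing_nm <= 0:
            raise ValueError("filament length and site spacing must be positive")
        if self.sites_per_zone not in (1, 3):
            raise ValueError("sites_per_zone must be 1 or 3")

    @property
    def n_zones(self) -> int:
        """One zone per started 36 nm repeat: ceil(length/d)."""
        return int(math.ceil(self.length_um * 1000.0 / self.spacing_nm))

    @property
    def n_sites(self) -> int:
        return self.n_zones * self.sites_per_zone

    @property
    def zone_centers(self) -> np.ndarray:
        return np.arange(self.n_zones) * self.spacing_nm

    @property
    def site_positions(self) -> np.ndarray:
        centers = self.zone_centers
        if self.sites_per_zone == 1:
            return centers
        offsets = np.array(
            [-self.intra_zone_spacing_nm, 0.0, self.intra_zone_spacing_nm]
        )
        return np.sort((centers[:, None] + offsets[None, :]).ravel())


def build_lattice(
    length_um: float,
    spacing_nm: float = 36.0,
    sites_per_zone: int = 1,
    intra_zone_spacing_nm: float = 5.5,
) -> SiteLattice:
    """Construct the deterministic actin site lattice."""
    return SiteLattice(length_um, spacing_nm, sites_per_zone, intra_zone_spacing_nm)


def head_count_from_density(
    density_per_um2: float, band_nm: float, length_um: float
) -> int:
    """Number of heads able to reach the filament.

    ``density * band(um) * length(um)``, floored: 5000 heads/um^2 over a
    30 nm band along 20 um gives 3000 heads (150 per um).
    """
    if density_per_um2 <= 0 or band_nm <= 0 or length_um <= 0:
        raise ValueError("density, band width and length must be positive")
    return int(math.floor(density_per_um2 * (band_nm / 1000.0) * length_um))


def sarcomere_heads_per_thin_filament(
    n_thick_halves: int, heads_per_half: int, n_thin: int
) -> float:
    """Heads available per thin filament in the half-sarcomere bookkeeping.

    Ten half thick filaments of 294 heads shared by twenty thin filaments
    gives 147 heads per thin filament.
    """
    if n_thick_halves <= 0 or heads_per_half <= 0 or n_thin <= 0:
        raise ValueError("all counts must be positive")
    return n_thick_halves * heads_per_half / n_thin


@dataclass
class MotorHead:
    """One myosin head: axial offset to its nearest target zone plus state."""

    id: int
    offset_nm: float                      # signed, within +/- spacing/2
    state: StateId = StateId.MDP
    bound_site: float | None = None       # strain-anchor c = x_bind + z, nm

    def __post_init__(self) -> None:
        if self.state.attached != (self.bound_site is not None):
            raise ValueError("bound site must be set iff the state is attached")


def place_heads(
    n_heads: int,
    mode: str = "random_binned",
    seed: int | None = None,
    half_period_nm: float = 18.0,
    bin_width_nm: float = 0.1,
    signed: bool = True,
    state: StateId = StateId.MDP,
) -> list[MotorHead]:
    """Draw myosin head offsets relative to the nearest target-zone centre.

    ``random_binned`` draws offsets uniformly over bins of ``bin_width_nm``
    covering the offset range (signed: [-half_period, +half_period), 360
    bins at the defaults; unsigned: [0, half_period), 180 bins), placing
    each head at its bin centre.  ``uniform_grid`` spaces heads evenly over
    the range, the deterministic large-ensemble limit.
    """
    if n_heads <= 0:
        raise ValueError("n_heads must be positive")
    lo = -half_period_nm if signed else 0.0
    hi = half_period_nm
    n_bins = int(round((hi - lo) / bin_width_nm))
    if mode == "random_binned":
        rng = np.random.default_rng(seed)
        bins = rng.integers(0, n_bins, size=n_heads)
        offsets = lo + (bins + 0.5) * bin_width_nm
    elif mode == "uniform_grid":
        offsets = lo + (np.arange(n_heads) + 0.5) * (hi - lo) / n_heads
    else:
        raise ValueError(f"unknown placement mode {mode!r}")
    return [MotorHead(id=i, offset_nm=float(o), state=state) for i, o in enumerate(offsets)]


@dataclass
class Ensemble:
    """A motor ensemble sharing one filament coordinate.

    ``filament_position`` (z, nm) increases in the shortening direction, so
    a head's strain when bound is ``bound_site - z`` and its detached offset
    advects as ``wrap(offset0 - z)``.
    """

    params: ModelParameters
    heads: list[MotorHead]
    filament_position: float = 0.0
    external_load: float = 0.0            # pN, opposing shortening
    lattice: SiteLattice | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.heads:
            raise ValueError("an ensemble needs at least one head")
        half = self.params.site_spacing / 2.0
        for h in self.heads:
            if abs(h.offset_nm) > half:
                raise ValueError(
                    f"head {h.id} offset {h.offset_nm} nm outside +/-{half} nm"
                )

    @property
    def n_heads(self) -> int:
        return len(self.heads)


def make_ensemble(
    params: ModelParameters,
    n_heads: int,
    mode: str = "random_binned",
    seed: int | None = None,
    external_load: float = 0.0,
    state: StateId = StateId.MDP,
) -> Ensemble:
    """Convenience constructor: place heads and wrap them in an Ensemble."""
    heads = place_heads(
        n_heads,
        mode=mode,
        seed=seed,
        half_period_nm=params.site_spacing / 2.0,
        state=state,
    )
    return Ensemble(params=params, heads=heads, external_load=external_load, seed=seed)
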