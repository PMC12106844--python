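"""Colony morphometry and derived kinetics.

Implements the quantities the simulator reports per snapshot: the
cross-sectional profile (bounding radial extent per z-bin), the
stack-of-disks volume estimate, colony radius and height, the peripheral
monolayer width, glucose/acetate flux partitioning, the growing-cell
fraction and radial/vertical expansion kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cells import CellPopulation
from .grid import DomainMasks
from .metabolism import SourceTerms

__all__ = [
    "CrossSectionProfile", "KineticsSeries", "FluxShares", "ExpansionFit",
    "profile_from_cells", "radius_height", "volume_from_profile",
    "monolayer_width", "monolayer_width_from_intensity", "flux_partition",
    "growing_fraction", "expansion_kinetics",
]


@dataclass
class CrossSectionProfile:
    """Bounding radial extent r(z) at fixed z-steps from the agar surface."""

    z: np.ndarray   # bin lower edges, strictly increasing from 0, um
    r: np.ndarray   # bounding radius per bin, um
    dz: float

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.z.size and (np.any(np.diff(self.z) <= 0) or self.z[0] < 0):
            raise ValueError("z must increase strictly from 0")
        if np.any(self.r < 0):
            raise ValueError("bounding radius must be nonnegative")


def profile_from_cells(pop: CellPopulation | list, dz: float = 5.0
                       ) -> CrossSectionProfile:
    """Cross-sectional profile: per z-bin maximum |x| extent of any cell.

    A cell's extent includes its cylinder projection and the cap radius;
    bins above the topmost cell are truncated.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if isinstance(pop, list):
        pop = CellPopulation.from_cells(pop)
    if len(pop) == 0:
        raise ValueError("no cells")
    r0 = pop.radius
    ux, uz = pop.axis
    half_x = np.abs(ux) * pop.length / 2.0 + r0
    half_z = np.abs(uz) * pop.length / 2.0 + r0
    x_ext = np.abs(pop.x) + half_x
    z_lo = np.maximum(pop.z - half_z, 0.0)
    z_hi = pop.z + half_z
    nbin = max(int(math.ceil(z_hi.max() / dz)), 1)
    r = np.zeros(nbin)
    k_lo = np.clip((z_lo / dz).astype(int), 0, nbin - 1)
    k_hi = np.clip(np.ceil(z_hi / dz).astype(int) - 1, 0, nbin - 1)
    for i in range(len(pop)):
        sl = slice(k_lo[i], k_hi[i] + 1)
        r[sl] = np.maximum(r[sl], x_ext[i])
    return CrossSectionProfile(z=np.arange(nbin) * dz, r=r, dz=dz)


def radius_height(profile: CrossSectionProfile) -> tuple[float, float]:
    """(radius, height): max bounding radius, and top z with nonzero radius."""
    if profile.r.size == 0:
        raise ValueError("empty profile")
    radius = float(profile.r.max())
    nz = np.nonzero(profile.r > 0)[0]
    height = float((nz.max() + 1) * profile.dz) if nz.size else 0.0
    return radius, height


def volume_from_profile(profile: CrossSectionProfile) -> float:
    """Stack-of-disks volume: V = sum(pi * r_i^2 * dz)."""
    if profile.r.size == 0:
        raise ValueError("empty profile")
    if profile.z.size > 1:
        steps = np.diff(profile.z)
        if not np.allclose(steps, profile.dz):
            raise ValueError("profile z-steps are not uniform")
    return float(np.sum(math.pi * profile.r ** 2 * profile.dz))


def _stack_layers(pop: CellPopulation, dx: float):
    """Per-x-column stack height in units of one cell thickness (2*r0).

    The stack height of a column is the top of the cell material above the
    agar surface divided by the cell diameter: a single resting horizontal
    layer gives 1, a second layer gives >= 2, a verticalized rod gives
    roughly its length in diameters.
    """
    r0 = pop.radius
    ux, uz = pop.axis
    half_x = np.abs(ux) * pop.length / 2.0 + r0
    top = pop.z + np.abs(uz) * pop.length / 2.0 + r0
    lo = pop.x - half_x
    hi = pop.x + half_x
    x_min = lo.min()
    nbin = max(int(math.ceil((hi.max() - x_min) / dx)), 1)
    z_top = np.zeros(nbin)
    k_lo = np.clip(((lo - x_min) / dx).astype(int), 0, nbin - 1)
    k_hi = np.clip(np.ceil((hi - x_min) / dx).astype(int) - 1, 0, nbin - 1)
    for i in range(len(pop)):
        sl = slice(k_lo[i], k_hi[i] + 1)
        z_top[sl] = np.maximum(z_top[sl], top[i])
    return z_top / (2 * r0), x_min


#: columns up to this many cell thicknesses count as monolayer (midpoint
#: between one and two resting layers)
_MONOLAYER_MAX_LAYERS = 1.5


def monolayer_width(pop: CellPopulation | list, grid_dx: float = 2.0) -> float:
    """Width of the peripheral single-cell-thick zone, two-side average.

    For each side the width is the horizontal extent of the outermost
    contiguous run of x-columns whose stack height is one cell (material
    top below 1.5 cell diameters).  A colony that is monolayer throughout
    returns half the footprint per side (the full footprint averaged over
    the two sides equals the half-width).
    """
    if isinstance(pop, list):
        pop = CellPopulation.from_cells(pop)
    if len(pop) == 0:
        raise ValueError("empty colony")
    layers, _ = _stack_layers(pop, grid_dx)
    occ = np.nonzero(layers > 0)[0]
    lo, hi = occ.min(), occ.max()
    mono = (layers > 0) & (layers <= _MONOLAYER_MAX_LAYERS)

    def run(idx_iter):
        w = 0
        for k in idx_iter:
            if layers[k] == 0:
                continue
            if mono[k]:
                w += 1
            else:
                break
        return w * grid_dx

    left = run(range(lo, hi + 1))
    right = run(range(hi, lo - 1, -1))
    footprint = (hi - lo + 1) * grid_dx
    if left + right >= footprint:  # all-monolayer degenerate case
        return footprint / 2.0
    return (left + right) / 2.0


def monolayer_width_from_intensity(intensity, dx: float,
                                   threshold_factor: float = 1.5) -> float:
    """Monolayer width from a projected-intensity trace (outer edge first).

    The monolayer plateau is the median of the leading quarter of the
    trace; the width is the distance from the outer edge to the first
    sample exceeding ``threshold_factor`` times the plateau (the sharp
    intensity rise where cells stack).
    """
    y = np.asarray(intensity, dtype=float)
    if y.size < 2:
        raise ValueError("trace too short")
    plateau = float(np.median(y[: max(1, y.size // 4)]))
    above = np.nonzero(y > threshold_factor * plateau)[0]
    return float((above[0] if above.size else y.size) * dx)


@dataclass
class FluxShares:
    """Colony-integrated flux partitions (fractions in [0, 1])."""

    glucose_aerobic: float
    glucose_anaerobic: float
    acetate_growth: float
    acetate_maintenance: float
    acetate_defined: bool
    glucose_defined: bool


def flux_partition(src: SourceTerms, masks: DomainMasks) -> FluxShares:
    """Integrate rho-weighted flux components over the colony region.

    Glucose uptake splits into its aerobic and anaerobic branches (each
    including the matching maintenance share); acetate uptake splits into
    growth vs maintenance.  A pair with zero total flux is flagged
    undefined (NaN shares).
    """
    col = masks.colony
    rho = masks.rho

    def integrate(q):
        return float(np.sum(rho[col] * np.broadcast_to(q, col.shape)[col]))

    g_maint_ana = integrate(src.Qg_maint_ana)
    g_maint = integrate(src.Q_g_maint)
    g_aer = integrate(src.Qg_aer) + (g_maint - g_maint_ana)
    g_ana = integrate(src.Qg_ana) + g_maint_ana
    a_growth = integrate(src.Qa_growth)
    a_maint = integrate(src.Q_a_maint)

    g_tot = g_aer + g_ana
    a_tot = a_growth + a_maint
    nan = float("nan")
    return FluxShares(
        glucose_aerobic=g_aer / g_tot if g_tot > 0 else nan,
        glucose_anaerobic=g_ana / g_tot if g_tot > 0 else nan,
        acetate_growth=a_growth / a_tot if a_tot > 0 else nan,
        acetate_maintenance=a_maint / a_tot if a_tot > 0 else nan,
        acetate_defined=a_tot > 0,
        glucose_defined=g_tot > 0,
    )


def growing_fraction(pop: CellPopulation | list, threshold: float = 0.01
                     ) -> float:
    """Fraction of cells with instantaneous growth rate strictly above threshold."""
    if isinstance(pop, list):
        pop = CellPopulation.from_cells(pop)
    if len(pop) == 0:
        return 0.0
    return float(np.mean(pop.lambda_inst > threshold))


@dataclass
class KineticsSeries:
    """Tidy per-snapshot series of colony-scale quantities."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["time", "radius", "height", "volume", "n_cells",
                 "growing_fraction", "monolayer_width",
                 "glucose_aerobic_share", "glucose_anaerobic_share",
                 "acetate_growth_share", "acetate_maintenance_share",
                 "expected_dead", "min_C_o_colony", "min_C_g_colony"]))

    def append(self, row: dict) -> None:
        self.table.loc[len(self.table)] = row

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ExpansionFit:
    radial_speed: float       # um/h
    r_squared: float
    height_increments: np.ndarray
    vertical_slowdown: bool


def expansion_kinetics(series: KineticsSeries | pd.DataFrame,
                       window: tuple[float, float],
                       slowdown_tol: float = 0.05) -> ExpansionFit:
    """Radial-speed fit and vertical-slowdown diagnosis inside a time window.

    The radial speed is the least-squares slope of radius vs time; the
    vertical trend is the sequence of height increments over the window's
    sample intervals, with ``vertical_slowdown`` true when every successive
    increment is no larger than the previous one (within ``slowdown_tol``
    of the largest increment).
    """
    df = series.table if isinstance(series, KineticsSeries) else series
    t1, t2 = window
    sub = df[(df["time"] >= t1) & (df["time"] <= t2)]
    if len(sub) < 4:
        raise ValueError("need at least 4 samples in the window")
    res = stats.linregress(sub["time"], sub["radius"])
    t = np.asarray(sub["time"], dtype=float)
    h = np.asarray(sub["height"], dtype=float)
    dh = np.diff(h)
    # compare mean vertical speeds over the two window halves; binning the
    # height into profile steps makes per-interval increments too noisy
    mid = (t1 + t2) / 2.0
    first = t <= mid
    v1 = stats.linregress(t[first], h[first]).slope if first.sum() >= 2 else np.nan
    v2 = stats.linregress(t[~first], h[~first]).slope if (~first).sum() >= 2 else np.nan
    slowdown = bool(v2 <= v1 * (1.0 - slowdown_tol))
    return ExpansionFit(radial_speed=float(res.slope),
                        r_squared=float(res.rvalue ** 2),
                        height_increments=dh,
                        vertical_slowdown=slowdown)
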