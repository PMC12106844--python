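"""Overdamped rod mechanics: contact forces, surface tension, motion.

Forces on a cell arise from (i) Hertz-like elastic repulsion at the
minimum-distance points between cylinder axes of overlapping cell pairs,
(ii) Hertz-like repulsion of cell caps penetrating the agar surface (z=0),
(iii) a spring pulling caps that protrude above the smoothed colony
outline back toward it (coarse surface tension), and (iv) a small settling
force toward the agar.  Pairwise contributions are equal and opposite.

Motion is overdamped: velocity = force / (zeta * L) and angular velocity =
torque / (zeta * L^3 / 12) with L the cap-to-cap cell length.  The explicit
update is stable only below a contact-stiffness bound, see
:func:`mech_stable_dt`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree

from .cells import Cell, CellPopulation, _wrap_angle
from .params import ParameterSet

__all__ = ["Forces", "compute_forces", "step_mechanics", "mech_stable_dt",
           "classify_orientation", "relax"]

#: margin (um) above the smoothed outline before surface tension engages
_SURFACE_TOL = 0.5
#: outline bin width (um) and smoothing window (bins)
_OUTLINE_DX = 2.0
_OUTLINE_SMOOTH = 7


@dataclass
class Forces:
    fx: np.ndarray
    fz: np.ndarray
    torque: np.ndarray
    max_overlap: float = 0.0


def _segment_gaps(pop: CellPopulation, pairs: np.ndarray):
    """Closest points between the cylinder axes of each candidate pair.

    Returns (distance, normal 2->1, contact offsets from both centres).
    Uses the standard clamped segment-segment closest-point construction.
    """
    i, j = pairs[:, 0], pairs[:, 1]
    ux, uz = pop.axis
    h = pop.length / 2.0
    wx = pop.x[i] - pop.x[j]
    wz = pop.z[i] - pop.z[j]
    b = ux[i] * ux[j] + uz[i] * uz[j]
    c = wx * ux[i] + wz * uz[i]
    f = wx * ux[j] + wz * uz[j]
    denom = 1.0 - b * b
    s = np.where(denom > 1e-12, (b * f - c) / np.maximum(denom, 1e-12), 0.0)
    s = np.clip(s, -h[i], h[i])
    t = np.clip(f + s * b, -h[j], h[j])
    s = np.clip(t * b - c, -h[i], h[i])
    # contact points and separation
    dx = wx + s * ux[i] - t * ux[j]
    dz = wz + s * uz[i] - t * uz[j]
    dist = np.hypot(dx, dz)
    return s, t, dx, dz, dist


def compute_forces(pop: CellPopulation, p: ParameterSet,
                   pairs: np.ndarray | None = None) -> Forces:
    """Per-cell forces (x, z) and torques for the current configuration."""
    n = len(pop)
    fx = np.zeros(n)
    fz = np.zeros(n)
    tq = np.zeros(n)
    r0 = pop.radius
    ux, uz = pop.axis
    h = pop.length / 2.0
    max_overlap = 0.0

    # --- cell-cell Hertzian repulsion -----------------------------------
    if n > 1:
        if pairs is None:
            pairs = neighbour_pairs(pop, p)
        if len(pairs):
            s, t, dx, dz, dist = _segment_gaps(pop, pairs)
            delta = 2.0 * r0 - dist
            hit = delta > 0
            if np.any(hit):
                i = pairs[hit, 0]
                j = pairs[hit, 1]
                d = delta[hit]
                max_overlap = float(d.max())
                dist_h = np.maximum(dist[hit], 1e-9)
                nx = dx[hit] / dist_h
                nz = dz[hit] / dist_h
                fmag = p.k_cc * math.sqrt(r0 / 2.0) * d ** 1.5
                fxi = fmag * nx
                fzi = fmag * nz
                fx += np.bincount(i, weights=fxi, minlength=n)
                fz += np.bincount(i, weights=fzi, minlength=n)
                fx -= np.bincount(j, weights=fxi, minlength=n)
                fz -= np.bincount(j, weights=fzi, minlength=n)
                # torque = r x F about each centre (2D scalar cross)
                rix = s[hit] * ux[i]
                riz = s[hit] * uz[i]
                rjx = t[hit] * ux[j]
                rjz = t[hit] * uz[j]
                tq += np.bincount(i, weights=rix * fzi - riz * fxi,
                                  minlength=n)
                tq -= np.bincount(j, weights=rjx * fzi - rjz * fxi,
                                  minlength=n)

    # --- cell-agar contact on both caps ---------------------------------
    for sgn in (-1.0, 1.0):
        ex = sgn * h * ux
        ez = pop.z + sgn * h * uz
        pen = r0 - ez
        hit = pen > 0
        if np.any(hit):
            fmag = p.k_ca * math.sqrt(r0) * pen[hit] ** 1.5
            fz[hit] += fmag
            tq[hit] += ex[hit] * fmag
            max_overlap = max(max_overlap, float(pen[hit].max()))

    # --- surface tension toward smoothed colony outline ------------------
    if n > 2:
        top = _smoothed_outline(pop)
        if top is not None:
            edges, smooth = top
            for sgn in (-1.0, 1.0):
                ex = pop.x + sgn * h * ux
                ez = pop.z + sgn * h * uz + r0
                k = np.clip(((ex - edges[0]) / _OUTLINE_DX).astype(int),
                            0, smooth.size - 1)
                excess = ez - smooth[k] - _SURFACE_TOL
                hit = excess > 0
                if np.any(hit):
                    fmag = p.k_surface * excess[hit]
                    fz[hit] -= fmag
                    tq[hit] -= sgn * h[hit] * ux[hit] * fmag

    # --- settling --------------------------------------------------------
    fz -= p.f_settle * (pop.length + 2 * r0)

    return Forces(fx, fz, tq, max_overlap)


def neighbour_pairs(pop: CellPopulation, p: ParameterSet,
                    skin: float = 1.0) -> np.ndarray:
    """Candidate contact pairs from a KD-tree on cell centres.

    ``skin`` enlarges the search radius so a pair list can be reused over
    several small mechanics steps before rebuilding.
    """
    reach = pop.length.max() + 2 * pop.radius + skin
    tree = cKDTree(np.column_stack([pop.x, pop.z]))
    pairs = tree.query_pairs(reach, output_type="ndarray")
    return pairs


def _smoothed_outline(pop: CellPopulation):
    """Per-x-bin maximum cap height, uniformly smoothed."""
    x1, z1, x2, z2 = pop.endpoints()
    xs = np.concatenate([x1, x2, pop.x])
    zs = np.concatenate([z1, z2, pop.z]) + pop.radius
    lo, hi = xs.min(), xs.max()
    nbin = max(int((hi - lo) / _OUTLINE_DX) + 1, 1)
    if nbin < 3:
        return None
    k = np.clip(((xs - lo) / _OUTLINE_DX).astype(int), 0, nbin - 1)
    top = np.zeros(nbin)
    np.maximum.at(top, k, zs)
    smooth = uniform_filter1d(top, size=min(_OUTLINE_SMOOTH, nbin),
                              mode="nearest")
    return (lo, hi), smooth


def mech_stable_dt(p: ParameterSet, delta_ref: float | None = None) -> float:
    """Largest mechanics step (h) stable for the stiffest expected contact.

    Linearizing the Hertz law at a reference overlap delta_ref (default
    0.3*r0), the overdamped contact relaxes with rate k_lin/(zeta*L_min);
    the explicit Euler update is stable below 2/rate, and a safety factor
    of 2 is applied.
    """
    if delta_ref is None:
        delta_ref = 0.3 * p.r0
    k = max(p.k_cc, p.k_ca)
    k_lin = 1.5 * k * math.sqrt(p.r0) * math.sqrt(delta_ref)
    l_min = p.l_div / 2.0
    return p.zeta * l_min / k_lin


def step_mechanics(pop: CellPopulation, forces: Forces, dt_mech: float,
                   p: ParameterSet) -> CellPopulation:
    """Advance positions and angles by one overdamped explicit step.

    dt_mech is in hours.  Refuses (ValueError, with a suggested step) when
    dt_mech exceeds the contact-stability bound.
    """
    bound = mech_stable_dt(p)
    if dt_mech > bound:
        raise ValueError(
            f"dt_mech={dt_mech:g} h exceeds the stability bound {bound:g} h "
            f"for the configured contact stiffness; use dt_mech <= {bound:g}")
    L = pop.length + 2 * pop.radius
    pop.x = pop.x + forces.fx / (p.zeta * L) * dt_mech
    pop.z = pop.z + forces.fz / (p.zeta * L) * dt_mech
    zeta_rot = p.zeta * L ** 3 / 12.0
    pop.angle = _wrap_angle(pop.angle + forces.torque / zeta_rot * dt_mech)
    return pop


def relax(pop: CellPopulation, p: ParameterSet, n_steps: int,
          dt_mech: float | None = None) -> CellPopulation:
    """Run n_steps mechanics steps at (or clamped to) the stable step."""
    bound = mech_stable_dt(p)
    dt = bound if dt_mech is None else min(dt_mech, bound)
    for _ in range(n_steps):
        f = compute_forces(pop, p)
        step_mechanics(pop, f, dt, p)
    return pop


def classify_orientation(cell: "Cell | float",
                         vertical_cutoff: float = math.pi / 4) -> str:
    """'vertical' iff |angle| > cutoff (strict; ties count as horizontal)."""
    angle = cell.angle if isinstance(cell, Cell) else float(cell)
    return "vertical" if abs(angle) > vertical_cutoff else "horizontal"
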