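"""Simulation orchestration: the macro/micro iteration loop and output.

Each macro iteration performs, in order: (1) rasterize the current cells
into colony/agar/air masks; (2) advance the glucose/oxygen/acetate fields
(implicit reaction-diffusion with oxygen at quasi-steady state); (3)
evaluate the local growth rate and maintenance state of every cell at its
position (bilinear sampling of the fields); (4) run the nested mechanics
loop - growth, division, contact forces, overdamped motion - and update
the starvation clocks and death probabilities.  Snapshots bundle cells,
fields, masks and derived observables at a fixed cadence.

The run is fully deterministic for a given parameter set and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metabolism, observables
from .cells import CellPopulation
from .grid import (DomainMasks, Grid, MetaboliteFields, build_masks,
                   metabolite_step, sample_bilinear)
from .mechanics import (compute_forces, mech_stable_dt, neighbour_pairs,
                        step_mechanics)
from .params import ParameterSet
from .starvation import (DeathModel, death_probability, death_zone_grid,
                         update_starvation_population)

logger = logging.getLogger("colonysim")

__all__ = ["Snapshot", "RunResult", "run_simulation", "write_run",
           "generate_fixtures"]


@dataclass
class Snapshot:
    """Time-stamped bundle of cells, fields and derived observables."""

    time: float
    pop: CellPopulation
    fields: MetaboliteFields | None
    masks: DomainMasks | None
    row: dict
    death_zone: tuple | None = None


@dataclass
class RunResult:
    snapshots: list[Snapshot]
    series: observables.KineticsSeries
    stop_reason: str  # "t_end" | "wall" | "top"


def _copy_pop(pop: CellPopulation) -> CellPopulation:
    return CellPopulation(
        id=pop.id, x=pop.x, z=pop.z, angle=pop.angle, length=pop.length,
        div_len=pop.div_len, radius=pop.radius, lambda_inst=pop.lambda_inst,
        tau_aer=pop.tau_aer, tau_ana=pop.tau_ana, p_death=pop.p_death,
        lineage=pop.lineage, next_id=pop.next_id)


def _derived_row(t, pop, masks, src, p, fields=None) -> dict:
    # 2 um z-steps: desk-scale colonies are tens of um tall, so the ~5 um
    # disks of the confocal imaging protocol would quantize the height
    prof = observables.profile_from_cells(pop, dz=2.0)
    radius, height = observables.radius_height(prof)
    volume = observables.volume_from_profile(prof)
    mono = observables.monolayer_width(pop) if len(pop) > 1 else float("nan")
    dz, _, _ = death_zone_grid(pop)
    row = {
        "time": t, "radius": radius, "height": height, "volume": volume,
        "n_cells": len(pop),
        "growing_fraction": observables.growing_fraction(pop, p.growth_threshold),
        "monolayer_width": mono,
        "glucose_aerobic_share": float("nan"),
        "glucose_anaerobic_share": float("nan"),
        "acetate_growth_share": float("nan"),
        "acetate_maintenance_share": float("nan"),
        "expected_dead": float(dz.sum()),
        "min_C_o_colony": float("nan"),
        "min_C_g_colony": float("nan"),
    }
    if masks is not None and src is not None and masks.colony.any():
        shares = observables.flux_partition(src, masks)
        row.update({
            "glucose_aerobic_share": shares.glucose_aerobic,
            "glucose_anaerobic_share": shares.glucose_anaerobic,
            "acetate_growth_share": shares.acetate_growth,
            "acetate_maintenance_share": shares.acetate_maintenance,
        })
    if masks is not None and fields is not None and masks.colony.any():
        col = masks.colony
        row["min_C_o_colony"] = float(fields.C_o[col].min())
        row["min_C_g_colony"] = float(fields.C_g[col].min())
    return row


def run_simulation(p: ParameterSet, t_end: float, snapshot_every: float = 1.0,
                   fixed_nutrients: tuple[float, float, float] | None = None,
                   keep_fields: bool = True,
                   initial_pop: CellPopulation | None = None) -> RunResult:
    """Run the hybrid model from a single founder cell.

    Parameters
    ----------
    p : validated parameter set (seed included).
    t_end : simulated duration in hours.
    snapshot_every : snapshot cadence in hours.
    fixed_nutrients : optional (C_g, C_o, C_a) to clamp every cell's local
        environment, disabling the PDE solve (nutrient-replete test mode).
    keep_fields : store fields/masks in snapshots (memory trade-off).
    initial_pop : optional starting population (default: one horizontal
        cell at the centre of the agar-air interface).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = p.rng()
    pop = initial_pop if initial_pop is not None else CellPopulation.founder(p, rng)
    grid = Grid.from_params(p)
    fields = MetaboliteFields.initial(grid, p)
    model = DeathModel(p.delta_aer, p.delta_ana)
    dt = p.dt_macro / 60.0
    n_steps = int(round(t_end / dt))
    # enough substeps that stability-sized mechanics steps span the whole
    # macro interval (n_mech_sub acts as a floor)
    n_sub = int(min(max(p.n_mech_sub, math.ceil(dt / mech_stable_dt(p))), 5000))
    dt_sub = dt / n_sub
    x_wall = p.domain_width / 2.0 - 2 * p.h_grid
    z_top = p.air_height - 3 * p.h_grid

    snapshots: list[Snapshot] = []
    series = observables.KineticsSeries()
    stop = "t_end"
    next_snap = 0.0
    t = 0.0
    masks = None
    src = None

    for step in range(n_steps + 1):
        # --- fields and per-cell growth state ---------------------------
        if fixed_nutrients is None:
            masks = build_masks(pop, grid, p)
            fields, src, _ = metabolite_step(fields, masks, p, dt,
                                             z_first=bool(step % 2))
            cg = sample_bilinear(fields.C_g, grid, pop.x, pop.z)
            co = sample_bilinear(fields.C_o, grid, pop.x, pop.z)
            ca = sample_bilinear(fields.C_a, grid, pop.x, pop.z)
        else:
            cg, co, ca = (np.full(len(pop), v, dtype=float)
                          for v in fixed_nutrients)
        g = metabolism.local_growth_rate(cg, co, ca, p)
        maint = metabolism.maintenance_allocation(cg, co, ca, p)
        lam = np.atleast_1d(np.asarray(g.lambda_total, dtype=float))
        pop.lambda_inst = lam.copy()

        # --- starvation clocks and death probability --------------------
        update_starvation_population(pop, np.atleast_1d(maint.starving),
                                     np.atleast_1d(maint.anaerobic), dt)
        pop.p_death = np.asarray(
            death_probability(pop.tau_aer, pop.tau_ana, model))

        # --- snapshot ----------------------------------------------------
        if t >= next_snap - 1e-9 or step == n_steps:
            row = _derived_row(t, pop, masks, src, p,
                               fields if fixed_nutrients is None else None)
            series.append(row)
            snapshots.append(Snapshot(
                time=t, pop=_copy_pop(pop),
                fields=fields.copy() if (keep_fields and fixed_nutrients is None) else None,
                masks=masks if keep_fields else None,
                row=row, death_zone=death_zone_grid(pop)))
            while next_snap <= t + 1e-9:
                next_snap += snapshot_every
        if step == n_steps:
            break

        # --- nested growth/mechanics loop -------------------------------
        # the candidate pair list is reused over substeps (displacements
        # per substep are far below the search skin) and rebuilt whenever
        # a division renumbers the population
        pairs = None
        for k_sub in range(n_sub):
            pop.grow(pop.lambda_inst, dt_sub)
            divided = pop.divide(p, rng)
            if divided or pairs is None or k_sub % 15 == 0:
                pairs = neighbour_pairs(pop, p, skin=2.0)
            f = compute_forces(pop, p, pairs=pairs)
            step_mechanics(pop, f, dt_sub, p)
        t += dt

        # --- domain guards -----------------------------------------------
        half_len = pop.length / 2 + pop.radius
        if np.any(np.abs(pop.x) + half_len > x_wall):
            logger.warning("colony reached the lateral wall at t=%.2f h", t)
            stop = "wall"
        if np.any(pop.z + half_len > z_top):
            logger.warning("colony reached the domain top at t=%.2f h", t)
            stop = "top"
        if stop != "t_end":
            row = _derived_row(t, pop, masks, src, p,
                               fields if fixed_nutrients is None else None)
            series.append(row)
            snapshots.append(Snapshot(t, _copy_pop(pop),
                                      fields.copy() if keep_fields and fixed_nutrients is None else None,
                                      masks if keep_fields else None,
                                      row, death_zone_grid(pop)))
            break

        logger.debug("t=%5.2f h  N=%6d  stop=%s", t, len(pop), stop)

    return RunResult(snapshots, series, stop)


def write_run(result: RunResult, out_dir: str | Path,
              light: bool = False) -> None:
    """Write a run to disk: kinetics CSV, cell tables and HDF5 fields."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.series.to_csv(out / "kinetics.csv")
    if light:
        return
    import h5py

    with h5py.File(out / "fields.h5", "w") as hf:
        for k, snap in enumerate(result.snapshots):
            snap.pop.to_csv(out / f"cells_t{snap.time:07.2f}.csv")
            grp = hf.create_group(f"t_{k:04d}")
            grp.attrs["time_h"] = snap.time
            if snap.fields is not None:
                grp.create_dataset("C_g", data=snap.fields.C_g)
                grp.create_dataset("C_o", data=snap.fields.C_o)
                grp.create_dataset("C_a", data=snap.fields.C_a)
            if snap.masks is not None:
                grp.create_dataset("mask", data=snap.masks.labels)
                grp.create_dataset("rho", data=snap.masks.rho)
                grp.attrs["h_um"] = snap.masks.grid.h
                grp.attrs["z_min_um"] = snap.masks.grid.z_min
            if snap.death_zone is not None:
                dz, xe, ze = snap.death_zone
                grp.create_dataset("death_zone", data=dz)
                grp.create_dataset("death_zone_x_edges", data=xe)
                grp.create_dataset("death_zone_z_edges", data=ze)


# ---------------------------------------------------------------------------
# synthetic fixture generation
# ---------------------------------------------------------------------------

def generate_fixtures(kind: str, params: dict | None = None, seed: int = 0,
                      out_dir: str | Path | None = None) -> dict:
    """Create synthetic cells / profiles / decay series with known truth.

    Kinds
    -----
    ``monolayer-colony``: a single row of horizontal cells spanning a
        configured footprint; the monolayer-width ground truth is the
        all-monolayer degenerate value (half the footprint).
    ``stacked-block``: a 3-deep block flanked by single-layer skirts of
        configured width; ground truth equals the skirt width.
    ``dome-profile``: r(z) = R*sqrt(1 - z/H) sampled every dz; the volume
        ground truth is the disk-sum in closed form,
        pi R^2 dz (n - dz*n*(n-1)/(2H)).
    ``decay-series``: counts a*exp(-delta*t) with optional lognormal noise.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    out: dict = {"kind": kind}

    if kind == "monolayer-colony":
        L = params.get("cell_length", 4.0)
        r0 = params.get("r0", 0.5)
        n = int(params.get("n_cells", 20))
        pitch = L + 2 * r0
        xs = (np.arange(n) - (n - 1) / 2) * pitch
        pop = CellPopulation(id=np.arange(n), x=xs, z=np.full(n, r0),
                             angle=np.zeros(n), length=np.full(n, L),
                             div_len=np.full(n, L + 1), radius=r0)
        out["pop"] = pop
        out["footprint"] = n * pitch
        out["monolayer_width_truth"] = n * pitch / 2.0

    elif kind == "stacked-block":
        L = params.get("cell_length", 4.0)
        r0 = params.get("r0", 0.5)
        half_core = params.get("half_core", 40.0)
        skirt = params.get("skirt", 25.0)
        pitch = L + 2 * r0
        xs_core = np.arange(-half_core + pitch / 2, half_core, pitch)
        rows = []
        for layer in range(3):
            for x in xs_core:
                rows.append((x, r0 + layer * 2 * r0))
        xs_sk = np.arange(half_core + pitch / 2, half_core + skirt, pitch)
        for x in xs_sk:
            rows.append((x, r0))
            rows.append((-x, r0))
        xs = np.array([r[0] for r in rows])
        zs = np.array([r[1] for r in rows])
        n = xs.size
        pop = CellPopulation(id=np.arange(n), x=xs, z=zs,
                             angle=np.zeros(n), length=np.full(n, L),
                             div_len=np.full(n, L + 1), radius=r0)
        out["pop"] = pop
        out["monolayer_width_truth"] = (xs_sk.size * pitch)

    elif kind == "dome-profile":
        R = params.get("R", 100.0)
        H = params.get("H", 40.0)
        dz = params.get("dz", 5.0)
        n = int(H / dz)
        z = np.arange(n) * dz
        r = R * np.sqrt(np.maximum(1 - z / H, 0.0))
        # closed-form disk sum: sum_i pi R^2 (1 - i dz/H) dz
        vol = math.pi * R ** 2 * dz * (n - dz * n * (n - 1) / (2 * H))
        out["profile"] = observables.CrossSectionProfile(z=z, r=r, dz=dz)
        out["volume_truth"] = vol

    elif kind == "decay-series":
        a = params.get("a", 1e9)
        delta = params.get("delta", 2.0)
        noise = params.get("noise", 0.0)
        n = int(params.get("n_points", 8))
        t = np.linspace(0.0, params.get("t_max", 3.0), n)
        counts = a * np.exp(-delta * t)
        if noise > 0:
            counts = counts * rng.lognormal(0.0, noise, size=n)
        out["times"] = t
        out["counts"] = counts
        out["a_truth"] = a
        out["delta_truth"] = delta

    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")

    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        if "pop" in out:
            out["pop"].to_csv(outp / f"{kind}-cells.csv")
        if "profile" in out:
            pd.DataFrame({"z_um": out["profile"].z,
                          "r_um": out["profile"].r}).to_csv(
                outp / f"{kind}.csv", index=False)
        if "times" in out:
            pd.DataFrame({"time_days": out["times"],
                          "cfu_per_ml": out["counts"]}).to_csv(
                outp / f"{kind}.csv", index=False)
    return out
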