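"""Rod-shaped cell agents: state, growth and division.

Cells are spherocylinders confined to the x-z plane: ``length`` is the
cylindrical (pole-to-pole) part excluding the two hemispherical caps of
radius ``radius``; ``angle`` is measured from the horizontal agar axis (+x)
and kept in [-pi/2, pi/2] (a rod is orientationally nematic).

The population is stored as a structure of numpy arrays
(:class:`CellPopulation`) for vectorized mechanics; a per-cell dataclass
(:class:`Cell`) is provided for single-cell semantics and I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Cell", "CellPopulation", "elongate_and_divide"]


@dataclass
class Cell:
    id: int
    x: float
    z: float
    angle: float
    length: float
    radius: float = 0.5
    lambda_inst: float = 0.0
    tau_aer: float = 0.0
    tau_ana: float = 0.0
    p_death: float = 0.0
    lineage: int = -1
    div_len: float | None = None  # division threshold drawn at birth


_FIELDS = ("id", "x", "z", "angle", "length", "lambda_inst",
           "tau_aer", "tau_ana", "p_death", "lineage")


class CellPopulation:
    """Structure-of-arrays container for the whole colony."""

    def __init__(self, *, id, x, z, angle, length, div_len, radius=0.5,
                 lambda_inst=None, tau_aer=None, tau_ana=None, p_death=None,
                 lineage=None, next_id=None):
        n = len(np.atleast_1d(x))

        def arr(v, fill=0.0, dtype=float):
            if v is None:
                return np.full(n, fill, dtype=dtype)
            return np.asarray(v, dtype=dtype).copy()

        self.id = arr(id, dtype=np.int64)
        self.x = arr(x)
        self.z = arr(z)
        self.angle = arr(angle)
        self.length = arr(length)
        self.div_len = arr(div_len)
        self.radius = float(radius)
        self.lambda_inst = arr(lambda_inst)
        self.tau_aer = arr(tau_aer)
        self.tau_ana = arr(tau_ana)
        self.p_death = arr(p_death)
        self.lineage = arr(lineage, fill=-1, dtype=np.int64)
        self.next_id = int(next_id if next_id is not None
                           else (self.id.max() + 1 if n else 0))

    # -- construction -----------------------------------------------------
    @classmethod
    def founder(cls, p, rng=None) -> "CellPopulation":
        """A single horizontal cell resting at the centre of the agar surface."""
        rng = rng or np.random.default_rng(p.seed)
        div = p.l_div * (1.0 + p.div_noise * rng.uniform(-1, 1))
        return cls(id=[0], x=[0.0], z=[p.r0], angle=[0.0],
                   length=[p.l_div / 2], div_len=[div], radius=p.r0,
                   next_id=1)

    @classmethod
    def from_cells(cls, cells: Sequence[Cell], p=None) -> "CellPopulation":
        radius = cells[0].radius if cells else (p.r0 if p else 0.5)
        l_div = p.l_div if p is not None else max(c.length for c in cells) + 1.0
        return cls(
            id=[c.id for c in cells], x=[c.x for c in cells],
            z=[c.z for c in cells], angle=[c.angle for c in cells],
            length=[c.length for c in cells],
            div_len=[c.div_len if c.div_len is not None else l_div
                     for c in cells],
            radius=radius,
            lambda_inst=[c.lambda_inst for c in cells],
            tau_aer=[c.tau_aer for c in cells],
            tau_ana=[c.tau_ana for c in cells],
            p_death=[c.p_death for c in cells],
            lineage=[c.lineage for c in cells])

    def to_cells(self) -> list[Cell]:
        return [Cell(int(self.id[i]), float(self.x[i]), float(self.z[i]),
                     float(self.angle[i]), float(self.length[i]), self.radius,
                     float(self.lambda_inst[i]), float(self.tau_aer[i]),
                     float(self.tau_ana[i]), float(self.p_death[i]),
                     int(self.lineage[i]), float(self.div_len[i]))
                for i in range(len(self))]

    def __len__(self) -> int:
        return self.x.size

    # -- geometry ---------------------------------------------------------
    @property
    def axis(self) -> tuple[np.ndarray, np.ndarray]:
        return np.cos(self.angle), np.sin(self.angle)

    def endpoints(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Cylinder-axis endpoints (x1, z1, x2, z2); caps extend r0 beyond."""
        ux, uz = self.axis
        h = self.length / 2.0
        return (self.x - h * ux, self.z - h * uz,
                self.x + h * ux, self.z + h * uz)

    # -- growth and division ---------------------------------------------
    def grow(self, rates: np.ndarray, dt: float) -> None:
        """Exponential elongation: length *= exp(rate*dt) per cell."""
        if dt < 0:
            raise ValueError("dt must be nonnegative")
        self.length *= np.exp(np.asarray(rates) * dt)
        self.lambda_inst = np.asarray(rates, dtype=float).copy()

    def divide(self, p, rng) -> int:
        """Split every cell whose cylinder length exceeds its threshold.

        The rod splits at its midpoint into daughters of cylinder length
        l/2 each, conserving rod material exactly (so that a population
        under constant growth rate lambda multiplies at exactly
        exp(lambda*t)); the two new caps introduce a small overlap at the
        split point which the contact mechanics relaxes.  Daughters
        inherit the parent's angle up to a small random kick, carry fresh
        ids and new division thresholds l_div*(1 + uniform noise).
        Returns the number of divisions.
        """
        idx = np.flatnonzero(self.length > self.div_len)
        if idx.size == 0:
            return 0
        r0 = self.radius
        ux, uz = np.cos(self.angle[idx]), np.sin(self.angle[idx])
        l_par = self.length[idx]
        l_dau = l_par / 2.0
        # daughters keep a slight cap overlap (0.2*r0) that the contact
        # mechanics relaxes without a large force spike
        off = l_par / 4.0 + 0.9 * r0
        kick = p.angle_kick * rng.uniform(-1, 1, size=(2, idx.size))
        noise = p.l_div * (1.0 + p.div_noise * rng.uniform(-1, 1, size=(2, idx.size)))

        n_new = idx.size
        ids_a = self.next_id + np.arange(n_new)
        ids_b = self.next_id + n_new + np.arange(n_new)
        parent = self.id[idx].copy()

        # first daughter overwrites the parent slot, second is appended
        self.x[idx] -= off * ux
        self.z[idx] -= off * uz
        xb = self.x[idx] + 2 * off * ux
        zb = self.z[idx] + 2 * off * uz
        self.length[idx] = l_dau
        ang = self.angle[idx]
        self.angle[idx] = _wrap_angle(ang + kick[0])
        self.div_len[idx] = noise[0]
        self.id[idx] = ids_a
        self.lineage[idx] = parent

        self.id = np.concatenate([self.id, ids_b])
        self.x = np.concatenate([self.x, xb])
        self.z = np.concatenate([self.z, zb])
        self.angle = np.concatenate([self.angle, _wrap_angle(ang + kick[1])])
        self.length = np.concatenate([self.length, l_dau])
        self.div_len = np.concatenate([self.div_len, noise[1]])
        for name in ("lambda_inst", "tau_aer", "tau_ana", "p_death"):
            v = getattr(self, name)
            setattr(self, name, np.concatenate([v, v[idx]]))
        self.lineage = np.concatenate([self.lineage, parent])
        self.next_id += 2 * n_new
        return n_new

    # -- I/O --------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({k: getattr(self, k) for k in _FIELDS})

    def to_csv(self, path) -> None:
        """Snapshot cell table: positions in um, 6 significant digits."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap rod angles into [-pi/2, pi/2] (nematic symmetry)."""
    a = np.asarray(a, dtype=float)
    return (a + np.pi / 2) % np.pi - np.pi / 2


def elongate_and_divide(cell: Cell, lam: float, dt: float, rng,
                        p) -> list[Cell]:
    """Grow one cell for dt hours at rate lam; divide if past threshold.

    Length is multiplied by exp(lam*dt).  If the cylinder length then
    exceeds the cell's division threshold (drawn at birth as
    l_div*(1 + uniform noise)), the rod splits at its midpoint into two
    daughters with conserved pole-to-pole material (see
    :meth:`CellPopulation.divide`); otherwise the updated single cell is
    returned.
    """
    if dt < 0 or lam < 0:
        raise ValueError("dt and lambda must be nonnegative")
    pop = CellPopulation.from_cells([cell], p)
    pop.grow(np.array([lam]), dt)
    pop.divide(p, rng)
    return pop.to_cells()
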