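"""Masks, the diffusion solver and the coupled metabolite step."""

import numpy as np
import pytest

from colonysim import ParameterSet
from colonysim.cells import CellPopulation
from colonysim.grid import (AGAR, AIR, COLONY, DomainMasks, Grid,
                            MetaboliteFields, build_masks, metabolite_step,
                            sample_bilinear, steady_solve, transient_solve)
from colonysim.metabolism import SourceTerms


def small_params(**kw):
    base = dict(domain_width=120.0, agar_depth=60.0, air_height=30.0,
                h_grid=5.0)
    base.update(kw)
    return ParameterSet().replace(**base)


def pop_of(rows, p):
    n = len(rows)
    return CellPopulation(id=np.arange(n), x=[r[0] for r in rows],
                          z=[r[1] for r in rows], angle=[r[2] for r in rows],
                          length=[r[3] for r in rows],
                          div_len=np.full(n, 1e9), radius=p.r0)


class TestBuildMasks:
    def test_no_cells_empty_colony(self):
        p = small_params()
        grid = Grid.from_params(p)
        masks = build_masks(CellPopulation(id=[], x=[], z=[], angle=[],
                                           length=[], div_len=[]), grid, p)
        assert not masks.colony.any()
        assert masks.gamma12().shape[0] == 0
        # the whole agar surface faces air
        assert masks.gamma02().sum() == grid.nx
        assert masks.rho.sum() == 0

    def test_single_resting_cell(self):
        p = small_params()
        grid = Grid.from_params(p)
        pop = pop_of([(0.0, p.r0, 0.0, 3.0)], p)
        masks = build_masks(pop, grid, p)
        iz0 = grid.iz_surface
        assert masks.colony.any()
        # colony occupies only the first row above the surface
        assert set(np.nonzero(masks.colony)[0]) == {iz0}
        # the agar-colony interface sits directly beneath the cell
        pairs = masks.gamma12()
        assert len(pairs) > 0
        assert all(a[0] == iz0 - 1 and c[0] == iz0 for a, c in pairs)
        assert np.all(masks.rho[masks.colony] > 0)

    def test_dense_block_mask_has_no_holes(self):
        p = small_params()
        grid = Grid.from_params(p)
        rows = [(x, z, 0.0, 3.0)
                for x in np.arange(-20, 21, 4.0)
                for z in (p.r0, 3 * p.r0, 5 * p.r0, 7 * p.r0, 9 * p.r0,
                          11 * p.r0, 13 * p.r0, 15 * p.r0)]
        masks = build_masks(pop_of(rows, p), grid, p)
        col = masks.colony
        # every column of the block spans contiguous rows (closing fills gaps)
        for ix in range(grid.nx):
            zs = np.nonzero(col[:, ix])[0]
            if zs.size:
                assert np.array_equal(zs, np.arange(zs.min(), zs.max() + 1))

    def test_cell_outside_domain_rejected(self):
        p = small_params()
        grid = Grid.from_params(p)
        pop = pop_of([(1000.0, p.r0, 0.0, 3.0)], p)
        with pytest.raises(ValueError, match="outside"):
            build_masks(pop, grid, p)


class TestSteadySolver:
    def test_1d_column_matches_parabolic_closed_form(self):
        """Constant uptake slab with a fixed base concentration.

        Steady balance D C'' = rho*Q with C(0) = C0 and no flux at z = L
        has the closed form C(z) = C0 - (rho*Q/D)*(L z - z^2/2).
        """
        h = 1.0
        n = 40
        L = n * h
        D = 200.0
        rhoQ = 0.05
        C0 = 10.0
        active = np.zeros((n + 1, 3), dtype=bool)
        active[1:, :] = True          # the slab
        ambient = np.zeros_like(active)
        ambient[0, :] = True          # Dirichlet reservoir below
        Df = np.full(active.shape, D)
        sink = np.zeros(active.shape)
        source = np.full(active.shape, -rhoQ)  # constant uptake
        C = steady_solve(active, Df, h, sink, source, ambient, C0)
        z = (np.arange(n) + 0.5) * h
        exact = C0 - (rhoQ / D) * (L * z - z ** 2 / 2)
        rel_err = np.abs(C[1:, 1] - exact) / C0
        assert rel_err.max() < 0.01

    def test_uniform_field_is_steady_without_sources(self):
        active = np.ones((8, 8), dtype=bool)
        ambient = np.zeros_like(active)
        ambient[0, :] = True
        D = np.full(active.shape, 50.0)
        C = steady_solve(active, D, 2.0, np.zeros_like(D), np.zeros_like(D),
                         ambient, 3.3)
        assert np.allclose(C[active], 3.3, atol=1e-10)


class TestTransientSolver:
    def test_mass_conserved_in_closed_domain(self):
        rng = np.random.default_rng(3)
        active = np.ones((20, 30), dtype=bool)
        D = np.full(active.shape, 123.0)
        C0 = rng.uniform(0.5, 2.0, active.shape)
        C = C0.copy()
        for _ in range(5):
            C = transient_solve(C, active, D, 2.5, 0.05,
                                np.zeros_like(D), np.zeros_like(D))
        assert abs(C.sum() - C0.sum()) / C0.sum() < 1e-10

    def test_heterogeneous_coefficients_conserve_mass(self):
        active = np.ones((16, 16), dtype=bool)
        D = np.broadcast_to(np.where(np.arange(16) < 8, 10.0, 500.0)[:, None],
                            (16, 16)).copy()
        C0 = np.broadcast_to(np.where(np.arange(16) < 8, 4.0, 0.0)[:, None],
                             (16, 16)).copy()
        C = transient_solve(C0, active, D, 1.0, 0.1,
                            np.zeros(D.shape), np.zeros(D.shape))
        assert abs(C.sum() - C0.sum()) / C0.sum() < 1e-10
        assert C.min() >= 0


class TestMetaboliteStep:
    def test_uniform_no_source_unchanged(self):
        p = small_params()
        grid = Grid.from_params(p)
        labels = np.full(grid.shape(), AIR, dtype=np.int8)
        labels[: grid.iz_surface] = AGAR
        masks = DomainMasks(labels, np.zeros(grid.shape()), grid)
        fields = MetaboliteFields.initial(grid, p)
        zero = SourceTerms(Q_g=0.0, Q_o=0.0, Q_a=0.0, P_a=0.0,
                           Q_g_maint=0.0, Q_o_maint=0.0, Q_a_maint=0.0,
                           P_a_maint=0.0, Qg_aer=0.0, Qg_ana=0.0,
                           Qa_growth=0.0)
        new, _, _ = metabolite_step(fields, masks, p, dt=0.05, sources=zero)
        np.testing.assert_allclose(new.C_g, fields.C_g, atol=1e-9)
        np.testing.assert_allclose(new.C_a, fields.C_a, atol=1e-9)

    def test_glucose_mass_conserved_without_uptake(self):
        p = small_params()
        grid = Grid.from_params(p)
        pop = pop_of([(0.0, p.r0, 0.0, 3.0), (4.0, p.r0, 0.0, 3.0)], p)
        masks = build_masks(pop, grid, p)
        fields = MetaboliteFields.initial(grid, p)
        zero = SourceTerms(Q_g=0.0, Q_o=0.0, Q_a=0.0, P_a=0.0,
                           Q_g_maint=0.0, Q_o_maint=0.0, Q_a_maint=0.0,
                           P_a_maint=0.0, Qg_aer=0.0, Qg_ana=0.0,
                           Qa_growth=0.0)
        m0 = fields.C_g[masks.active].sum()
        f = fields
        for _ in range(4):
            f, _, _ = metabolite_step(f, masks, p, dt=0.05, sources=zero)
        assert abs(f.C_g[masks.active].sum() - m0) / m0 < 1e-10

    def test_concentrations_stay_nonnegative_under_strong_uptake(self):
        p = small_params()
        grid = Grid.from_params(p)
        pop = pop_of([(0.0, p.r0, 0.0, 3.0)], p)
        masks = build_masks(pop, grid, p)
        fields = MetaboliteFields.initial(grid, p)
        f = fields
        for _ in range(6):
            f, _, _ = metabolite_step(f, masks, p, dt=0.1)
            assert f.C_g.min() >= 0
            assert f.C_o.min() >= 0
            assert f.C_a.min() >= 0

    def test_oxygen_depletes_inside_thick_colony(self):
        p = small_params(domain_width=200.0)
        grid = Grid.from_params(p)
        rows = [(x, z, 0.0, 3.0)
                for x in np.arange(-40, 41, 4.0)
                for z in np.arange(0.5, 26.0, 1.0)]
        masks = build_masks(pop_of(rows, p), grid, p)
        fields = MetaboliteFields.initial(grid, p)
        f, _, _ = metabolite_step(fields, masks, p, dt=0.05)
        col = masks.colony
        assert f.C_o[col].min() < p.K_o      # anoxic interior
        assert f.C_o[col].max() > p.K_o      # aerated surface


class TestSampling:
    def test_bilinear_reproduces_linear_field(self):
        p = small_params()
        grid = Grid.from_params(p)
        zz, xx = np.meshgrid(grid.z, grid.x, indexing="ij")
        field = 2.0 * xx + 0.5 * zz + 1.0
        x = np.array([-20.0, 0.0, 13.0])
        z = np.array([-30.0, 5.0, 12.0])
        np.testing.assert_allclose(sample_bilinear(field, grid, x, z),
                                   2.0 * x + 0.5 * z + 1.0, rtol=1e-12)
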