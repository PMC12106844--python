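"""Colony morphometry: profiles, volume, monolayer width, kinetics."""

import math

import numpy as np
import pandas as pd
import pytest

from colonysim import ParameterSet
from colonysim.cells import Cell, CellPopulation
from colonysim.driver import generate_fixtures
from colonysim.grid import AGAR, AIR, COLONY, DomainMasks, Grid
from colonysim.metabolism import SourceTerms
from colonysim.observables import (CrossSectionProfile, KineticsSeries,
                                   expansion_kinetics, flux_partition,
                                   growing_fraction, monolayer_width,
                                   monolayer_width_from_intensity,
                                   profile_from_cells, radius_height,
                                   volume_from_profile)


def hcell(x, z, length=4.0, angle=0.0, lam=0.0, i=0):
    return Cell(i, x, z, angle, length, 0.5, lambda_inst=lam)


class TestProfile:
    def test_single_horizontal_cell_geometry(self):
        prof = profile_from_cells([hcell(0.0, 0.5, length=6.0)], dz=5.0)
        assert prof.r.size == 1
        assert prof.r[0] == pytest.approx(6.0 / 2 + 0.5)

    def test_reflection_symmetry(self):
        cells = [hcell(7.0, 0.5, i=0), hcell(-3.0, 2.5, i=1, angle=0.4)]
        mirror = [hcell(-7.0, 0.5, i=0), hcell(3.0, 2.5, i=1, angle=-0.4)]
        p1 = profile_from_cells(cells, dz=2.0)
        p2 = profile_from_cells(mirror, dz=2.0)
        np.testing.assert_allclose(p1.r, p2.r)

    def test_stacked_cells_two_bins(self):
        cells = [hcell(0.0, 0.5, i=0), hcell(0.0, 3.0, i=1)]
        prof = profile_from_cells(cells, dz=2.0)
        assert (prof.r > 0).sum() == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            profile_from_cells([], dz=5.0)


class TestRadiusHeight:
    def test_rectangle_profile(self):
        prof = CrossSectionProfile(z=np.arange(0, 40, 5.0),
                                   r=np.full(8, 100.0), dz=5.0)
        assert radius_height(prof) == (100.0, 40.0)

    def test_dome_radius_at_base(self):
        r = np.array([50.0, 40.0, 25.0, 10.0])
        prof = CrossSectionProfile(z=np.arange(4) * 5.0, r=r, dz=5.0)
        radius, height = radius_height(prof)
        assert radius == 50.0 and height == 20.0

    def test_single_bin_height_is_dz(self):
        prof = CrossSectionProfile(z=np.array([0.0]), r=np.array([3.0]),
                                   dz=5.0)
        assert radius_height(prof)[1] == 5.0


class TestVolume:
    def test_one_disk(self):
        prof = CrossSectionProfile(z=np.array([0.0]), r=np.array([10.0]),
                                   dz=5.0)
        assert volume_from_profile(prof) == pytest.approx(500 * math.pi)

    def test_cylinder(self):
        prof = CrossSectionProfile(z=np.arange(4) * 5.0, r=np.full(4, 10.0),
                                   dz=5.0)
        assert volume_from_profile(prof) == pytest.approx(2000 * math.pi)

    def test_linear_cone_direct_sum(self):
        prof = CrossSectionProfile(z=np.arange(5) * 1.0,
                                   r=np.array([10.0, 8, 6, 4, 2]), dz=1.0)
        assert volume_from_profile(prof) == pytest.approx(220 * math.pi)

    def test_scaling_in_dz_and_r(self):
        r = np.array([10.0, 8, 6])
        p1 = CrossSectionProfile(z=np.arange(3) * 2.0, r=r, dz=2.0)
        p2 = CrossSectionProfile(z=np.arange(3) * 4.0, r=r, dz=4.0)
        p3 = CrossSectionProfile(z=np.arange(3) * 2.0, r=2 * r, dz=2.0)
        assert volume_from_profile(p2) == pytest.approx(2 * volume_from_profile(p1))
        assert volume_from_profile(p3) == pytest.approx(4 * volume_from_profile(p1))

    def test_dome_fixture_closed_form(self):
        fx = generate_fixtures("dome-profile", {"R": 80.0, "H": 40.0,
                                                "dz": 5.0})
        assert volume_from_profile(fx["profile"]) == pytest.approx(
            fx["volume_truth"], rel=1e-12)


class TestMonolayerWidth:
    def test_all_monolayer_half_footprint(self):
        fx = generate_fixtures("monolayer-colony", {"n_cells": 20})
        assert monolayer_width(fx["pop"]) == pytest.approx(
            fx["monolayer_width_truth"], abs=2.5)

    def test_stacked_block_with_skirt(self):
        fx = generate_fixtures("stacked-block",
                               {"half_core": 40.0, "skirt": 25.0})
        assert monolayer_width(fx["pop"]) == pytest.approx(
            fx["monolayer_width_truth"], abs=3.0)

    def test_interior_cells_do_not_change_width(self):
        fx = generate_fixtures("stacked-block",
                               {"half_core": 40.0, "skirt": 25.0})
        w0 = monolayer_width(fx["pop"])
        cells = fx["pop"].to_cells()
        extra = [Cell(1000 + i, 0.0 + 3 * i, 4.5, 0.0, 4.0, 0.5)
                 for i in range(3)]  # extra interior cells, fourth layer
        assert monolayer_width(cells + extra) == pytest.approx(w0)

    def test_intensity_mode_step_trace(self):
        dx = 1.0
        trace = np.concatenate([np.ones(20), np.full(30, 3.0)])
        assert monolayer_width_from_intensity(trace, dx, 1.5) == 20.0


class TestFluxPartition:
    def _masks(self):
        p = ParameterSet().replace(domain_width=40.0, agar_depth=20.0,
                                   air_height=10.0, h_grid=5.0)
        grid = Grid.from_params(p)
        labels = np.full(grid.shape(), AIR, dtype=np.int8)
        labels[: grid.iz_surface] = AGAR
        labels[grid.iz_surface, 3:5] = COLONY
        rho = np.zeros(grid.shape())
        rho[labels == COLONY] = 100.0
        return DomainMasks(labels, rho, grid)

    def _src(self, **kw):
        base = dict(Q_g=0.0, Q_o=0.0, Q_a=0.0, P_a=0.0, Q_g_maint=0.0,
                    Q_o_maint=0.0, Q_a_maint=0.0, P_a_maint=0.0,
                    Qg_aer=0.0, Qg_ana=0.0, Qa_growth=0.0, Qg_maint_ana=0.0)
        base.update(kw)
        return SourceTerms(**base)

    def test_fully_anaerobic(self):
        shares = flux_partition(self._src(Qg_ana=5.0), self._masks())
        assert shares.glucose_anaerobic == pytest.approx(1.0)
        assert shares.glucose_aerobic == pytest.approx(0.0)

    def test_no_acetate_flux_flagged_undefined(self):
        shares = flux_partition(self._src(Qg_aer=1.0), self._masks())
        assert not shares.acetate_defined
        assert math.isnan(shares.acetate_growth)

    def test_equal_split_is_half(self):
        shares = flux_partition(self._src(Qg_aer=2.0, Qg_ana=2.0,
                                          Qa_growth=1.0, Q_a_maint=1.0),
                                self._masks())
        assert shares.glucose_aerobic == pytest.approx(0.5)
        assert shares.acetate_growth == pytest.approx(0.5)
        assert shares.acetate_growth + shares.acetate_maintenance == \
            pytest.approx(1.0)


class TestGrowingFraction:
    @pytest.mark.parametrize("rates, expected", [
        ([0.0, 0.0], 0.0),
        ([1.0, 1.0, 1.0], 1.0),
        ([0.005, 0.02, 0.5], 2 / 3),
    ])
    def test_strict_threshold(self, rates, expected):
        cells = [hcell(i * 6.0, 0.5, lam=r, i=i) for i, r in enumerate(rates)]
        assert growing_fraction(cells, 0.01) == pytest.approx(expected)

    def test_threshold_is_strict_inequality(self):
        cells = [hcell(0, 0.5, lam=0.01)]
        assert growing_fraction(cells, 0.01) == 0.0

    def test_partition_sums_to_one(self, rng):
        cells = [hcell(i * 6.0, 0.5, lam=r, i=i)
                 for i, r in enumerate(rng.uniform(0, 0.1, 50))]
        g = growing_fraction(cells, 0.01)
        nong = 1.0 - g
        assert g + nong == 1.0


class TestExpansionKinetics:
    def _series(self, t, radius, height):
        ks = KineticsSeries()
        for ti, ri, hi in zip(t, radius, height):
            ks.append({"time": ti, "radius": ri, "height": hi,
                       "volume": 0.0, "n_cells": 0, "growing_fraction": 0.0,
                       "monolayer_width": 0.0,
                       "glucose_aerobic_share": 0.0,
                       "glucose_anaerobic_share": 0.0,
                       "acetate_growth_share": 0.0,
                       "acetate_maintenance_share": 0.0,
                       "expected_dead": 0.0, "min_C_o_colony": 0.0,
                       "min_C_g_colony": 0.0})
        return ks

    def test_linear_radius_exact_recovery(self):
        t = np.arange(10.0)
        ks = self._series(t, 3.0 * t + 7.0, t)
        fit = expansion_kinetics(ks, (0.0, 9.0))
        assert fit.radial_speed == pytest.approx(3.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_saturating_height_flags_slowdown(self):
        t = np.linspace(0, 8, 5)
        height = 30 * (1 - np.exp(-t / 3.0))
        ks = self._series(t, t, height)
        assert expansion_kinetics(ks, (0.0, 8.0)).vertical_slowdown

    def test_constant_radius_zero_slope(self):
        t = np.arange(6.0)
        ks = self._series(t, np.full(6, 5.0), t)
        assert expansion_kinetics(ks, (0.0, 5.0)).radial_speed == 0.0

    def test_too_few_samples_rejected(self):
        ks = self._series([0, 1, 2], [1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError):
            expansion_kinetics(ks, (0.0, 2.0))
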