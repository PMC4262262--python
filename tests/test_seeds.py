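"""Seed rain: mast years, dispersal kernels, inhibition, bank, germination."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from woodsim.grid import Cell, LandscapeGrid, VegType, classify_all
from woodsim.agents import WoodyAgent
from woodsim.seeds import (
    MAST_CATEGORIES,
    build_kernel,
    disperse,
    disperse_production,
    germinate,
    grass_inhibition,
    mast_fraction,
    seedbank_decay,
    seedbank_input,
)


def _mixture_pdf(x, ed, md, k):
    """Independent statement of the double-exponential distance law."""
    lam1 = -math.log(1 - k) / ed
    lam2 = -math.log(1 - k) / md
    inner = k * lam1 * math.exp(-lam1 * x) / (1 - math.exp(-lam1 * ed)) if x <= ed else 0.0
    outer = (
        (1 - k) * lam2 * math.exp(-lam2 * x) / (math.exp(-lam2 * ed) - math.exp(-lam2 * md))
        if ed < x <= md
        else 0.0
    )
    return inner + outer


class TestMastFraction:
    def test_draws_stay_in_the_published_bands(self, rng):
        draws = np.array([mast_fraction(rng) for _ in range(20_000)])
        assert ((draws == 0.0) | ((draws >= 0.10) & (draws <= 1.00))).all()

    def test_four_categories_equally_likely_by_default(self, rng):
        draws = np.array([mast_fraction(rng) for _ in range(40_000)])
        edges = [(0.0, 0.0), (0.10, 0.40), (0.40, 0.70), (0.70, 1.00)]
        for lo, hi in edges:
            if lo == hi:
                freq = (draws == 0.0).mean()
            else:
                freq = ((draws >= lo) & (draws < hi + 1e-12)).mean()
            assert freq == pytest.approx(0.25, abs=0.015)

    def test_no_seed_year_is_exactly_zero(self, rng):
        draws = [mast_fraction(rng, probabilities=(1.0, 0.0, 0.0, 0.0)) for _ in range(10)]
        assert draws == [0.0] * 10


class TestDispersalKernel:
    @pytest.mark.parametrize("name", ["birch", "broom", "beech", "spruce", "oak"])
    def test_weights_sum_to_one(self, woody, name):
        k = build_kernel(woody[name])
        assert k.total.sum() == pytest.approx(1.0, abs=1e-9)
        assert (k.total >= 0).all()

    @pytest.mark.parametrize("name", ["birch", "broom", "beech", "spruce", "oak"])
    def test_ed_quantile_matches_numeric_integration_oracle(self, woody, name):
        sp = woody[name]
        k = build_kernel(sp)
        oracle, _ = quad(
            _mixture_pdf, 0, sp.ed, args=(sp.ed, sp.md, sp.p_ed), limit=200
        )
        assert oracle == pytest.approx(sp.p_ed, abs=1e-6)  # oracle sanity
        assert k.cumulative_within(sp.ed) == pytest.approx(oracle, abs=0.05)

    def test_birch_mass_within_effective_distance(self, woody):
        k = build_kernel(woody["birch"])
        assert k.cumulative_within(200.0) == pytest.approx(0.95, abs=0.02)

    def test_no_weight_beyond_maximum_distance(self, woody):
        k = build_kernel(woody["oak"])
        for (dc, dr), w in k.weights.items():
            if 10.0 * math.hypot(dc, dr) > 200.0:
                assert w == 0.0

    def test_weight_non_increasing_with_distance(self, woody):
        k = build_kernel(woody["spruce"])
        items = sorted(
            ((10.0 * math.hypot(dc, dr), w) for (dc, dr), w in k.weights.items())
        )
        for (d1, w1), (d2, w2) in zip(items, items[1:]):
            if d2 > d1 + 1e-9:
                assert w2 <= w1 + 1e-12

    def test_ed_above_md_rejected(self, woody):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(woody["oak"], ed=300.0)


class TestDisperse:
    def test_zero_seeds_give_zero_increments(self, woody):
        grid = LandscapeGrid(n_cols=5, n_rows=5)
        inc = disperse(grid, grid[(2, 2)], 0.0, build_kernel(woody["oak"]))
        assert inc.sum() == 0.0

    def test_ungated_mass_conserved_when_md_fits_in_grid(self, woody):
        # oak MD = 200 m -> radius 20 cells; a 41x41 grid holds everything
        grid = LandscapeGrid(n_cols=41, n_rows=41)
        inc = disperse_production(grid, _point(grid, 1000.0), build_kernel(woody["oak"]), gated=False)
        assert inc.sum() == pytest.approx(1000.0, rel=1e-9)

    def test_gated_mass_discarded_in_empty_grassland(self, woody):
        # beech seeds beyond ED only land where a bush or tree stands
        grid = LandscapeGrid(n_cols=41, n_rows=41)
        classify_all(grid)
        k = build_kernel(woody["beech"])
        inc = disperse_production(grid, _point(grid, 1000.0), k, gated=True)
        dist = _distance_field(grid) * 10.0
        assert inc[dist > 30.0].sum() == 0.0
        # the within-ED share still arrives
        assert inc.sum() == pytest.approx(1000.0 * 0.99, abs=15.0)

    def test_gated_mass_reaches_cells_with_trees_outside_forest(self, woody):
        grid = LandscapeGrid(n_cols=41, n_rows=41)
        target = grid[(20, 30)]  # 100 m from the source: beyond beech ED
        target.agents.append(WoodyAgent(woody["birch"], height=2.0))
        classify_all(grid)
        assert target.veg_type is not VegType.FOREST
        k = build_kernel(woody["beech"])
        inc = disperse_production(grid, _point(grid, 1_000_000.0), k, gated=True)
        assert inc[20, 30] > 0.0


def _point(grid, n):
    arr = np.zeros((grid.n_rows, grid.n_cols))
    arr[grid.n_rows // 2, grid.n_cols // 2] = n
    return arr


def _distance_field(grid):
    r0, c0 = grid.n_rows // 2, grid.n_cols // 2
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    return np.hypot(rr - r0, cc - c0)


class TestGrassInhibition:
    def test_no_grass_no_inhibition(self, woody, herbs_table):
        cell = Cell(col=0, row=0)
        assert grass_inhibition(cell, woody["broom"], herbs_table) == 0.0

    def test_half_inhibition_at_i50(self, woody, herbs_table):
        cell = Cell(col=0, row=0)
        cell.herb_cover["cocksfoot"] = 26.1  # broom I50
        assert grass_inhibition(cell, woody["broom"], herbs_table) == pytest.approx(0.5)

    def test_management_reduces_total_by_thirty_percent(self, woody, herbs_table):
        cell = Cell(col=0, row=0)
        cell.herb_cover["cocksfoot"] = 26.1
        cell.mown = True
        assert grass_inhibition(cell, woody["broom"], herbs_table) == pytest.approx(0.35)

    def test_monotone_in_every_grass_cover(self, woody, herbs_table, rng):
        sp = woody["birch"]
        prev = -1.0
        for cover in np.linspace(0.0, 90.0, 40):
            cell = Cell(col=0, row=0)
            cell.herb_cover["red_fescue"] = float(cover)
            cell.herb_cover["tall_oat"] = 15.0
            t = grass_inhibition(cell, sp, herbs_table)
            assert t >= prev - 1e-12
            assert 0.0 <= t <= 1.0
            prev = t

    def test_thorny_shrubs_do_not_inhibit(self, woody, herbs_table):
        cell = Cell(col=0, row=0)
        cell.herb_cover["bramble"] = 80.0
        assert grass_inhibition(cell, woody["birch"], herbs_table) == 0.0


class TestSeedBank:
    def test_predator_loss_arithmetic(self, woody):
        cell = Cell(col=0, row=0)
        added = seedbank_input(cell, 1000.0, woody["oak"], inhibition=0.0)
        assert added == pytest.approx(200.0)

    def test_full_inhibition_blocks_everything(self, woody):
        cell = Cell(col=0, row=0)
        assert seedbank_input(cell, 1000.0, woody["oak"], inhibition=1.0) == 0.0

    def test_combined_loss_and_inhibition(self, woody):
        cell = Cell(col=0, row=0)
        assert seedbank_input(cell, 1000.0, woody["oak"], inhibition=0.5) == pytest.approx(100.0)

    def test_decay_is_exponential(self, woody):
        cell = Cell(col=0, row=0)
        cell.seed_bank["oak"] = 1000.0
        assert seedbank_decay(cell, woody["oak"]) == pytest.approx(444.9, abs=0.05)
        cell.seed_bank["broom"] = 1000.0
        assert seedbank_decay(cell, woody["broom"]) == pytest.approx(938.9, abs=0.05)

    def test_zero_decay_rate_preserves_bank(self, woody):
        import dataclasses

        sp = dataclasses.replace(woody["oak"], decay_rate=0.0)
        cell = Cell(col=0, row=0)
        cell.seed_bank["oak"] = 123.0
        assert seedbank_decay(cell, sp) == 123.0

    def test_positive_banks_strictly_shrink_without_input(self, woody):
        cell = Cell(col=0, row=0)
        for name in woody:
            cell.seed_bank[name] = 50.0
        for name, sp in woody.items():
            assert 0.0 < seedbank_decay(cell, sp) < 50.0


class TestGermination:
    def test_cap_and_surplus_bookkeeping(self, woody, rng):
        cell = Cell(col=0, row=0)
        cell.seed_bank["birch"] = 1000.0  # Germ 0.1 -> 100 candidates
        new = germinate(cell, woody, rng)
        assert len(new) == 35
        assert cell.surplus["birch"] == 65
        # bank drawn down by candidates / Germ
        assert cell.seed_bank["birch"] == pytest.approx(1000.0 - 100 / 0.1)

    def test_no_space_no_seedlings_all_surplus(self, woody, rng):
        cell = Cell(col=0, row=0)
        blocker = WoodyAgent(woody["spruce"], height=10.0)
        blocker.cover = 100.0
        cell.agents.append(blocker)
        cell.seed_bank["birch"] = 1000.0
        new = germinate(cell, woody, rng)
        assert new == []
        assert cell.surplus["birch"] == 100

    def test_empty_bank_yields_nothing(self, woody, rng):
        cell = Cell(col=0, row=0)
        assert germinate(cell, woody, rng) == []

    def test_broom_cap_independent_of_tree_cap(self, woody, rng):
        cell = Cell(col=0, row=0)
        cell.seed_bank["birch"] = 1000.0
        cell.seed_bank["broom"] = 100.0  # Germ 0.8 -> 80 candidates
        new = germinate(cell, woody, rng)
        names = [a.species.name for a in new]
        assert names.count("birch") == 35
        assert names.count("broom") == 35
        assert cell.surplus["broom"] == 45

    def test_proportional_allocation_under_the_tree_cap(self, woody, rng):
        cell = Cell(col=0, row=0)
        cell.seed_bank["birch"] = 300.0   # 30 candidates
        cell.seed_bank["spruce"] = 40.0   # 30 candidates
        new = germinate(cell, woody, rng)
        names = [a.species.name for a in new]
        # 60 candidates for 35 places: 17.5 each -> 18/17 by remainder order
        assert len(new) == 35
        assert abs(names.count("birch") - names.count("spruce")) <= 1

    def test_seedlings_start_at_initial_height(self, woody, rng):
        cell = Cell(col=0, row=0)
        cell.seed_bank["oak"] = 10.0
        new = germinate(cell, woody, rng)
        assert all(a.height == 0.05 and a.age == 0.0 for a in new)
        assert all(0.9 * 800 <= a.a_max_ind <= 1.1 * 800 for a in new)
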