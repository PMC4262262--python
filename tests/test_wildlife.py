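"""Red-deer browsing budget and wild-boar disturbance."""

import numpy as np
import pytest

from woodsim.agents import WoodyAgent
from woodsim.grid import Cell, LandscapeGrid, VegType, classify_all
from woodsim.scenarios import make_grassland
from woodsim.wildlife import (
    BrowserParams,
    annual_demand_per_deer,
    apply_browsing_mortality,
    available_browse,
    bite_biomass,
    boar_disturb,
    browse_cell,
    nurse_factor,
    standard_deer_weight,
)


class TestDemand:
    def test_standard_deer_is_the_herd_mean(self):
        herd = ((5, 105.0), (10, 70.0), (20, 42.5))
        assert standard_deer_weight(herd) == pytest.approx(59.2857, abs=1e-4)

    def test_single_class_herd(self):
        assert standard_deer_weight(((1, 100.0),)) == 100.0
        assert standard_deer_weight(((1, 0.0), (1, 100.0))) == 50.0

    def test_empty_herd_rejected(self):
        with pytest.raises(ValueError):
            standard_deer_weight(())

    def test_published_annual_demand(self):
        assert annual_demand_per_deer(BrowserParams()) == pytest.approx(157.46, abs=0.005)

    def test_no_woody_diet_no_demand(self):
        assert annual_demand_per_deer(BrowserParams(frw=0.0)) == 0.0

    def test_demand_linear_in_deer_mass(self):
        d1 = annual_demand_per_deer(BrowserParams(herd=((1, 50.0),)))
        d2 = annual_demand_per_deer(BrowserParams(herd=((1, 100.0),)))
        assert d2 == pytest.approx(2.0 * d1)


class TestNurseFactor:
    def test_no_shrubs_no_protection(self):
        assert nurse_factor(0.0, 0.0) == 1.0

    def test_blackthorn_protects_more_than_bramble(self):
        assert nurse_factor(50.0, 0.0) < nurse_factor(0.0, 50.0)

    def test_dense_thickets_exclude_browsing(self):
        assert nurse_factor(100.0, 100.0) < 0.07
        assert nurse_factor(1000.0, 1000.0) < 1e-4

    def test_monotone_non_increasing_in_each_cover(self):
        covers = np.linspace(0.0, 100.0, 30)
        fp = [nurse_factor(c, 10.0) for c in covers]
        fr = [nurse_factor(10.0, c) for c in covers]
        assert all(a >= b - 1e-12 for a, b in zip(fp, fp[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(fr, fr[1:]))


class TestAvailableBrowse:
    def test_oak_bite_biomass(self, woody):
        assert bite_biomass(woody["oak"], 0.1) == pytest.approx(1.466e-4, abs=2e-7)

    def test_tall_trees_provide_no_forage(self, woody):
        assert available_browse(6.0, woody["birch"]) == 0.0

    def test_vanishes_with_height(self, woody):
        assert available_browse(1e-6, woody["birch"]) < 1e-6

    def test_non_decreasing_up_to_the_browsing_ceiling(self, woody):
        heights = np.linspace(0.05, 1.7, 25)
        ab = [available_browse(h, woody["birch"]) for h in heights]
        assert all(b >= a - 1e-12 for a, b in zip(ab, ab[1:]))
        # constant between ceiling and forage limit
        assert available_browse(3.0, woody["birch"]) == pytest.approx(ab[-1])

    def test_injected_supply_curve_is_used(self, woody):
        params = BrowserParams(supply=lambda h, sp, p: 0.5)
        assert available_browse(1.0, woody["birch"], params) == 0.5


class TestBrowseCell:
    def test_zero_density_is_a_no_op(self, woody):
        cell = Cell(col=0, row=0)
        cell.agents.append(WoodyAgent(woody["oak"], height=1.0))
        rec = browse_cell(cell, BrowserParams(), 0.0, woody)
        assert rec.demand == rec.consumed == 0.0
        assert not cell.agents[0].browsed

    def test_cell_demand_at_status_quo_density(self, woody):
        cell = Cell(col=0, row=0)
        cell.agents.append(WoodyAgent(woody["oak"], height=1.0))
        rec = browse_cell(cell, BrowserParams(), 22.0, woody)
        assert rec.demand == pytest.approx(22.0 * 157.46 / 1e4, abs=1e-4)

    def test_budget_identity_consumed_never_exceeds_demand(self, woody, rng):
        for _ in range(50):
            cell = Cell(col=0, row=0)
            for _ in range(int(rng.integers(0, 20))):
                name = str(rng.choice(["oak", "birch", "beech", "spruce"]))
                cell.agents.append(
                    WoodyAgent(woody[name], height=float(rng.uniform(0.05, 8.0)))
                )
            cell.surplus = {"birch": float(rng.integers(0, 300))}
            density = float(rng.uniform(0.0, 40.0))
            rec = browse_cell(cell, BrowserParams(), density, woody)
            assert rec.consumed <= rec.demand + 1e-12
            assert rec.consumed >= 0.0

    def test_preference_order_oak_before_spruce(self, woody):
        cell = Cell(col=0, row=0)
        spruce = [WoodyAgent(woody["spruce"], height=1.0) for _ in range(5)]
        oak = WoodyAgent(woody["oak"], height=1.0)
        cell.agents += spruce + [oak]
        # demand small enough that the oak alone can satisfy it
        params = BrowserParams()
        density = 0.1  # demand ~ 1.6e-3 kg < oak's available browse
        rec = browse_cell(cell, params, density, woody)
        assert oak.browsed
        assert not any(a.browsed for a in spruce)
        assert rec.consumed == pytest.approx(rec.demand)

    def test_tiny_trees_die_immediately_when_browsed(self, woody):
        cell = Cell(col=0, row=0)
        cell.agents += [WoodyAgent(woody["birch"], height=0.15) for _ in range(30)]
        rec = browse_cell(cell, BrowserParams(), 22.0, woody)
        assert rec.instant_deaths == rec.agents_browsed > 0
        assert len(cell.agents) == 30 - rec.instant_deaths

    def test_surplus_seedlings_absorb_demand_first(self, woody):
        cell = Cell(col=0, row=0)
        sapling = WoodyAgent(woody["birch"], height=0.5)
        cell.agents.append(sapling)
        cell.surplus = {"birch": 1e6}
        rec = browse_cell(cell, BrowserParams(), 22.0, woody)
        assert not sapling.browsed
        assert rec.surplus_eaten == pytest.approx(rec.demand)

    def test_broom_is_never_browsed(self, woody):
        cell = Cell(col=0, row=0)
        broom = WoodyAgent(woody["broom"], height=1.0)
        cell.agents.append(broom)
        rec = browse_cell(cell, BrowserParams(), 22.0, woody)
        assert not broom.browsed
        assert rec.consumed == 0.0

    def test_nurse_shrubs_never_increase_consumption(self, woody):
        def consumed(blackthorn):
            cell = Cell(col=0, row=0)
            cell.herb_cover["blackthorn"] = blackthorn
            cell.agents += [WoodyAgent(woody["birch"], height=0.5) for _ in range(40)]
            return browse_cell(cell, BrowserParams(), 22.0, woody).consumed

        assert consumed(50.0) <= consumed(0.0)


class TestBrowsingMortality:
    def test_flagged_saplings_die_at_the_species_rate(self, woody, rng):
        cell = Cell(col=0, row=0)
        for _ in range(2000):
            a = WoodyAgent(woody["birch"], height=0.5, browsed=True)
            cell.agents.append(a)
        dead = apply_browsing_mortality(cell, rng)
        assert len(dead) == pytest.approx(200, abs=60)  # Brow_mort = 0.1
        assert all(not a.browsed for a in cell.agents)

    def test_tall_browsed_trees_do_not_die(self, woody, rng):
        cell = Cell(col=0, row=0)
        cell.agents.append(WoodyAgent(woody["birch"], height=3.0, browsed=True))
        assert apply_browsing_mortality(cell, rng) == []

    def test_mortality_non_decreasing_in_deer_density(self, woody):
        # seeded replicate ensembles of identical seedling stands
        def deaths(density, seed):
            rng = np.random.default_rng(seed)
            total = 0
            for _ in range(30):
                cell = Cell(col=0, row=0)
                cell.agents += [
                    WoodyAgent(woody["birch"], height=0.15) for _ in range(20)
                ]
                rec = browse_cell(cell, BrowserParams(), density, woody)
                total += rec.instant_deaths
                total += len(apply_browsing_mortality(cell, rng))
            return total

        means = [
            np.mean([deaths(d, s) for s in range(3)]) for d in (0.0, 5.0, 10.0, 22.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


class TestBoarDisturbance:
    def test_meadow_rate_is_ten_percent(self):
        grid = make_grassland(100, 100, mown=True)
        disturbed = boar_disturb(grid, np.random.default_rng(7))
        frac = len(disturbed) / grid.n_cells
        # binomial 99% interval around 0.10 for n = 10,000
        assert 0.0923 <= frac <= 0.1077

    def test_forest_cells_are_never_ploughed(self, woody):
        grid = LandscapeGrid(n_cols=20, n_rows=20)
        for cell in grid.iter_cells():
            tree = WoodyAgent(woody["birch"], height=20.0)
            cell.agents.append(tree)
            cell.herb_cover["red_fescue"] = 20.0
        classify_all(grid)
        assert all(c.veg_type is VegType.FOREST for c in grid.iter_cells())
        assert boar_disturb(grid, np.random.default_rng(0)) == []

    def test_disturbed_cells_lose_45_percent_of_the_sward(self):
        grid = make_grassland(30, 30, grass_cover={"red_fescue": 40.0}, mown=True)
        disturbed = boar_disturb(grid, np.random.default_rng(1))
        assert disturbed  # ~90 of 900 cells
        for cell in disturbed:
            assert cell.herb_cover["red_fescue"] == pytest.approx(22.0)

    def test_fallow_rate_is_much_lower(self):
        fallow = make_grassland(100, 100, mown=False)
        disturbed = boar_disturb(fallow, np.random.default_rng(3))
        frac = len(disturbed) / fallow.n_cells
        assert 0.005 <= frac <= 0.015


class TestParamFiles:
    def test_browser_params_yaml_round_trip(self, tmp_path):
        from woodsim.wildlife import browser_params_from_yaml, browser_params_to_yaml

        path = tmp_path / "deer.yaml"
        browser_params_to_yaml(BrowserParams(), path)
        back = browser_params_from_yaml(path)
        assert back.herd == BrowserParams().herd
        assert annual_demand_per_deer(back) == pytest.approx(157.46, abs=0.005)
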