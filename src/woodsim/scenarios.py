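"""Scenario builders: synthetic single-parent stands and raster landscapes.

The single-parent scenario is the canonical 1-ha encroachment experiment:
a 10 × 10 grid of 100 m² cells with one mature individual of the focal
species, optionally on a grass-saturated fallow sward, optionally under a
constant red-deer density.  Raster initialization reproduces the clumping
rules used when importing vegetation maps: a percentage of a region's cells
is fully covered by trees of a stated age class while the rest stay empty,
and scattered bushes occupy four times their percentage of cells at 25%
cover each.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .agents import WoodyAgent
from .engine import ScenarioConfig, Simulation
from .grid import LandscapeGrid, classify_all
from .species import default_herb_species, default_woody_species

__all__ = [
    "FALLOW_GRASS_COVER",
    "make_single_parent_scenario",
    "make_grassland",
    "init_from_rasters",
    "single_parent_trajectory",
    "year_reaching",
    "plateau_year",
]

#: Near-saturated tall-grass sward of an old fallow [m² per 100 m² cell].
FALLOW_GRASS_COVER: dict[str, float] = {
    "cocksfoot": 40.0,
    "tall_oat": 30.0,
    "red_fescue": 25.0,
}


def make_single_parent_scenario(
    species: str,
    inhibition: bool = False,
    deer_density: float = 0.0,
    years: int = 25,
    seed: int = 0,
    parent_position: str = "center",
    n_cols: int = 10,
    n_rows: int = 10,
) -> tuple[LandscapeGrid, ScenarioConfig]:
    """Build the 1-ha single-parent encroachment experiment.

    The parent is a mature individual (age = age of maturity, height on the
    deterministic growth curve) placed in the center (default) or the
    upper-left corner.  With ``inhibition`` the landscape is an unmanaged
    fallow with a near-saturated tall-grass sward; without it the herb
    layer is bare.  Boar disturbance is off; browsing is active only for a
    positive deer density.
    """
    woody = default_woody_species()
    if species not in woody:
        raise KeyError(f"unknown woody species {species!r}")
    config = ScenarioConfig(
        n_cols=n_cols,
        n_rows=n_rows,
        years=years,
        seed=seed,
        deer_density=deer_density,
        inhibition=inhibition,
        browsing=deer_density > 0.0,
        boar=False,
        herb_dynamics=inhibition,
        woody_species=woody,
        herb_species=default_herb_species(),
    )
    grid = LandscapeGrid(n_cols=n_cols, n_rows=n_rows, cellsize=config.cellsize)
    if inhibition:
        for cell in grid.iter_cells():
            cell.herb_cover.update(FALLOW_GRASS_COVER)

    if parent_position == "center":
        host = grid[(n_rows // 2, n_cols // 2)]
    elif parent_position == "corner":
        host = grid[(0, 0)]
    else:
        raise ValueError("parent_position must be 'center' or 'corner'")
    sp = woody[species]
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    host.agents.append(WoodyAgent.of_age(sp, age=sp.a_mat, rng=rng))
    classify_all(grid)
    return grid, config


def make_grassland(
    n_cols: int,
    n_rows: int,
    grass_cover: dict[str, float] | None = None,
    mown: bool = False,
    grazed: bool = False,
    cellsize: float = 10.0,
) -> LandscapeGrid:
    """A uniform grassland landscape (managed meadow/pasture or fallow)."""
    grid = LandscapeGrid(n_cols=n_cols, n_rows=n_rows, cellsize=cellsize)
    cover = FALLOW_GRASS_COVER if grass_cover is None else grass_cover
    for cell in grid.iter_cells():
        cell.herb_cover.update(cover)
        cell.mown = mown
        cell.grazed = grazed
        if mown:
            cell.i_c = 60.0
        if grazed:
            cell.i_g = 60.0
            cell.i_t = 40.0
    classify_all(grid)
    return grid


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def init_from_rasters(
    region_layer: np.ndarray,
    attributes: dict[int, dict],
    rng: np.random.Generator,
    cellsize: float = 10.0,
    species=None,
    max_agents_per_cell: int = 200,
) -> LandscapeGrid:
    """Initialize a landscape from a region-label raster plus attributes.

    ``attributes`` maps a region label to a dict with optional keys:

    ``management``
        one of ``"mown"``, ``"grazed"`` or ``"fallow"`` (default).
    ``herb_cover``
        map herb species → m² per cell.
    ``trees``
        map ``(species_name, age)`` → percent of the region's cells that are
        completely covered by trees of that age; the chosen cells are drawn
        at random (clumped import rule), the rest stay empty.
    ``bushes``
        map ``(species_name, age)`` → percent cover of scattered bushes;
        four times that percentage of cells receives 25% bush cover each.
    """
    region_layer = np.asarray(region_layer)
    n_rows, n_cols = region_layer.shape
    woody = default_woody_species() if species is None else species
    grid = LandscapeGrid(n_cols=n_cols, n_rows=n_rows, cellsize=cellsize)

    for label, attrs in attributes.items():
        for pct in list(attrs.get("trees", {}).values()) + list(attrs.get("bushes", {}).values()):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"region {label}: percentage {pct} outside [0, 100]")

    for label, attrs in attributes.items():
        cells = [c for c in grid.iter_cells() if region_layer[c.row, c.col] == label]
        if not cells:
            continue
        management = attrs.get("management", "fallow")
        for cell in cells:
            if management == "mown":
                cell.mown, cell.i_c = True, 60.0
            elif management == "grazed":
                cell.grazed, cell.i_g, cell.i_t = True, 60.0, 40.0
            cell.herb_cover.update(attrs.get("herb_cover", {}))

        for (sp_name, age), pct in attrs.get("trees", {}).items():
            sp = woody[sp_name]
            n_sel = min(len(cells), _round_half_up(len(cells) * pct / 100.0))
            chosen = rng.choice(len(cells), size=n_sel, replace=False)
            proto = WoodyAgent.of_age(sp, age=age, rng=rng)
            n_fill = max(1, min(max_agents_per_cell, _round_half_up(cells[0].area / proto.cover)))
            for idx in chosen:
                cell = cells[int(idx)]
                for _ in range(n_fill):
                    cell.agents.append(WoodyAgent.of_age(sp, age=age, rng=rng))

        for (sp_name, age), pct in attrs.get("bushes", {}).items():
            sp = woody[sp_name]
            n_sel = min(len(cells), _round_half_up(len(cells) * 4.0 * pct / 100.0))
            chosen = rng.choice(len(cells), size=n_sel, replace=False)
            proto = WoodyAgent.of_age(sp, age=age, rng=rng)
            target = 0.25 * cells[0].area
            n_fill = max(1, min(max_agents_per_cell, _round_half_up(target / proto.cover)))
            for idx in chosen:
                cell = cells[int(idx)]
                for _ in range(n_fill):
                    cell.agents.append(WoodyAgent.of_age(sp, age=age, rng=rng))

    classify_all(grid)
    return grid


def single_parent_trajectory(
    species: str,
    seed: int = 0,
    years: int = 25,
    inhibition: bool = False,
    deer_density: float = 0.0,
    **kwargs,
) -> pd.DataFrame:
    """Run a single-parent scenario and return the annual cover trajectory.

    Columns: ``year``, ``cover`` (m², per-cell capped), ``fraction`` of the
    landscape, ``agents`` of the focal species.
    """
    grid, config = make_single_parent_scenario(
        species, inhibition=inhibition, deer_density=deer_density,
        years=years, seed=seed, **kwargs,
    )
    sim = Simulation(grid, config)
    rows = []

    def record(s: Simulation) -> None:
        cover = s.grid.total_species_cover(species)
        rows.append(
            {
                "year": s.year,
                "cover": cover,
                "fraction": cover / s.grid.area,
                "agents": s.grid.count_agents(species),
            }
        )

    sim.run(observers=(record,))
    return pd.DataFrame(rows)


def year_reaching(traj: pd.DataFrame, fraction: float) -> int | None:
    """First year in which the cover fraction reaches the given level."""
    hit = traj[traj["fraction"] >= fraction]
    return None if hit.empty else int(hit["year"].iloc[0])


def plateau_year(traj: pd.DataFrame, rel: float = 0.99) -> int:
    """First year in which cover reaches ``rel`` of the run's maximum."""
    peak = traj["fraction"].max()
    return int(traj[traj["fraction"] >= rel * peak]["year"].iloc[0])
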