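"""Annual scheduler and scenario configuration.

A simulated year executes, in a fixed documented order: (1) wild-boar
disturbance, (2) the daily herb-layer loop (365 increments including
management), (3) seed production (maturity and mast) and dispersal, (4)
inhibition-filtered seed-bank input, (5) seed-bank decay, (6) germination
with the per-cell caps and surplus bookkeeping, (7) the browsing budget per
cell, (8) agent growth and allometry, (9) mowing kill, (10) self-thinning
(broom pass, then tree pass), (11) senescence and year-end browsing
mortality, (12) herb-space reclamation and vegetation re-classification,
(13) observers.  Browsing precedes growth so that a browsed sapling's
zero-growth year is expressible; all woody processes are annual while only
the herb layer runs in daily increments.

Randomness flows through named substreams spawned from the master seed
(mast, germination, growth, browsing, boar, initialization), each consumed
in row-major cell order, so runs are bit-reproducible and robust to
switching individual processes off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable

import numpy as np
import yaml

from . import agents as ag
from . import herbs, seeds, wildlife
from .grid import LandscapeGrid, VegType, classify_all
from .species import (
    HerbSpeciesParams,
    WoodySpeciesParams,
    default_herb_species,
    default_woody_species,
)
from .wildlife import BrowserParams, BrowseRecord

__all__ = ["ScenarioConfig", "Simulation", "RNG_STREAMS"]

RNG_STREAMS = ("mast", "germination", "growth", "browsing", "boar", "init")


@dataclass
class ScenarioConfig:
    """Everything that defines a runnable scenario except the landscape."""

    n_cols: int = 10
    n_rows: int = 10
    cellsize: float = 10.0
    years: int = 25
    deer_density: float = 0.0          # red deer per 100 ha
    seed: int = 0
    inhibition: bool = True            # grass inhibition of seed-bank input
    browsing: bool = True
    boar: bool = True
    herb_dynamics: bool = True
    herb_spill: float = 0.2            # growth fraction spilling to neighbours
    suppression_rate: float = 1.0      # management removal rate [1/a]
    tree_seedling_cap: int = 35
    broom_seedling_cap: int = 35
    mast_probs: tuple[float, ...] | None = None
    boar_rates: dict[VegType, float] | None = None
    woody_species: dict[str, WoodySpeciesParams] = field(default_factory=default_woody_species)
    herb_species: dict[str, HerbSpeciesParams] = field(default_factory=default_herb_species)
    browser: BrowserParams = field(default_factory=BrowserParams)
    output_dir: str | None = None
    output_every: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.deer_density < 0:
            raise ValueError("deer_density must be >= 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 <= self.herb_spill <= 1.0:
            raise ValueError("herb_spill must lie in [0, 1]")

    # -- plain-text round trip (scalar fields only; species tables are code
    #    defaults or CSV, see woodsim.species) --------------------------------

    _YAML_FIELDS = (
        "n_cols", "n_rows", "cellsize", "years", "deer_density", "seed",
        "inhibition", "browsing", "boar", "herb_dynamics", "herb_spill",
        "suppression_rate", "tree_seedling_cap", "broom_seedling_cap",
        "output_dir", "output_every",
    )

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self._YAML_FIELDS}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - set(cls._YAML_FIELDS)
        if bad or not set(data) <= known:
            raise ValueError(f"unknown configuration keys: {sorted(bad)}")
        return cls(**data)


class Simulation:
    """Drives one landscape through the annual cycle."""

    def __init__(self, grid: LandscapeGrid, config: ScenarioConfig):
        self.grid = grid
        self.config = config
        self.year = 0
        ss = np.random.SeedSequence(config.seed)
        self.rng = dict(zip(RNG_STREAMS, map(np.random.default_rng, ss.spawn(len(RNG_STREAMS)))))
        self._kernels: dict[str, seeds.DispersalKernel] = {}
        self.browse_records: list[BrowseRecord] = []
        classify_all(grid)

    def kernel(self, species: WoodySpeciesParams) -> seeds.DispersalKernel:
        if species.name not in self._kernels:
            self._kernels[species.name] = seeds.build_kernel(species, self.grid.cellsize)
        return self._kernels[species.name]

    # -- annual phases -------------------------------------------------------

    def _produce_and_disperse(self) -> dict[str, np.ndarray]:
        """Phase 3: mast draw, per-cell production, kernel dispersal."""
        cfg, grid = self.config, self.grid
        incoming: dict[str, np.ndarray] = {}
        for name, sp in cfg.woody_species.items():
            mast = seeds.mast_fraction(self.rng["mast"], cfg.mast_probs)
            if mast <= 0.0:
                continue
            production = np.zeros((grid.n_rows, grid.n_cols))
            for cell in grid.iter_cells():
                n_mature = sum(
                    1 for a in cell.agents if a.species.name == name and a.age >= sp.a_mat
                )
                if n_mature:
                    production[cell.row, cell.col] = n_mature * sp.seed_max * mast
            if production.any():
                incoming[name] = seeds.disperse_production(
                    grid, production, self.kernel(sp), gated=sp.zoochory_gated
                )
        return incoming

    def _seedbank_update(self, incoming: dict[str, np.ndarray]) -> None:
        """Phases 4-5: inhibition-filtered input, then exponential decay."""
        cfg, grid = self.config, self.grid
        for name, inc in incoming.items():
            sp = cfg.woody_species[name]
            for cell in grid.iter_cells():
                n_in = float(inc[cell.row, cell.col])
                if n_in <= 0.0:
                    continue
                t = (
                    seeds.grass_inhibition(cell, sp, cfg.herb_species)
                    if cfg.inhibition
                    else 0.0
                )
                seeds.seedbank_input(cell, n_in, sp, t)
        for cell in grid.iter_cells():
            for name in list(cell.seed_bank):
                if cell.seed_bank[name] > 0.0:
                    seeds.seedbank_decay(cell, cfg.woody_species[name])

    def run_year(self) -> list[BrowseRecord]:
        cfg, grid = self.config, self.grid

        # 1. wild boar ploughs a share of the open cells
        if cfg.boar:
            wildlife.boar_disturb(grid, self.rng["boar"], cfg.boar_rates)

        # 2. herb layer, iterated in daily increments
        if cfg.herb_dynamics:
            herbs.herb_year(
                grid, cfg.herb_species,
                spill_frac=cfg.herb_spill, suppression_rate=cfg.suppression_rate,
            )

        # 3-5. seed rain into the banks
        incoming = self._produce_and_disperse()
        self._seedbank_update(incoming)

        # 6. germination (caps + browsing surplus)
        for cell in grid.iter_cells():
            cell.surplus = {}
            seeds.germinate(
                cell, cfg.woody_species, self.rng["germination"],
                tree_cap=cfg.tree_seedling_cap, broom_cap=cfg.broom_seedling_cap,
            )

        # 7. browsing budget
        records: list[BrowseRecord] = []
        if cfg.browsing and cfg.deer_density > 0.0:
            for cell in grid.iter_cells():
                records.append(
                    wildlife.browse_cell(cell, cfg.browser, cfg.deer_density, cfg.woody_species)
                )

        # 8. growth (browsed saplings skip the year)
        for cell in grid.iter_cells():
            for agent in cell.agents:
                ag.annual_growth(agent, self.rng["growth"])

        # 9-11. mowing, space competition, senescence and browsing mortality
        for cell in grid.iter_cells():
            ag.mow_kill(cell)
            ag.self_thinning(cell)
            ag.apply_senescence(cell)
            wildlife.apply_browsing_mortality(cell, self.rng["browsing"], cfg.browser)

        # 12. herbs yield the newly covered space; retype the cells
        for cell in grid.iter_cells():
            herbs.reclaim_space(cell)
        classify_all(grid)

        self.year += 1
        self.browse_records = records
        return records

    def run(self, observers: tuple[Callable[["Simulation"], None], ...] = ()) -> None:
        """Run the configured number of years, notifying observers.

        Observers are called once on the initial state (year 0) and after
        every completed year.
        """
        for obs in observers:
            obs(self)
        for _ in range(self.config.years):
            self.run_year()
            for obs in observers:
                obs(self)
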