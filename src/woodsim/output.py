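"""Observers and tabular/raster output.

The standard observation set: per-year total cover and agent count per
woody species, vegetation-type cell counts, optional per-agent dumps, the
annual browsing ledger, and vegetation-type rasters in Esri ASCII format.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .engine import Simulation
from .grid import LandscapeGrid, VegType
from .rasters import write_ascii_grid
from .wildlife import BrowseRecord

__all__ = [
    "CoverObserver",
    "agent_table",
    "browse_ledger_frame",
    "vegtype_array",
    "write_vegtype_raster",
    "RasterObserver",
]


class CoverObserver:
    """Collects the annual landscape summary into a DataFrame."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def __call__(self, sim: Simulation) -> None:
        row: dict = {"year": sim.year}
        for name in sim.config.woody_species:
            row[f"cover_{name}"] = sim.grid.total_species_cover(name)
            row[f"agents_{name}"] = sim.grid.count_agents(name)
        counts = {vt: 0 for vt in VegType}
        for cell in sim.grid.iter_cells():
            counts[cell.veg_type] += 1
        for vt, n in counts.items():
            row[f"cells_{vt.value}"] = n
        self.rows.append(row)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def agent_table(grid: LandscapeGrid, year: int | None = None) -> pd.DataFrame:
    """Per-agent dump: one row per bush or tree in the landscape."""
    rows = [
        {
            "year": year,
            "col": cell.col,
            "row": cell.row,
            "species": a.species.name,
            "height": a.height,
            "age": a.age,
            "cover": a.cover,
        }
        for cell in grid.iter_cells()
        for a in cell.agents
    ]
    df = pd.DataFrame(rows, columns=["year", "col", "row", "species", "height", "age", "cover"])
    return df if year is not None else df.drop(columns="year")


def browse_ledger_frame(records: list[BrowseRecord]) -> pd.DataFrame:
    """The annual browsing ledger (cell, demand, consumed, effects)."""
    return pd.DataFrame(
        [
            {
                "col": r.col,
                "row": r.row,
                "demand": r.demand,
                "consumed": r.consumed,
                "surplus_eaten": r.surplus_eaten,
                "agents_browsed": r.agents_browsed,
                "instant_deaths": r.instant_deaths,
            }
            for r in records
        ]
    )


def vegtype_array(grid: LandscapeGrid) -> np.ndarray:
    """Vegetation types as an integer-coded raster array."""
    out = np.zeros((grid.n_rows, grid.n_cols))
    for cell in grid.iter_cells():
        out[cell.row, cell.col] = cell.veg_type.code
    return out


def write_vegtype_raster(grid: LandscapeGrid, path) -> None:
    write_ascii_grid(vegtype_array(grid), path, cellsize=grid.cellsize)


class RasterObserver:
    """Writes a vegetation-type raster every ``every`` years."""

    def __init__(self, out_dir: str, every: int = 1):
        self.out_dir = out_dir
        self.every = every
        os.makedirs(out_dir, exist_ok=True)

    def __call__(self, sim: Simulation) -> None:
        if sim.year % self.every == 0:
            path = os.path.join(self.out_dir, f"vegtype_{sim.year:04d}.asc")
            write_vegtype_raster(sim.grid, path)
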