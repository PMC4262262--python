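"""Raster landscape: cells, the grid, distances and vegetation typing.

The landscape is a regular raster of 100 m² cells (10 m edge by default).
Each cell carries the management intensities, the herb-layer covers, the
per-species seed banks, the list of individually modelled woody agents and a
derived vegetation type.  The grid origin is the upper-left corner and all
whole-landscape iteration is row-major (upper left to lower right), which
fixes the draw order of every stochastic per-cell process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterator

from .species import BLACKTHORN, BRAMBLE

if TYPE_CHECKING:  # pragma: no cover
    from .agents import WoodyAgent

__all__ = [
    "VegType",
    "Cell",
    "LandscapeGrid",
    "centroid_distance",
    "classify_vegetation",
    "classify_all",
]


class VegType(str, Enum):
    """Vegetation type of a cell, derived from cover and management."""

    GRASSLAND = "grassland"              # managed hay meadow or pasture
    FALLOW_GRASSLAND = "fallow_grassland"
    SHRUB = "shrub"
    FOREST = "forest"
    DISTURBED_GROUND = "disturbed_ground"

    @property
    def code(self) -> int:
        """Small integer code used in vegetation-type raster output."""
        return _VEG_CODES[self]


_VEG_CODES = {
    VegType.GRASSLAND: 1,
    VegType.FALLOW_GRASSLAND: 2,
    VegType.SHRUB: 3,
    VegType.FOREST: 4,
    VegType.DISTURBED_GROUND: 5,
}


@dataclass
class Cell:
    """One 100 m² raster cell.

    ``herb_cover`` maps herb-layer species name to cover in m² (grasses,
    tufted plants, bramble, blackthorn); ``seed_bank`` maps woody species
    name to a real-valued seed count (dispersal spreads fractional kernel
    proportions; germination floors to whole seedlings); ``surplus`` holds
    this year's germination surplus per woody species, which feeds the
    browsing budget.
    """

    col: int
    row: int
    area: float = 100.0
    i_c: float = 0.0     # cutting intensity, 0-100
    i_g: float = 0.0     # grazing intensity, 0-100
    i_t: float = 0.0     # trampling intensity, 0-100
    mown: bool = False
    grazed: bool = False
    herb_cover: dict[str, float] = field(default_factory=dict)
    seed_bank: dict[str, float] = field(default_factory=dict)
    agents: list["WoodyAgent"] = field(default_factory=list)
    surplus: dict[str, float] = field(default_factory=dict)
    veg_type: VegType = VegType.FALLOW_GRASSLAND

    # -- derived covers -----------------------------------------------------

    @property
    def managed(self) -> bool:
        return self.mown or self.grazed

    @property
    def tree_cover(self) -> float:
        """Summed crown cover of all tree-guild agents [m²]."""
        return sum(a.cover for a in self.agents if not a.species.is_broom)

    @property
    def broom_cover(self) -> float:
        return sum(a.cover for a in self.agents if a.species.is_broom)

    @property
    def thorny_cover(self) -> float:
        """Bramble plus blackthorn cover from the herb layer [m²]."""
        return self.herb_cover.get(BRAMBLE, 0.0) + self.herb_cover.get(BLACKTHORN, 0.0)

    @property
    def bush_cover(self) -> float:
        """Broom agents plus the thorny shrubs: the shrub-typing cover."""
        return self.broom_cover + self.thorny_cover

    @property
    def herb_total(self) -> float:
        return sum(self.herb_cover.values())

    @property
    def woody_cover(self) -> float:
        """Cover taken from the herbaceous layer (trees + broom agents)."""
        return sum(a.cover for a in self.agents)

    @property
    def herbaceous_space(self) -> float:
        """Space available to the herb layer: cell area minus agent cover."""
        return max(0.0, self.area - self.woody_cover)

    def species_cover(self, name: str, capped: bool = True) -> float:
        """Summed agent cover of one woody species, capped at cell area.

        A solitary old tree's allometric crown can exceed the cell, but a
        cell cannot contribute more than its own area to landscape totals.
        """
        c = sum(a.cover for a in self.agents if a.species.name == name)
        return min(c, self.area) if capped else c


@dataclass
class LandscapeGrid:
    """Rectangular raster of cells; ``cells[row][col]``, row-major iteration."""

    n_cols: int
    n_rows: int
    cellsize: float = 10.0
    cells: list[list[Cell]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cells:
            self.cells = [
                [Cell(col=c, row=r, area=self.cellsize ** 2) for c in range(self.n_cols)]
                for r in range(self.n_rows)
            ]

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def area(self) -> float:
        """Total landscape area [m²]."""
        return self.n_cells * self.cellsize ** 2

    def __getitem__(self, rc: tuple[int, int]) -> Cell:
        r, c = rc
        return self.cells[r][c]

    def iter_cells(self) -> Iterator[Cell]:
        """Row-major iteration, upper left to lower right."""
        for row in self.cells:
            yield from row

    def neighbors4(self, cell: Cell) -> list[Cell]:
        """Orthogonally adjacent cells (used for vegetative herb spread)."""
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r, c = cell.row + dr, cell.col + dc
            if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
                out.append(self.cells[r][c])
        return out

    def total_species_cover(self, name: str) -> float:
        """Landscape total of one woody species' cover, per-cell capped [m²]."""
        return sum(cell.species_cover(name) for cell in self.iter_cells())

    def count_agents(self, name: str | None = None) -> int:
        if name is None:
            return sum(len(c.agents) for c in self.iter_cells())
        return sum(
            1 for c in self.iter_cells() for a in c.agents if a.species.name == name
        )


def centroid_distance(cell1: Cell, cell2: Cell, cellsize: float) -> float:
    """Euclidean centroid-to-centroid distance between two cells [m]."""
    return cellsize * math.hypot(cell1.col - cell2.col, cell1.row - cell2.row)


def classify_vegetation(
    cell: Cell,
    forest_threshold: float = 0.5,
    shrub_threshold: float = 0.1,
    bare_threshold: float = 0.0,
) -> VegType:
    """Map a cell's covers and management onto one vegetation type.

    Forest: tree cover at least 50% of the cell.  Shrub: bush cover (broom
    agents plus bramble and blackthorn) at least 10%.  Otherwise managed
    cells are grassland and unmanaged cells fallow grassland.  With a
    positive ``bare_threshold``, unmanaged cells whose herb layer stays
    below it are typed disturbed ground instead (by default that category
    only enters through initialization).  The thresholds are configurable
    because the full grassland typology lives in the herbaceous reference
    model.
    """
    a = cell.area
    if min(cell.tree_cover, a) >= forest_threshold * a:
        return VegType.FOREST
    if min(cell.bush_cover, a) >= shrub_threshold * a:
        return VegType.SHRUB
    if cell.managed:
        return VegType.GRASSLAND
    if cell.herb_total < bare_threshold * a:
        return VegType.DISTURBED_GROUND
    return VegType.FALLOW_GRASSLAND


def classify_all(grid: LandscapeGrid, **thresholds) -> None:
    """Reclassify every cell in place."""
    for cell in grid.iter_cells():
        cell.veg_type = classify_vegetation(cell, **thresholds)
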