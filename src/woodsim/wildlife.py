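"""Wild-boar soil disturbance and the red-deer browsing budget.

Browsing weighs a supply of woody browse against a demand derived from the
deer density.  Demand per "standard deer" — the mean-mass individual of a
reference herd — follows the seasonal dry-weight intake scaled by the woody
diet fraction.  Deer are spread evenly, so each cell receives the same
demand, reduced by the nurse-shrub factor where blackthorn or bramble
provide cover.  Bites of a fixed branch length are converted to dry biomass
with the species' twig allometry and taken from germination-surplus
seedlings first, then from standing trees in the preference order oak,
birch, beech, spruce (broom is not browsed), until the cell's demand is
met.  Browsed trees with the leader shoot in reach stop growing and may die
at year's end; trees below 0.2 m die at once.

Wild boar plough a fixed share of grassland-type cells each year, removing
45% of the herbaceous layer and thereby weakening the grass inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .grid import Cell, LandscapeGrid, VegType
from .herbs import remove_herb_cover
from .species import BLACKTHORN, BRAMBLE, WoodySpeciesParams

__all__ = [
    "BrowserParams",
    "BrowseRecord",
    "standard_deer_weight",
    "annual_demand_per_deer",
    "nurse_factor",
    "bite_biomass",
    "available_browse",
    "browse_cell",
    "apply_browsing_mortality",
    "BOAR_RATES",
    "boar_disturb",
]

#: Annual wild-boar disturbance probability per vegetation type.
BOAR_RATES: dict[VegType, float] = {
    VegType.GRASSLAND: 0.10,         # hay meadows and pastures
    VegType.SHRUB: 0.03,
    VegType.FALLOW_GRASSLAND: 0.01,
}

#: Fraction of the herbaceous layer removed in a disturbed cell.
BOAR_REMOVAL = 0.45


@dataclass(frozen=True)
class BrowserParams:
    """Red-deer demand constants, herd composition and browsing geometry.

    ``dsd``/``dwd`` are daily summer/winter dry-weight demand per 100 kg of
    deer; ``frw`` the woody fraction of the diet; ``herd`` a list of
    (count, body mass kg) classes defining the standard deer.  ``supply``
    may inject an alternative available-browse function aB(H, species,
    params) [kg dw].
    """

    dsd: float = 2.5
    sdays: int = 214
    dwd: float = 3.0
    wdays: int = 152
    frw: float = 0.268
    herd: tuple[tuple[float, float], ...] = ((5, 105.0), (10, 70.0), (20, 42.5))
    bite_length: float = 0.1           # browsed branch length per event [m]
    max_forage_height: float = 5.0     # taller trees provide no forage [m]
    max_browse_height: float = 1.7     # leader shoot in reach below this [m]
    instant_death_height: float = 0.2  # browsed trees below this die [m]
    nurse_half_blackthorn: float = 25.0  # cover at 50% protection [m²]
    nurse_half_bramble: float = 50.0
    nurse_slope: float = 4.0
    supply: Callable | None = field(default=None, compare=False)


def browser_params_to_yaml(params: BrowserParams, path) -> None:
    """Write the demand constants, herd and geometry as plain YAML."""
    import yaml

    data = {
        "dsd": params.dsd, "sdays": params.sdays,
        "dwd": params.dwd, "wdays": params.wdays, "frw": params.frw,
        "herd": [list(cls) for cls in params.herd],
        "bite_length": params.bite_length,
        "max_forage_height": params.max_forage_height,
        "max_browse_height": params.max_browse_height,
        "instant_death_height": params.instant_death_height,
        "nurse_half_blackthorn": params.nurse_half_blackthorn,
        "nurse_half_bramble": params.nurse_half_bramble,
        "nurse_slope": params.nurse_slope,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def browser_params_from_yaml(path) -> BrowserParams:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "herd" in data:
        data["herd"] = tuple((float(n), float(m)) for n, m in data["herd"])
    return BrowserParams(**data)


def standard_deer_weight(herd) -> float:
    """Mean body mass of one individual in the herd [kg]."""
    herd = tuple(herd)
    if not herd:
        raise ValueError("herd must not be empty")
    total = sum(count * mass for count, mass in herd)
    n = sum(count for count, _ in herd)
    return total / n


def annual_demand_per_deer(params: BrowserParams) -> float:
    """Annual woody-browse demand of one standard deer [kg dw a⁻¹].

    D = (dsd·sdays + dwd·wdays) · (sdeer / 100) · frw.
    """
    sdeer = standard_deer_weight(params.herd)
    return (params.dsd * params.sdays + params.dwd * params.wdays) * (sdeer / 100.0) * params.frw


def nurse_factor(
    blackthorn_cover: float,
    bramble_cover: float,
    params: BrowserParams = BrowserParams(),
) -> float:
    """Demand reduction F ∈ [0, 1] by the thorny nurse shrubs.

    Decreasing Hill sigmoid in each cover, combined multiplicatively;
    blackthorn is parameterized to protect more strongly than bramble at
    equal cover (half-protection at 25 vs 50 m²).  The half-covers and
    slope are package defaults, injectable through :class:`BrowserParams`.
    """
    if blackthorn_cover < 0 or bramble_cover < 0:
        raise ValueError("covers must be >= 0")
    n = params.nurse_slope
    f_p = 1.0 / (1.0 + (blackthorn_cover / params.nurse_half_blackthorn) ** n)
    f_r = 1.0 / (1.0 + (bramble_cover / params.nurse_half_bramble) ** n)
    return f_p * f_r


def bite_biomass(species: WoodySpeciesParams, length: float) -> float:
    """Dry biomass of one browsed branch piece: B = A_biom_const·L^A_biom_coeff."""
    if species.a_biom_const is None or species.a_biom_coeff is None:
        raise ValueError(f"{species.name} has no twig-biomass allometry")
    return species.a_biom_const * length ** species.a_biom_coeff

def available_browse(
    height: float,
    species: WoodySpeciesParams,
    params: BrowserParams = BrowserParams(),
) -> float:
    """Browsable dry biomass of one tree of the given height [kg dw].

    Trees above 5 m provide no forage; below that, the default proxy offers
    the bite events along the crown circumference of the stratum below the
    1.7 m browsing ceiling: aB = (π·D(min(H, 1.7)) / bite length) · B(bite
    length).  The event count is continuous so aB → 0 with H → 0 and is
    non-decreasing up to the ceiling.  A literature supply curve can be
    injected via ``params.supply``.
    """
    if height <= 0.0:
        return 0.0
    if params.supply is not None:
        return max(0.0, params.supply(height, species, params))
    if height > params.max_forage_height:
        return 0.0
    stratum_h = min(height, params.max_browse_height)
    circumference = math.pi * species.a_cd_const * stratum_h ** species.a_cd_coeff
    n_events = circumference / params.bite_length
    return n_events * bite_biomass(species, params.bite_length)


@dataclass
class BrowseRecord:
    """Per-cell annual browsing ledger."""

    col: int
    row: int
    demand: float = 0.0
    consumed: float = 0.0
    surplus_eaten: float = 0.0
    agents_browsed: int = 0
    instant_deaths: int = 0


def browse_cell(
    cell: Cell,
    params: BrowserParams,
    density: float,
    species_table: dict[str, WoodySpeciesParams],
) -> BrowseRecord:
    """Apply one year of browsing to a cell; returns the consumption ledger.

    Demand per cell = density · (cell area / 100 ha) · annual demand ·
    nurse factor.  The germination surplus is consumed first (one bite per
    seedling), then standing agents of height ≤ 5 m in preference order and
    smallest first within a species.  From each agent at most its available
    browse is taken, with a fractional final bite so that the consumed total
    never exceeds demand.  Browsed agents are flagged; those below 0.2 m die
    immediately.
    """
    rec = BrowseRecord(col=cell.col, row=cell.row)
    if density <= 0.0:
        return rec
    f = nurse_factor(
        cell.herb_cover.get(BLACKTHORN, 0.0), cell.herb_cover.get(BRAMBLE, 0.0), params
    )
    demand = density * (cell.area / 1.0e6) * annual_demand_per_deer(params) * f
    rec.demand = demand
    remaining = demand

    order = sorted(
        (n for n in species_table if species_table[n].browse_rank is not None),
        key=lambda n: species_table[n].browse_rank,
    )

    # germination surplus first: recruits that would be eaten before anything
    for name in order:
        if remaining <= 0.0:
            break
        sp = species_table[name]
        avail = cell.surplus.get(name, 0.0)
        if avail < 1.0:
            continue
        b = bite_biomass(sp, params.bite_length)
        n_eat = min(math.floor(avail), math.ceil(remaining / b))
        take = min(n_eat * b, remaining)
        cell.surplus[name] = avail - n_eat
        rec.surplus_eaten += take
        rec.consumed += take
        remaining -= take

    if remaining > 0.0:
        dead: list = []
        for name in order:
            if remaining <= 0.0:
                break
            sp = species_table[name]
            eligible = sorted(
                (
                    a
                    for a in cell.agents
                    if a.species.name == name and a.height <= params.max_forage_height
                ),
                key=lambda a: (a.height, a.age),
            )
            for agent in eligible:
                if remaining <= 0.0:
                    break
                cap = available_browse(agent.height, sp, params)
                take = min(cap, remaining)
                if take <= 0.0:
                    continue
                agent.browsed = True
                rec.agents_browsed += 1
                rec.consumed += take
                remaining -= take
                if agent.height < params.instant_death_height:
                    dead.append(agent)
                    rec.instant_deaths += 1
        if dead:
            gone = set(map(id, dead))
            cell.agents = [a for a in cell.agents if id(a) not in gone]
    return rec


def apply_browsing_mortality(
    cell: Cell, rng: np.random.Generator, params: BrowserParams = BrowserParams()
) -> list:
    """Year-end stochastic death of browsed saplings; clears all flags.

    A flagged agent whose leader shoot was in reach (H ≤ 1.7 m) dies with
    its species' browsing-induced mortality probability.
    """
    dead = []
    for agent in cell.agents:
        if agent.browsed:
            p = agent.species.brow_mort
            if (
                p is not None
                and agent.height <= params.max_browse_height
                and rng.random() < p
            ):
                dead.append(agent)
            agent.browsed = False
    if dead:
        gone = set(map(id, dead))
        cell.agents = [a for a in cell.agents if id(a) not in gone]
    return dead


def boar_disturb(
    grid: LandscapeGrid,
    rng: np.random.Generator,
    rates: dict[VegType, float] | None = None,
    removal: float = BOAR_REMOVAL,
) -> list[Cell]:
    """One year of wild-boar soil disturbance; returns the disturbed cells.

    Cells are chosen by independent Bernoulli draws at the per-vegetation-
    type rates (10% of meadows/pastures, 3% of shrub, 1% of fallow
    grassland); forest and disturbed-ground cells are never ploughed.  Each
    selected cell loses 45% of every herb species' cover.
    """
    if rates is None:
        rates = BOAR_RATES
    disturbed = []
    for cell in grid.iter_cells():
        p = rates.get(cell.veg_type, 0.0)
        if p > 0.0 and rng.random() < p:
            remove_herb_cover(cell, removal)
            disturbed.append(cell)
    return disturbed
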