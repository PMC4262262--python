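"""Individual life cycle of bushes and trees.

Each agent grows along a Bertalanffy height curve with an annually redrawn
growth rate, carries a height-derived crown (allometric diameter, circular
cover), competes for space within its cell through iterative self-thinning,
and dies of senescence at an individually jittered maximum age.  Mowing
kills saplings in the 0.1-1 m window.  Browsing effects (growth stop,
immediate and stochastic mortality) are driven by :mod:`woodsim.wildlife`
via the ``browsed`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import Cell
from .species import WoodySpeciesParams

__all__ = [
    "WoodyAgent",
    "update_allometry",
    "annual_growth",
    "available_space",
    "self_thinning",
    "senescence",
    "apply_senescence",
    "mow_kill",
]


@dataclass
class WoodyAgent:
    """One bush or tree: height, age, crown state and the browsed flag."""

    species: WoodySpeciesParams
    height: float
    age: float = 0.0
    a_max_ind: float = 0.0
    diameter: float = field(default=0.0)
    cover: float = field(default=0.0)
    browsed: bool = False

    def __post_init__(self) -> None:
        if self.a_max_ind <= 0.0:
            self.a_max_ind = self.species.a_max
        if self.diameter == 0.0:
            update_allometry(self)

    @classmethod
    def seedling(cls, species: WoodySpeciesParams, rng: np.random.Generator) -> "WoodyAgent":
        """New germinated seedling; individual maximum age jittered ±10%."""
        a_max_ind = species.a_max * rng.uniform(0.9, 1.1)
        return cls(species=species, height=species.h_ini, age=0.0, a_max_ind=a_max_ind)

    @classmethod
    def of_age(
        cls, species: WoodySpeciesParams, age: float, rng: np.random.Generator
    ) -> "WoodyAgent":
        """Agent of a given age on the deterministic mean growth curve."""
        a_max_ind = species.a_max * rng.uniform(0.9, 1.1)
        return cls(species=species, height=species.height_at(age), age=age, a_max_ind=a_max_ind)


def update_allometry(agent: WoodyAgent) -> None:
    """Recompute crown diameter and circular cover from height.

    D = A_cd_const · H^A_cd_coeff;  C = π (D/2)².
    """
    sp = agent.species
    agent.diameter = sp.a_cd_const * agent.height ** sp.a_cd_coeff
    agent.cover = math.pi * (agent.diameter / 2.0) ** 2


def annual_growth(agent: WoodyAgent, rng: np.random.Generator) -> float:
    """One annual Bertalanffy height increment; returns ΔH.

    The growth rate is redrawn each year from N(G, sd), truncated at zero,
    and the height step is the exact one-year integral of
    dH/dt = g (H_max − H), i.e. ΔH = (H_max − H)(1 − e^{−g}).  A browsed
    individual whose leader shoot is still within reach (H ≤ 1.7 m) does
    not grow this year.  Ages by one year and refreshes the allometry.
    """
    sp = agent.species
    g = max(0.0, float(rng.normal(sp.g_mean, sp.g_sd)))
    dh = (sp.h_max - agent.height) * (1.0 - math.exp(-g))
    if agent.browsed and agent.height <= 1.7:
        dh = 0.0
    agent.height += dh
    agent.age += 1.0
    update_allometry(agent)
    return dh


def available_space(cell: Cell, guild: str) -> float:
    """Space open for germination, per guild [m²], floored at zero.

    Trees ignore the bushes: AS_T = A − Σ tree cover.  Broom competes with
    everything woody: AS_C = A − Σ tree cover − blackthorn − bramble −
    Σ broom cover.
    """
    if guild == "tree":
        return max(0.0, cell.area - cell.tree_cover)
    if guild == "broom":
        return max(
            0.0, cell.area - cell.tree_cover - cell.thorny_cover - cell.broom_cover
        )
    raise ValueError(f"unknown guild {guild!r}")


def _smallest(agents: list[WoodyAgent]) -> WoodyAgent:
    # equal smallest heights: the younger individual dies (deterministic
    # given the cell's agent ordering)
    return min(agents, key=lambda a: (a.height, a.age))


def self_thinning(cell: Cell) -> list[WoodyAgent]:
    """Iterative space competition within one cell; returns removed agents.

    Broom is inferior: first, while the combined cover of broom, trees,
    bramble and blackthorn exceeds the cell area, the smallest broom dies.
    Then, while the tree cover alone exceeds the cell area, the smallest
    tree dies — but a last remaining tree always survives, since a solitary
    crown may legitimately overhang the 100 m² cell.
    """
    removed: list[WoodyAgent] = []
    brooms = [a for a in cell.agents if a.species.is_broom]
    trees = [a for a in cell.agents if not a.species.is_broom]
    thorny = cell.thorny_cover

    tree_cover = sum(a.cover for a in trees)
    broom_cover = sum(a.cover for a in brooms)
    while brooms and broom_cover + tree_cover + thorny > cell.area:
        victim = _smallest(brooms)
        brooms.remove(victim)
        broom_cover -= victim.cover
        removed.append(victim)

    while len(trees) > 1 and tree_cover > cell.area:
        victim = _smallest(trees)
        trees.remove(victim)
        tree_cover -= victim.cover
        removed.append(victim)

    if removed:
        gone = set(map(id, removed))
        cell.agents = [a for a in cell.agents if id(a) not in gone]
    return removed


def senescence(agent: WoodyAgent) -> bool:
    """True if the agent has reached its individual maximum age and dies."""
    return agent.age >= agent.a_max_ind


def apply_senescence(cell: Cell) -> list[WoodyAgent]:
    """Remove all agents past their individual maximum age."""
    dead = [a for a in cell.agents if senescence(a)]
    if dead:
        cell.agents = [a for a in cell.agents if not senescence(a)]
    return dead


def mow_kill(cell: Cell) -> list[WoodyAgent]:
    """Mowing kills every woody individual with 0.1 m ≤ H ≤ 1 m (closed).

    Only applies to mown cells; returns the removed agents.
    """
    if not cell.mown:
        return []
    dead = [a for a in cell.agents if 0.1 <= a.height <= 1.0]
    if dead:
        gone = set(map(id, dead))
        cell.agents = [a for a in cell.agents if id(a) not in gone]
    return dead
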