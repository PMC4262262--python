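"""Seed production, dispersal, seed-bank dynamics and germination.

Annual seed production varies with a four-category mast-year draw.  Seeds
travel along a double-exponential distance law characterized by the
effective seeding distance ED (holding the fraction ``p_ed`` of all seeds)
and the maximum seeding distance MD (holding the rest).  The law is the
mixture of an exponential truncated to [0, ED] and an exponential restricted
to (ED, MD]; rates are fixed by the published quantiles, so the kernel is
fully determined by (ED, MD, p_ed).  For the 2-D raster it is converted to
an isotropic planar density f(r)/(2πr), evaluated at cell-centroid
distances, and renormalized so its sum over all sink cells is one — which
preserves the ED-quantile on the cell sum.

For the zoochorously dispersed acorns and beechnuts the kernel mass beyond
ED only lands in sink cells holding at least one bush or tree that are not
forest cells (jays cache in small diverse woodland patches); the gated mass
aimed at ineligible cells is lost.

Incoming seeds are thinned by unspecific seed predators and by the grass
inhibition sigmoid before entering the seed bank, which decays
exponentially.  Once a year a species-specific fraction of the bank
germinates, capped at 35 tree plus 35 broom seedlings per cell; surplus
germinators are booked for the browsing budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .grid import Cell, LandscapeGrid, VegType
from .species import WoodySpeciesParams

__all__ = [
    "MAST_CATEGORIES",
    "mast_fraction",
    "DispersalKernel",
    "build_kernel",
    "disperse",
    "disperse_production",
    "grass_inhibition",
    "seedbank_input",
    "seedbank_decay",
    "germinate",
]

#: Mast-year categories: fraction of the maximal seed crop is drawn
#: uniformly from the selected band (a no-seed year yields exactly 0).
MAST_CATEGORIES: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.10, 0.40),
    (0.40, 0.70),
    (0.70, 1.00),
)


def mast_fraction(rng: np.random.Generator, probabilities=None) -> float:
    """Draw this year's seed-crop fraction of ``seed_max``.

    One of the four mast categories is chosen (uniformly by default,
    configurable via *probabilities*), then the fraction is drawn uniformly
    within the category's band.
    """
    k = int(rng.choice(len(MAST_CATEGORIES), p=probabilities))
    lo, hi = MAST_CATEGORIES[k]
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


# -- double-exponential distance law ----------------------------------------

class _DistanceLaw:
    """Two-component exponential mixture on [0, MD] with quantile p_ed at ED."""

    def __init__(self, ed: float, md: float, p_ed: float):
        if ed > md:
            raise ValueError("need ED <= MD")
        self.ed, self.md, self.k = ed, md, p_ed
        # rates from the published quantiles; guard the degenerate corners
        tail = max(1.0 - p_ed, 1e-6)
        self.lam1 = -math.log(tail) / ed
        self.lam2 = -math.log(tail) / md
        self._z1 = 1.0 - math.exp(-self.lam1 * ed)
        self._z2 = math.exp(-self.lam2 * ed) - math.exp(-self.lam2 * md)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        inner = np.clip((1.0 - np.exp(-self.lam1 * np.minimum(x, self.ed))) / self._z1, 0.0, 1.0)
        beyond = np.clip(x, self.ed, self.md)
        outer = (math.exp(-self.lam2 * self.ed) - np.exp(-self.lam2 * beyond)) / self._z2
        out = self.k * inner + (1.0 - self.k) * outer
        return np.where(x >= self.md, 1.0, out)

    def pdf_inner(self, x):
        """Density of the within-ED component (already weighted by p_ed)."""
        x = np.asarray(x, dtype=float)
        d = self.k * self.lam1 * np.exp(-self.lam1 * x) / self._z1
        return np.where((x >= 0) & (x <= self.ed), d, 0.0)

    def pdf_outer(self, x):
        x = np.asarray(x, dtype=float)
        if self.md == self.ed:
            return np.zeros_like(x)
        d = (1.0 - self.k) * self.lam2 * np.exp(-self.lam2 * x) / self._z2
        return np.where((x > self.ed) & (x <= self.md), d, 0.0)


@dataclass(frozen=True)
class DispersalKernel:
    """Discrete per-sink-cell seed proportions around a source cell.

    ``inner`` and ``outer`` are (2R+1, 2R+1) arrays holding the kernel
    weights from the within-ED and beyond-ED components, respectively; for
    zoochory-gated species only the outer part is subject to the sink-cell
    eligibility rule.  ``inner + outer`` sums to one.
    """

    species_name: str
    cellsize: float
    ed: float
    md: float
    radius: int
    inner: np.ndarray
    outer: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.inner + self.outer

    @property
    def weights(self) -> dict[tuple[int, int], float]:
        """Map (Δcol, Δrow) → proportion for offsets within MD."""
        r = self.radius
        t = self.total
        out = {}
        for i in range(2 * r + 1):
            for j in range(2 * r + 1):
                if t[i, j] > 0.0:
                    out[(j - r, i - r)] = float(t[i, j])
        return out

    def cumulative_within(self, distance: float) -> float:
        """Summed weight of all sink cells with centroid distance <= d."""
        r = self.radius
        jj, ii = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
        d = self.cellsize * np.hypot(ii, jj)
        return float(self.total[d <= distance + 1e-9].sum())


@lru_cache(maxsize=32)
def _kernel_cached(ed: float, md: float, p_ed: float, cellsize: float, name: str) -> DispersalKernel:
    law = _DistanceLaw(ed, md, p_ed)
    r = int(math.floor(md / cellsize))
    jj, ii = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    d = cellsize * np.hypot(ii, jj)
    with np.errstate(divide="ignore", invalid="ignore"):
        # isotropic planar density times the cell area
        inner = np.where(
            (d > 0) & (d <= md), cellsize**2 * law.pdf_inner(d) / (2.0 * math.pi * d), 0.0
        )
        outer = np.where(
            (d > 0) & (d <= md), cellsize**2 * law.pdf_outer(d) / (2.0 * math.pi * d), 0.0
        )
    # the source cell collects the central disc of the inner component
    inner[r, r] = float(law.cdf(cellsize / 2.0))
    z = inner.sum() + outer.sum()
    return DispersalKernel(
        species_name=name, cellsize=cellsize, ed=ed, md=md, radius=r,
        inner=inner / z, outer=outer / z,
    )


def build_kernel(species: WoodySpeciesParams, cellsize: float = 10.0) -> DispersalKernel:
    """Build (and cache) the discrete dispersal kernel for a species."""
    if species.ed > species.md:
        raise ValueError(f"{species.name}: ED exceeds MD")
    return _kernel_cached(species.ed, species.md, species.p_ed, cellsize, species.name)


def _eligibility_mask(grid: LandscapeGrid) -> np.ndarray:
    """Sink cells that may receive zoochorously dispersed seeds beyond ED."""
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for cell in grid.iter_cells():
        mask[cell.row, cell.col] = bool(cell.agents) and cell.veg_type != VegType.FOREST
    return mask


def disperse_production(
    grid: LandscapeGrid,
    production: np.ndarray,
    kernel: DispersalKernel,
    gated: bool = False,
) -> np.ndarray:
    """Disperse a per-cell seed production array; return per-cell increments.

    Kernel mass falling outside the grid is lost.  For gated species the
    beyond-ED mass is delivered only to eligible cells (at least one woody
    agent, not forest); mass aimed at ineligible cells is discarded.
    """
    production = np.asarray(production, dtype=float)
    if production.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("production array does not match the grid shape")
    nonzero = np.argwhere(production > 0.0)
    if nonzero.size == 0:
        return np.zeros_like(production)

    if len(nonzero) <= 64:
        inner = _window_sum(production, nonzero, kernel.inner, grid)
        outer = _window_sum(production, nonzero, kernel.outer, grid)
    else:
        inner = np.clip(signal.fftconvolve(production, kernel.inner, mode="same"), 0.0, None)
        outer = np.clip(signal.fftconvolve(production, kernel.outer, mode="same"), 0.0, None)
    if gated:
        outer = outer * _eligibility_mask(grid)
    return inner + outer


def _window_sum(production, nonzero, weights, grid) -> np.ndarray:
    """Direct kernel placement for a small number of source cells."""
    out = np.zeros_like(production)
    r = (weights.shape[0] - 1) // 2
    nr, nc = grid.n_rows, grid.n_cols
    for row, col in nonzero:
        n = production[row, col]
        r0, r1 = max(0, row - r), min(nr, row + r + 1)
        c0, c1 = max(0, col - r), min(nc, col + r + 1)
        out[r0:r1, c0:c1] += n * weights[
            r0 - row + r : r1 - row + r, c0 - col + r : c1 - col + r
        ]
    return out


def disperse(
    grid: LandscapeGrid,
    source: Cell,
    n_seeds: float,
    kernel: DispersalKernel,
) -> np.ndarray:
    """Disperse ``n_seeds`` from one source cell; return per-cell increments.

    The increments are a staging buffer: predator loss and grass inhibition
    are applied by :func:`seedbank_input` before anything enters a bank.
    """
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    production = np.zeros((grid.n_rows, grid.n_cols))
    production[source.row, source.col] = n_seeds
    return disperse_production(grid, production, kernel, gated=_is_gated(kernel))


def _is_gated(kernel: DispersalKernel) -> bool:
    # The kernel does not carry the flag; resolve it from the species name
    # so the stand-alone entry point behaves like the engine path.
    from .species import default_woody_species

    sp = default_woody_species().get(kernel.species_name)
    return bool(sp and sp.zoochory_gated)


# -- seed bank ---------------------------------------------------------------

def grass_inhibition(
    cell: Cell,
    species: WoodySpeciesParams,
    herb_species: dict,
) -> float:
    """Total grass inhibition T ∈ [0, 1] for a woody species in a cell.

    Each grass species' cover passes through the sigmoid
    ``s(c) = 1 / (1 + (c / I50)**S)`` (S < 0, so s(0)=0, s(I50)=0.5 and s
    increases towards 1); the per-species factors are summed and clamped at
    one.  Mown or grazed cells have a weaker sward: total inhibition is
    reduced by 30%.
    """
    total = 0.0
    for name, hs in herb_species.items():
        if not hs.is_grass:
            continue
        c = cell.herb_cover.get(name, 0.0)
        if c > 0.0:
            total += 1.0 / (1.0 + (c / species.i50) ** species.s)
    t = min(1.0, total)
    if cell.managed:
        t *= 0.7
    return t


def seedbank_input(
    cell: Cell,
    incoming: float,
    species: WoodySpeciesParams,
    inhibition: float = 0.0,
) -> float:
    """Add incoming seeds to the bank after predator loss and inhibition.

    ``N_sb = N_in * (1 - P_loss) * (1 - T)``; returns the number added.
    """
    if incoming < 0:
        raise ValueError("incoming seed count must be >= 0")
    added = incoming * (1.0 - species.p_loss) * (1.0 - inhibition)
    cell.seed_bank[species.name] = cell.seed_bank.get(species.name, 0.0) + added
    return added


def seedbank_decay(cell: Cell, species: WoodySpeciesParams, dt: float = 1.0) -> float:
    """Exponential seed-bank decay ``N ← N·exp(-λ·dt)``; returns the new N."""
    n = cell.seed_bank.get(species.name, 0.0) * math.exp(-species.decay_rate * dt)
    cell.seed_bank[species.name] = n
    return n


# -- germination -------------------------------------------------------------

def _largest_remainder(counts: dict[str, int], cap: int, order: list[str]) -> dict[str, int]:
    """Allocate ``cap`` seedlings proportionally with largest remainders.

    Ties are broken by the species order in the configuration table.
    """
    total = sum(counts.values())
    if total <= cap:
        return dict(counts)
    shares = {n: cap * counts[n] / total for n in counts}
    alloc = {n: math.floor(shares[n]) for n in counts}
    rest = cap - sum(alloc.values())
    ranked = sorted(counts, key=lambda n: (-(shares[n] - alloc[n]), order.index(n)))
    for n in ranked[:rest]:
        alloc[n] += 1
    return alloc


def germinate(
    cell: Cell,
    species_table: dict[str, WoodySpeciesParams],
    rng: np.random.Generator,
    tree_cap: int = 35,
    broom_cap: int = 35,
) -> list:
    """Germinate seeds from the cell's bank into new agents.

    Candidate seedlings per species are ``floor(N·Germ)``; producing them
    draws ``candidates / Germ`` seeds from the bank.  Realized recruits are
    capped at ``tree_cap`` across the tree species (largest-remainder
    proportional allocation) plus ``broom_cap`` for broom, and are zero for
    a guild whose available space is exhausted.  The surplus
    (candidates − realized) is booked per species on the cell for the
    browsing budget.  Returns the list of newly instantiated agents (also
    appended to the cell).
    """
    from .agents import WoodyAgent, available_space

    order = list(species_table.keys())
    candidates: dict[str, int] = {}
    for name in order:
        sp = species_table[name]
        n = cell.seed_bank.get(name, 0.0)
        cand = math.floor(n * sp.germ)
        if cand > 0:
            cell.seed_bank[name] = max(0.0, n - cand / sp.germ)
        candidates[name] = cand

    tree_names = [n for n in order if not species_table[n].is_broom]
    broom_names = [n for n in order if species_table[n].is_broom]

    realized: dict[str, int] = {n: 0 for n in order}
    if available_space(cell, "tree") > 0.0:
        tree_cands = {n: candidates[n] for n in tree_names if candidates[n] > 0}
        realized.update(_largest_remainder(tree_cands, tree_cap, order))
    if available_space(cell, "broom") > 0.0:
        broom_total = sum(candidates[n] for n in broom_names)
        if broom_total > 0:
            broom_cands = {n: candidates[n] for n in broom_names if candidates[n] > 0}
            realized.update(_largest_remainder(broom_cands, broom_cap, order))

    new_agents = []
    for name in order:
        cell.surplus[name] = cell.surplus.get(name, 0.0) + candidates[name] - realized[name]
        for _ in range(realized[name]):
            new_agents.append(WoodyAgent.seedling(species_table[name], rng))
    cell.agents.extend(new_agents)
    return new_agents
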