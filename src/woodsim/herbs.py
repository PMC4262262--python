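"""Cover dynamics of the herbaceous layer.

Grasses, tufted plants and the vegetatively spreading thorny shrubs
(bramble, blackthorn) are modelled as per-cell cover pools iterated in daily
increments.  This module is a deliberately minimal stand-in for the full
herbaceous reference model; its hard obligations towards the woody model
are (i) grass covers feeding the seed-bank inhibition, (ii) bramble and
blackthorn covers feeding nurse protection and broom space competition, and
(iii) decades-scale replacement of a fallow sward by the thorny shrubs.

Growth is logistic in the free herbaceous space.  Grasses and herbs can only
occupy space left by every other species, while the thorny shrubs overtop
and displace grasses (they are limited only by tree/broom cover and by other
thorny shrubs).  A configurable fraction of each day's growth spills into
the four orthogonal neighbour cells, which lets closed bramble and
blackthorn thickets advance into adjacent grassland.  Management (cutting,
grazing, trampling intensities crossed with the utilization indicator
values) removes cover from intolerant species.
"""

from __future__ import annotations

import numpy as np

from .grid import Cell, LandscapeGrid
from .species import HerbSpeciesParams

__all__ = [
    "herb_step",
    "herb_year",
    "remove_herb_cover",
    "reclaim_space",
    "suppression_coefficient",
]

#: Utilization midpoint: species with U below it are suppressed by management.
_U_MID = 5.0


def suppression_coefficient(sp: HerbSpeciesParams) -> tuple[float, float, float]:
    """Per-channel management sensitivity in [0, 1] (cutting, grazing, trampling)."""
    return tuple(max(0.0, (_U_MID - u) / (_U_MID - 1.0)) for u in (sp.u_c, sp.u_g, sp.u_t))


def _daily_updates(
    cover: np.ndarray,          # (S, ...) covers [m²]
    species: list[HerbSpeciesParams],
    h_space: np.ndarray,        # (...) herbaceous space [m²]
    i_c: np.ndarray,
    i_g: np.ndarray,
    i_t: np.ndarray,
    dt_days: float,
    spill_frac: float,
    suppression_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One daily increment: return (local cover change, spill per species).

    The spill array is the growth fraction exported to neighbours; the
    caller distributes it (a quarter per orthogonal neighbour) and applies
    the space caps afterwards.
    """
    thorny = np.array([sp.is_thorny_shrub for sp in species])
    gmax = np.array([sp.g_max for sp in species])
    fs = np.array([sp.f_s for sp in species])
    shape = (-1,) + (1,) * (cover.ndim - 1)

    total = cover.sum(axis=0)
    thorny_total = cover[thorny].sum(axis=0) if thorny.any() else np.zeros_like(total)
    free_grass = np.clip(h_space - total, 0.0, None)
    free_thorny = np.clip(h_space - thorny_total, 0.0, None)
    free = np.where(thorny.reshape(shape), free_thorny, free_grass)

    pot = (gmax.reshape(shape) / 365.0) * cover * free / fs.reshape(shape) * dt_days
    spill = spill_frac * pot
    local = pot - spill

    coeff = np.array([suppression_coefficient(sp) for sp in species])  # (S, 3)
    supp = (
        coeff[:, 0].reshape(shape) * i_c
        + coeff[:, 1].reshape(shape) * i_g
        + coeff[:, 2].reshape(shape) * i_t
    ) / 100.0
    loss = cover * (suppression_rate / 365.0) * supp * dt_days
    return local - loss, spill


def _apply_space_caps(
    cover: np.ndarray, species: list[HerbSpeciesParams], h_space: np.ndarray
) -> np.ndarray:
    """Scale covers so that thorny shrubs fit H_space and grasses the rest.

    Thorny shrubs displace grasses: when the sum of all covers exceeds the
    herbaceous space, the non-thorny species are scaled down first; the
    thorny shrubs themselves are bounded by the herbaceous space.
    """
    cover = np.clip(cover, 0.0, None)
    thorny = np.array([sp.is_thorny_shrub for sp in species])
    shape = (-1,) + (1,) * (cover.ndim - 1)

    if thorny.any():
        thorny_total = cover[thorny].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(thorny_total > h_space, h_space / np.where(thorny_total > 0, thorny_total, 1.0), 1.0)
        cover = np.where(thorny.reshape(shape), cover * f, cover)
        thorny_total = cover[thorny].sum(axis=0)
    else:
        thorny_total = np.zeros_like(h_space)

    grass_total = cover[~thorny].sum(axis=0) if (~thorny).any() else np.zeros_like(h_space)
    room = np.clip(h_space - thorny_total, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(grass_total > room, room / np.where(grass_total > 0, grass_total, 1.0), 1.0)
    cover = np.where(thorny.reshape(shape), cover, cover * f)
    return cover


def herb_step(
    cell: Cell,
    neighbors: tuple[Cell, ...] = (),
    species: dict[str, HerbSpeciesParams] | None = None,
    dt_days: float = 1.0,
    spill_frac: float = 0.2,
    suppression_rate: float = 1.0,
) -> None:
    """Advance one cell's herb covers by ``dt_days`` days (in place).

    Growth spilling out of the cell is deposited into the given orthogonal
    neighbours (one quarter of the spill per neighbour; the share of missing
    neighbours at the landscape edge is lost).
    """
    if species is None:
        from .species import default_herb_species

        species = default_herb_species()
    names = list(species.keys())
    splist = [species[n] for n in names]
    cover = np.array([cell.herb_cover.get(n, 0.0) for n in names], dtype=float)
    if (cover < 0).any():
        raise ValueError("negative herb cover")
    h_space = np.array(cell.herbaceous_space)
    delta, spill = _daily_updates(
        cover, splist,
        h_space,
        np.array(cell.i_c), np.array(cell.i_g), np.array(cell.i_t),
        dt_days, spill_frac, suppression_rate,
    )
    cover = _apply_space_caps(cover + delta, splist, h_space)
    for n, c in zip(names, cover):
        cell.herb_cover[n] = float(c)
    for nb in neighbors[:4]:
        for n, s in zip(names, spill):
            if s > 0:
                nb.herb_cover[n] = nb.herb_cover.get(n, 0.0) + float(s) / 4.0
        # keep the neighbour inside its own space bound
        reclaim_space(nb)


def herb_year(
    grid: LandscapeGrid,
    species: dict[str, HerbSpeciesParams],
    steps: int = 365,
    spill_frac: float = 0.2,
    suppression_rate: float = 1.0,
) -> None:
    """Run the daily herb-layer loop for one year over the whole grid.

    Vectorized equivalent of calling :func:`herb_step` cell by cell; woody
    cover (and hence the herbaceous space) is held constant within the year,
    matching the annual scheduling of all woody processes.
    """
    names = list(species.keys())
    splist = [species[n] for n in names]
    nr, nc = grid.n_rows, grid.n_cols

    cover = np.zeros((len(names), nr, nc))
    h_space = np.zeros((nr, nc))
    i_c = np.zeros((nr, nc))
    i_g = np.zeros((nr, nc))
    i_t = np.zeros((nr, nc))
    for cell in grid.iter_cells():
        r, c = cell.row, cell.col
        for k, n in enumerate(names):
            cover[k, r, c] = cell.herb_cover.get(n, 0.0)
        h_space[r, c] = cell.herbaceous_space
        i_c[r, c], i_g[r, c], i_t[r, c] = cell.i_c, cell.i_g, cell.i_t

    if (cover < 0).any():
        raise ValueError("negative herb cover")
    if not cover.any():
        return  # nothing can grow from zero cover

    for _ in range(steps):
        delta, spill = _daily_updates(
            cover, splist, h_space, i_c, i_g, i_t, 1.0, spill_frac, suppression_rate
        )
        gain = np.zeros_like(cover)
        q = spill / 4.0
        gain[:, 1:, :] += q[:, :-1, :]   # from the cell above
        gain[:, :-1, :] += q[:, 1:, :]   # from below
        gain[:, :, 1:] += q[:, :, :-1]   # from the left
        gain[:, :, :-1] += q[:, :, 1:]   # from the right
        cover = _apply_space_caps(cover + delta + gain, splist, h_space)

    for cell in grid.iter_cells():
        r, c = cell.row, cell.col
        for k, n in enumerate(names):
            cell.herb_cover[n] = float(cover[k, r, c])


def remove_herb_cover(cell: Cell, fraction: float) -> None:
    """Remove a fraction of every herb species' cover (boar disturbance)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    for name in cell.herb_cover:
        cell.herb_cover[name] *= 1.0 - fraction


def reclaim_space(cell: Cell) -> None:
    """Scale herb covers down proportionally to fit the herbaceous space.

    Called after woody growth: space newly covered by trees and broom is no
    longer available to the herb layer.
    """
    total = cell.herb_total
    h_space = cell.herbaceous_space
    if total > h_space:
        factor = h_space / total if total > 0 else 0.0
        for name in cell.herb_cover:
            cell.herb_cover[name] *= factor
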