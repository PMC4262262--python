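"""Species parameter tables for the woody and herbaceous layers.

Woody species (birch, broom, beech, spruce, oak) carry the full life-cycle
parameter set: Bertalanffy height growth, crown and twig allometries, the
double-exponential dispersal kernel quantiles, seed production and seed-bank
constants, browsing mortality and the grass-inhibition sigmoid.  Herbaceous
species (grasses, tufted plants and the vegetatively spreading thorny shrubs
bramble and blackthorn) carry the cover-dynamics parameters of the
difference-equation layer plus the management utilization indicator values.

Parameters can be round-tripped through plain CSV tables so that scenarios
may swap in alternative parameterizations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import pandas as pd

__all__ = [
    "WoodySpeciesParams",
    "HerbSpeciesParams",
    "default_woody_species",
    "default_herb_species",
    "woody_species_from_csv",
    "woody_species_to_csv",
    "herb_species_from_csv",
    "herb_species_to_csv",
    "BRAMBLE",
    "BLACKTHORN",
]

#: Herb-layer species names with a structural role in the woody model.
BRAMBLE = "bramble"
BLACKTHORN = "blackthorn"


@dataclass(frozen=True)
class WoodySpeciesParams:
    """Per-species constants of an individually modelled bush or tree.

    Units: heights in m, ages in years, rates per year, covers in m²,
    dispersal distances in m.  ``p_ed`` is the probability mass of the
    dispersal kernel inside the effective seeding distance (fraction).
    ``a_biom_*`` (twig biomass allometry) and ``brow_mort`` are absent for
    broom, which is not browsed.  ``s`` is the (negative) slope of the
    grass-inhibition sigmoid.
    """

    name: str
    g_mean: float          # mean height growth rate [1/a]
    g_sd: float            # growth-rate standard deviation [1/a]
    h_max: float           # asymptotic height [m]
    h_ini: float           # seedling height at germination [m]
    a_max: float           # maximal age [a]
    a_mat: float           # age of maturity [a]
    a_cd_const: float      # crown-diameter allometry D = const * H**coeff
    a_cd_coeff: float
    ed: float              # effective seeding distance [m]
    md: float              # maximum seeding distance [m]
    p_ed: float            # kernel mass within ED [-]
    seed_max: float        # maximal annual seed production per individual
    p_loss: float          # seed loss to unspecific predators [-]
    germ: float            # germination rate [-]
    decay_rate: float      # seed-bank exponential decay constant [1/a]
    i50: float             # grass cover causing 50% inhibition [m²]
    s: float = -10.0       # inhibition sigmoid slope [-]
    a_biom_const: float | None = None   # twig biomass B = const * L**coeff
    a_biom_coeff: float | None = None
    brow_mort: float | None = None      # annual browsing-induced mortality
    zoochory_gated: bool = False        # jay-dispersed mass beyond ED gated
    is_broom: bool = False              # bush guild (vs. tree guild)
    browse_rank: int | None = None      # 1 = most preferred; None = unbrowsed

    def __post_init__(self) -> None:
        if not 0.0 < self.h_ini < self.h_max:
            raise ValueError(f"{self.name}: need 0 < h_ini < h_max")
        if not 0.0 < self.a_mat < self.a_max:
            raise ValueError(f"{self.name}: need 0 < a_mat < a_max")
        if not 0.0 <= self.p_loss <= 1.0:
            raise ValueError(f"{self.name}: p_loss outside [0, 1]")
        if not 0.0 <= self.germ <= 1.0:
            raise ValueError(f"{self.name}: germ outside [0, 1]")
        if not 0.0 < self.ed <= self.md:
            raise ValueError(f"{self.name}: need 0 < ED <= MD")
        if not 0.0 < self.p_ed <= 1.0:
            raise ValueError(f"{self.name}: p_ed outside (0, 1]")
        if self.decay_rate < 0.0:
            raise ValueError(f"{self.name}: decay_rate must be >= 0")
        if self.i50 <= 0.0:
            raise ValueError(f"{self.name}: i50 must be > 0")

    def height_at(self, age: float) -> float:
        """Deterministic Bertalanffy height at a given age (mean growth rate).

        H(t) = H_max - (H_max - H_ini) * exp(-G t); the stochastic annual
        step in :mod:`woodsim.agents` integrates to exactly this curve when
        the growth-rate draw equals its mean every year.
        """
        return self.h_max - (self.h_max - self.h_ini) * math.exp(-self.g_mean * age)


@dataclass(frozen=True)
class HerbSpeciesParams:
    """Cover-dynamics parameters of one herb-layer species.

    ``u_c``, ``u_g``, ``u_t`` are utilization indicator values (1-9) for
    cutting, grazing and trampling; low values mean the species is suppressed
    by that form of management.  ``g_max`` is the maximal vegetative growth
    rate [1/a], applied in daily increments; ``f_s`` the self-regulation
    factor.  Grasses (``is_grass``) feed the seed-bank inhibition sum, the
    thorny shrubs bramble and blackthorn (``is_thorny_shrub``) feed nurse
    protection and broom space competition.
    """

    name: str
    u_c: float
    u_g: float
    u_t: float
    g_max: float
    f_s: float
    is_grass: bool = False
    is_thorny_shrub: bool = False

    def __post_init__(self) -> None:
        if self.g_max <= 0.0:
            raise ValueError(f"{self.name}: g_max must be > 0")
        if self.f_s <= 0.0:
            raise ValueError(f"{self.name}: f_s must be > 0")
        for u in (self.u_c, self.u_g, self.u_t):
            if not 1.0 <= u <= 9.0:
                raise ValueError(f"{self.name}: utilization values lie in [1, 9]")


def default_woody_species() -> dict[str, WoodySpeciesParams]:
    """The five reference species with their published parameter values."""
    sp = [
        WoodySpeciesParams(
            name="birch", g_mean=0.03, g_sd=0.007, h_max=30.0, h_ini=0.05,
            a_max=100, a_mat=15, a_cd_const=1.146, a_cd_coeff=0.791,
            a_biom_const=0.0044, a_biom_coeff=1.247,
            ed=200.0, md=700.0, p_ed=0.95, seed_max=11_775_000,
            p_loss=0.8, germ=0.1, decay_rate=0.36, brow_mort=0.1,
            i50=29.0, browse_rank=2,
        ),
        WoodySpeciesParams(
            name="broom", g_mean=0.3, g_sd=0.04, h_max=3.7, h_ini=0.05,
            a_max=12, a_mat=4, a_cd_const=0.945, a_cd_coeff=1.236,
            ed=10.0, md=500.0, p_ed=0.97, seed_max=10_000,
            p_loss=0.8, germ=0.8, decay_rate=0.063,
            i50=26.1, is_broom=True,
        ),
        WoodySpeciesParams(
            name="beech", g_mean=0.024, g_sd=0.002, h_max=45.0, h_ini=0.05,
            a_max=350, a_mat=50, a_cd_const=0.716, a_cd_coeff=1.073,
            a_biom_const=0.0250, a_biom_coeff=2.180,
            ed=30.0, md=200.0, p_ed=0.99, seed_max=29_000,
            p_loss=0.8, germ=0.7, decay_rate=0.6, brow_mort=0.2,
            i50=29.5, zoochory_gated=True, browse_rank=3,
        ),
        WoodySpeciesParams(
            name="spruce", g_mean=0.021, g_sd=0.002, h_max=45.0, h_ini=0.05,
            a_max=500, a_mat=45, a_cd_const=0.880, a_cd_coeff=0.877,
            a_biom_const=0.1292, a_biom_coeff=2.569,
            ed=70.0, md=250.0, p_ed=0.95, seed_max=96_500,
            p_loss=0.8, germ=0.75, decay_rate=0.46, brow_mort=0.1,
            i50=29.3, browse_rank=4,
        ),
        WoodySpeciesParams(
            name="oak", g_mean=0.028, g_sd=0.004, h_max=35.0, h_ini=0.05,
            a_max=800, a_mat=50, a_cd_const=1.144, a_cd_coeff=0.929,
            a_biom_const=0.8172, a_biom_coeff=3.746,
            ed=30.0, md=200.0, p_ed=0.99, seed_max=27_500,
            p_loss=0.8, germ=0.75, decay_rate=0.81, brow_mort=0.2,
            i50=29.8, zoochory_gated=True, browse_rank=1,
        ),
    ]
    return {s.name: s for s in sp}


def default_herb_species() -> dict[str, HerbSpeciesParams]:
    """Herb-layer species of the grassland mosaic.

    Bramble and blackthorn use their published utilization and growth
    constants.  The grasses and tufted plants are a documented stand-in for
    the full herbaceous reference model: their utilization values follow the
    species' known management tolerances, and the grass growth rate is set so
    that a sward disturbed by wild boar closes again within one to two
    seasons while the thorny shrubs need decades to replace a fallow sward
    (see docs/methods.md).
    """
    sp = [
        # grasses of the hay meadows, pastures and fallows
        HerbSpeciesParams("red_fescue", 7, 8, 7, 300.0, 15000.0, is_grass=True),
        HerbSpeciesParams("tall_oat", 7, 4, 4, 300.0, 15000.0, is_grass=True),
        HerbSpeciesParams("cocksfoot", 7, 6, 5, 300.0, 15000.0, is_grass=True),
        HerbSpeciesParams("common_velvet", 6, 6, 5, 300.0, 15000.0, is_grass=True),
        HerbSpeciesParams("crested_dogstail", 7, 8, 8, 300.0, 15000.0, is_grass=True),
        HerbSpeciesParams("perennial_rye", 8, 9, 9, 300.0, 15000.0, is_grass=True),
        # perennial tufted plants: counted in the inhibition sum
        HerbSpeciesParams("tufted_plants", 3, 4, 4, 150.0, 15000.0, is_grass=True),
        # vegetatively spreading thorny shrubs
        HerbSpeciesParams(BRAMBLE, 2, 3, 3, 4.7, 15000.0, is_thorny_shrub=True),
        HerbSpeciesParams(BLACKTHORN, 3, 5, 9, 4.7, 15000.0, is_thorny_shrub=True),
    ]
    return {s.name: s for s in sp}


# -- CSV round trips ---------------------------------------------------------

def woody_species_to_csv(species: dict[str, WoodySpeciesParams], path) -> None:
    rows = [{f.name: getattr(s, f.name) for f in fields(s)} for s in species.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


def woody_species_from_csv(path) -> dict[str, WoodySpeciesParams]:
    df = pd.read_csv(path)
    out: dict[str, WoodySpeciesParams] = {}
    for rec in df.to_dict(orient="records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in rec.items()}
        for key in ("zoochory_gated", "is_broom"):
            clean[key] = bool(clean.get(key))
        if clean.get("browse_rank") is not None:
            clean["browse_rank"] = int(clean["browse_rank"])
        p = WoodySpeciesParams(**clean)
        out[p.name] = p
    return out


def herb_species_to_csv(species: dict[str, HerbSpeciesParams], path) -> None:
    rows = [{f.name: getattr(s, f.name) for f in fields(s)} for s in species.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


def herb_species_from_csv(path) -> dict[str, HerbSpeciesParams]:
    df = pd.read_csv(path)
    out: dict[str, HerbSpeciesParams] = {}
    for rec in df.to_dict(orient="records"):
        rec["is_grass"] = bool(rec.get("is_grass"))
        rec["is_thorny_shrub"] = bool(rec.get("is_thorny_shrub"))
        p = HerbSpeciesParams(**rec)
        out[p.name] = p
    return out


def with_overrides(params: WoodySpeciesParams, **changes) -> WoodySpeciesParams:
    """Return a copy of *params* with selected fields replaced."""
    return replace(params, **changes)
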