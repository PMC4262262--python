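# woodsim

A spatially explicit, raster-based simulator of woody-species encroachment
on temperate semi-natural grasslands.  It couples an individual-based model
of bushes and trees (birch, broom, beech, spruce, oak) with a cover-based
herbaceous layer, and adds the two wildlife pressures that shape succession
on abandoned grassland: wild-boar soil disturbance and a density-dependent
red-deer browsing budget moderated by thorny nurse shrubs (blackthorn,
bramble).  It is aimed at ecologists and land managers who want to explore
how management regimes, deer densities and initial vegetation composition
steer grassland-to-woodland succession on decadal time scales.

## Model core

The landscape is a grid of 100 m² cells.  Within a year:

- **Seed rain.** Each mature individual produces `Seed_max · m` seeds, where
  the mast fraction `m` is drawn from one of four year classes
  ({0}, [0.1, 0.4], [0.4, 0.7], [0.7, 1.0]).  Seeds travel along a
  double-exponential distance law fixed by the effective seeding distance
  ED (holding the fraction `p_ED` of seeds) and the maximum distance MD,
  discretized over sink cells so the kernel sums to one.  Acorns and
  beechnuts dispersed beyond ED (jay caching) only land in cells holding at
  least one bush or tree that are not forest.
- **Seed bank.** Input is thinned by predators and by grass:
  `N_sb = N_in (1 − P_loss)(1 − I)` with the inhibition
  `I = min(1, Σᵢ 1/(1 + (cᵢ/I₅₀)^S))` summed over grass covers cᵢ
  (S = −10; mown/grazed cells: `I ← 0.7·I`).  Banks decay as
  `dN/dt = −λN`.  A fraction `Germ` of the bank germinates yearly, capped
  at 35 tree + 35 broom seedlings per cell; the surplus feeds browsing.
- **Growth and competition.** Heights follow the Bertalanffy step
  `ΔH = (H_max − H)(1 − e^{−g})`, `g ~ N(G, σ_G)`; crowns are allometric,
  `D = a·H^b`, cover `C = π(D/2)²`.  When crowns overfill a cell the
  smallest individual dies (broom first — it also competes with bramble and
  blackthorn; trees only with trees).  Individuals die at a maximum age
  jittered ±10%; mowing kills saplings between 0.1 and 1 m.
- **Browsing.** A standard deer (herd-mean mass 59.29 kg) demands
  `(dsd·sdays + dwd·wdays)(sdeer/100)·frw = 157.46 kg dw a⁻¹` of woody
  browse; demand is spread evenly over cells and reduced by a sigmoid
  nurse-shrub factor.  Bites of 0.1 m branch convert to biomass via twig
  allometry and are taken from surplus seedlings, then from standing trees
  (oak ≻ birch ≻ beech ≻ spruce, ≤ 5 m tall) until the cell demand is met.
  Browsed trees ≤ 1.7 m stop growing and may die; trees < 0.2 m die at
  once.
- **Herb layer.** Grass and shrub covers grow logistically in daily
  increments within the space not taken by woody crowns; bramble and
  blackthorn displace grasses and spill into neighbour cells, management
  suppresses intolerant species.

## Worked example

The classic experiment: 1 ha of bare ground, one mature birch in the
center, no grass inhibition, no deer.

```
$ woodsim scenario single-parent --species birch --years 25 --seed 1 --out out/
birch: cover 87.6% of the area after 25 years (236 individuals)
```

`out/cover_timeseries.csv` holds the annual per-species totals — birch
cover climbs from the parent's 45 m² crown to > 9 000 m² of the 10 000 m²
landscape within a few years, after which iterative self-thinning keeps the
stand hovering below full packing (the 87.6% above is such a post-thinning
year; the run's maximum exceeds 98%).  `out/vegtype_final.asc` is an Esri
ASCII raster of the final vegetation types (1 grassland, 2 fallow, 3 shrub,
4 forest, 5 disturbed ground).  Running the same command with
`--species beech` caps at 29% cover — exactly the 29 cells within the 30 m
effective seeding distance, since an empty neighborhood attracts no jays.

The same experiments are available from Python:

```python
from woodsim.scenarios import single_parent_trajectory
traj = single_parent_trajectory("beech", seed=1, years=25)
print(traj.tail(1))   #  year 25: fraction 0.29, 29 individuals
```

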