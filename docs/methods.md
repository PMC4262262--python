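# Methods

## Model overview and assumptions

`woodsim` simulates grassland-to-woodland succession on a raster of 100 m²
cells.  Woody plants are individual agents with height, age, crown and a
browsed flag; the herbaceous layer is a set of per-cell cover pools.  Space
is the single contested resource: crowns exclude herbs, trees exclude
trees, and broom is additionally excluded by trees, bramble and blackthorn.
There is no vertical light competition, no within-forest succession, no
seasonality, and deer density is constant in space and time.  All woody
processes run annually; only the herb layer iterates in daily increments.

The annual schedule is: boar disturbance → daily herb loop → seed
production and dispersal → inhibition-filtered seed-bank input → bank decay
→ germination (caps, surplus) → browsing → growth → mowing kill →
self-thinning → senescence and browsing mortality → space reclamation and
vegetation typing.  The order is centralized in `engine.run_year`;
browsing precedes growth so that a browsed sapling's zero-growth year is
expressible, and decay follows input so fresh seeds face one winter in the
bank before their first germination opportunity.  Randomness flows through
six named substreams spawned from the master seed and is consumed in
row-major cell order, so runs are bit-reproducible and insensitive to
toggling individual processes off.

## Parameters that matter

Per woody species (defaults in `species.default_woody_species`): growth
rate G ± σ_G [a⁻¹] and asymptotic height H_max [m] (Bertalanffy), maximal
age A_max [a] (individually jittered ±10%, uniform), age of maturity A_mat,
crown allometry (D = a·H^b), twig-biomass allometry for browsing, dispersal
quantiles ED/MD/p_ED [m, m, –], seed constants (Seed_max per individual and
year, predator loss P_loss = 0.8, germination rate Germ, bank decay λ
[a⁻¹]), browsing mortality, and the inhibition sigmoid (I₅₀ ≈ 26–30 m²,
slope S = −10).  The birch germination rate is stored already halved (0.1)
to stand in for the density-dependent seedling mortality the model omits.

Red-deer demand (defaults in `wildlife.BrowserParams`): 2.5/3.0 kg dw per
100 kg deer and day over 214 summer/152 winter days, woody diet fraction
0.268, herd 5×105 + 10×70 + 20×42.5 kg.  These yield 157.46 kg dw a⁻¹ per
standard deer; note the day counts sum to 366, which is what that printed
total requires, so they are kept as-is.  Browsing geometry: 0.1 m bite,
browsing ceiling 1.7 m, forage ceiling 5 m, instant death below 0.2 m.

## Design choices at open points

Several component equations of the original formulation are only available
as qualitative constraints; the concrete forms below are this package's
choices, each injectable or configurable:

- **Dispersal kernel.**  The double-exponential distance law is built as
  an exponential truncated to [0, ED] mixed (weight p_ED) with an
  exponential restricted to (ED, MD]; both rates are −ln(1 − p_ED)/ED and
  /MD, so the kernel is fully fixed by the published quantiles.  For the
  grid, the 1-D law is converted to the isotropic planar density
  f(r)/(2πr), sampled at cell centroids (the source cell receives the
  central half-cell disc) and renormalized.  This conversion is what makes
  the *cell-sum* within ED equal p_ED; evaluating the 1-D density directly
  per cell would shift roughly a quarter of the mass outward.  Per-cell
  weights are strictly non-increasing with distance.
- **Inhibition sigmoid.**  s(c) = 1/(1 + (c/I₅₀)^S) with S = −10
  satisfies s(0) = 0, s(I₅₀) = 0.5, monotone increase; species factors are
  summed and clamped at 1; the management reduction multiplies the total by
  0.7.
- **Available browse.**  aB(H) = (π·D(min(H, 1.7))/bite length) ·
  B(bite length): bite events along the crown circumference of the
  browsable stratum, with a continuous event count so aB → 0 as H → 0 and
  aB is flat between 1.7 and 5 m.  An alternative literature curve can be
  injected via `BrowserParams.supply`.
- **Nurse factor.**  Two decreasing Hill sigmoids (half-protection at
  25 m² blackthorn, 50 m² bramble; slope 4) combined multiplicatively.
  These half-covers are package defaults, not literature values.
- **Mast classes** are drawn uniformly (¼ each) by default.
- **Germination accounting.**  candidates = ⌊N·Germ⌋ consume
  candidates/Germ seeds from the bank; the 35-place tree cap is allocated
  across species by largest remainder (ties by table order); candidates in
  a space-exhausted guild all become browsing surplus.
- **Self-thinning guard.**  The iterative removal never deletes the last
  tree of a cell: a solitary mature crown (e.g. beech, ≈ 660 m² at
  maturity) legitimately overhangs its 100 m² cell.
- **Boar selection** uses independent Bernoulli draws per cell (10%
  meadows/pastures, 3% shrub, 1% fallow), not exact quotas.
- **Mowing window** [0.1 m, 1 m] is closed on both ends.

## The herb-layer stand-in

The full herbaceous reference model is out of scope; `woodsim.herbs`
implements the minimal contract the woody model needs.  Growth is logistic
in free herbaceous space with daily increments of g_max·c·free/F_S/365;
thorny shrubs (bramble, blackthorn: g_max = 4.7 a⁻¹, F_S = 15 000,
utilization values from their published table) overtop grasses and spill
20% of their daily growth into orthogonal neighbours, giving
decades-scale replacement of a fallow sward (≈ 40 years from a quarter-cell
bramble patch to half the cell) and thicket advance into grassland.  The
grasses' g_max is not published; it is set to 300 a⁻¹ so a boar-disturbed
sward (−45%) closes again within one to two seasons.  Management crosses
the cutting/grazing/trampling intensities with the utilization values:
species below the tolerance midpoint (U < 5) lose cover at a rate
proportional to intensity.  The stand-in reproduces the coupling
obligations (grass covers → inhibition, thorny covers → nurse factor and
broom competition, slow fallow takeover), not the floristics of real
swards; conclusions about species composition of the herb layer are
outside what passing tests support.

## What the synthetic scenarios do and do not show

The single-parent experiment (10×10 cells, one mature individual, bare or
grass-saturated sward, optional deer) probes dispersal, recruitment,
growth and competition jointly.  Reproduced behaviors: beech confined to
exactly the 29 cells within its 30 m effective distance (29% maximum
cover) because zoochorous transport needs woody sink cells; broom
populations oscillating on the scale of their 12-year lifespan; a
grass-saturated fallow gaining no forest cells beyond the parent's over 40
years; forest development non-increasing in deer density.

Two quantitative deviations are measured and deliberate, not calibrated
away: with the tabulated per-individual seed crops (birch ≈ 1.2 × 10⁷
seeds a⁻¹), every 1-ha cell saturates its 35-seedling cap from the first
seed year, so the landscape closes in ~3 (birch) and ~11 (spruce) years
rather than the reported 12 and 16, and beech reaches its cover plateau
around year 15 rather than 22.  For the same reason the germination
surplus usually absorbs the entire per-cell browse demand before any
standing sapling is bitten, so at these seed levels deer density shifts
forest counts only where seeds are scarce.  The browsing machinery itself
(budget identity, preference order, instant and stochastic mortality,
nurse protection) is exercised directly in the test suite on stands
without surplus.

## Numerical notes

Seed banks are real-valued (kernels spread fractional proportions);
germination floors to whole seedlings.  Dispersal uses direct kernel
placement for ≤ 64 source cells and FFT convolution above that (clipped at
zero); kernel mass leaving the grid is lost.  Self-thinning ties (equal
smallest heights) remove the younger agent.  Growth draws are clipped at
zero.  The daily herb loop is vectorized over the grid; the per-cell
`herb_step` applies the same update and the two are tested for agreement.
Degenerate inputs (empty herds, negative covers, fractions outside [0, 1],
ED > MD, malformed rasters) raise errors rather than being silently
repaired.

Default problem sizes keep a full test run in the tens of seconds: 20
replicate 25-year runs per species for the encroachment medians, a
10,000-cell landscape for the disturbance rate, 40-year runs for the
fallow-persistence and oscillation checks.
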