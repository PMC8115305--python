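# Methods

## Model and assumptions

`windcea` accumulates the effects of offshore wind farm (OWF) pressures on
marine receptors per raster cell and calendar year. The score is a plain
product-sum — receptor density × sensitivity × weighted, spatially spread
activity — with no saturation, interaction or recovery terms: pressures
from overlapping farms add, a receptor hit twice is counted twice, and a
year's score does not depend on earlier years. These are the standard
assumptions of additive cumulative-effects mapping; they make the model
linear in each scorecard, which in turn makes percentage outputs invariant
to any global rescaling of weights or sensitivities.

All layers live on one regular grid in a planar equal-area reference
(coordinates in metres). No reprojection is performed; inputs must be
pre-projected, and the CRS is compared as an opaque tag.

## Lifecycle scheduling

Construction time is 1.06 days per MW of capacity (an explicit
`installation_days` column in the repository overrides the rule, logged);
operation lasts 20 years; decommissioning takes 50 % of the construction
time. Day counts convert to whole calendar years as `ceil(days/365)` with
a minimum of one year per phase — outputs are reported by year, and no
rounding rule finer than the year grid would be observable. Construction
is anchored backwards from the operation start year because repositories
record when farms start operating, not when building began. Farms without
a known operation start cannot be placed on the timeline and are excluded
with a logged reason. Phase intervals are half-open, so every (farm, year)
has exactly one status.

## Pressure propagation

Each pressure's ordinal propagation class (≤1 km, 5, 10, 20, ≥25 km) maps
to a kernel buffer radius (1, 5, 10, 20, 50 km). The kernel is a 2D
Gaussian with σ = radius/3, truncated at the radius (≈99.7 % of the
untruncated mass inside the buffer) and renormalized to unit sum. Unit-sum
rather than unit-peak taps are a deliberate contract: a wider buffer
redistributes a farm's pressure over more cells without creating more of
it, so total effect is independent of distance for a fixed activity mass.
Edges are zero-padded (pressure mass may leave the open study area). A
buffer smaller than the cell size degenerates to the identity kernel with
a warning. Propagation distance is per pressure, not per receptor;
`PhaseBundle`-level overrides can perturb it per run.

## Receptor layers and scorecards

Density and biomass layers are transformed with log[x+1] — damping the
right tail typical of modelled animal densities and catch-per-unit-effort
biomass — then min–max rescaled to [0, 1] over study-area cells only, so
land or no-data cells never set the range. A layer already spanning [0, 1]
with both endpoints attained is taken as pre-rescaled and passed through.
Habitat polygons burn to binary presence (any positive cell coverage
counts as presence; coverage-weighted occupancy was rejected because
presence/absence sources carry no abundance signal).

Sensitivity scores merge a literature value and an expert value: sources
more than 2 units apart are averaged (one of them is likely an outlier);
otherwise the higher value wins (precautionary principle). A gap of
exactly 2 also takes the max — the precautionary reading of a boundary the
rule itself leaves open. Confidence levels (0.2–1) attached to weights and
sensitivities do not move deterministic results; they only size the
perturbations of the uncertainty analysis.

## Accumulation, normalization, decomposition

Footprints rasterize by exact polygon–cell intersection areas (coverage
fraction), conserving area to floating precision. Within a phase a farm's
activity and propagated surfaces are static, so they are computed once per
(farm, phase, distance) and reused across years. Alongside the per-cell
maps the engine records an additive ledger at (year, farm, country, phase,
pressure, component) granularity whose entries sum exactly to the raster
totals; every marginal or cross-tabulated percentage is derived from this
ledger, never recomputed from rasters, which guarantees all published
tables agree with each other. Country attribution follows the source
farm's repository attribute, including for pressure mass a kernel pushes
across a boundary.

For mapping, the total raster is resampled onto a hexagonal lattice
(centroid spacing 10 km by default) by nearest-centroid assignment — a
partition of the cells, so mass is conserved — and grouped into five
classes (quantile scheme by default; the scheme and cut points are
recorded in the output metadata).

## Scenario projection

The forward scenario grows installed capacity at 33 %/year from the last
observed installation year, capped so the cumulative total reaches 212 GW
by 2050. Each added GW contributes through fitted per-phase rates — the
run's total phase score divided by its capacity-years in that phase — as
one construction year, 20 operation years, then one decommissioning year.
The projection is deliberately spatial-free: where future farms sit
dominates their score, and inventing locations would suggest precision the
method cannot have.

## Uncertainty analysis

Per phase, two input groups are perturbed: the propagation model (each
pressure's weight and distance) and the effect functions (each
pressure–receptor sensitivity). An input with confidence *c* is sampled
uniformly on base ± h, with h = (1 − c) × 2.5 for scores (half the [0, 5]
domain) and h = (1 − c) × base for distances, clipped to the legal domain;
confidence 1 pins the input, and its total order index is exactly zero by
construction (its hybrid matrix equals the base matrix).

The design is Saltelli's radial scheme (matrices A, B, and per-input
AB_i), sized so `n_base × (p + 2)` meets the requested budget of 5600 runs
per phase; base points come from a scrambled, seeded Sobol' sequence,
which converges much faster than plain pseudo-random sampling at this
budget. Total order indices use the Jansen estimator
`ST_i = mean[(f(A) − f(AB_i))²] / (2 Var[f])` with the variance pooled
over f(A) and f(B); confidence intervals bootstrap the base points. The
evaluated model is the scalar total score of a fixed phase bundle (one
convolution per pressure per run), keeping 5600 evaluations at desk
scale. Zero output variance is reported as degenerate rather than as
indices.

## Synthetic basin

The default generator emulates the structure of the real inputs at desk
scale: a 500 × 500 km basin of 10 km cells, 15 farms of 60–1200 MW placed
without overlap in 3 longitudinal EEZ bands, installation years 2001–2027,
footprint area 0.23 km²/MW (the ratio of a basin-scale OWF inventory's
area to its capacity), 18 pressures split 6/6/6 over the phases, and 12
receptors (3 binary EUNIS-style habitats, 3 seabirds, 1 mammal, 5 fish).
Bird/mammal fields are exponentiated smooth Gaussian fields; fish fields
are log-normal (heavier-tailed, like catch-per-unit-effort biomass) and go
through the standard log[x+1] + min–max path. Species fields are static
over time, as in assessments that use one distribution per species for
all years.

What the generator does **not** emulate: survey sampling bias, seasonal
migration and range shifts, correlations between receptor distributions
and bathymetry or distance to coast, and the clustered, irregular
footprint geometry of real farms. Passing tests on synthetic data
therefore demonstrate the correctness of the accumulation machinery and
its invariants — not that real-basin headline percentages would be
reproduced, which depend entirely on the real repository and receptor
rasters.

## Numerical choices

- Convolution via `scipy.signal.convolve` (auto method); FFT round-off
  below zero is clipped; equivalence to a direct double loop is tested at
  1e-9 relative.
- Min–max degenerate (constant) layers rescale to all-zero with a warning
  rather than erroring: an empty receptor is a valid, if useless, input.
- Classification of a constant surface collapses to a single class.
- Ledger CSVs are written with a stable sort order and fixed float format,
  so identical configs and seeds produce byte-identical files.
- Problem sizes in the test suite and acceptance script (grids ≤ 50×50,
  ≤ 20 farms, 5600-run sensitivity budgets) are chosen so a full run
  completes in seconds on one CPU while still exercising every code path
  at the study's real cell size and scorecard dimensions.

## Known limitations

- No pressures from other sectors (fishing, shipping, oil and gas) and no
  receptor recovery dynamics; scores are potential exposure-weighted
  effects, not measured population outcomes.
- Kernels are isotropic; advection by currents and frequency-dependent
  noise propagation are out of scope.
- Partial construction years count as full activity years — the year grid
  cannot resolve finer.
- The scenario projection inherits the fitted run's spatial configuration
  through its per-GW rates and says nothing about where future impacts
  would fall.
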