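# Methods

`sargasso` implements a complete desk-scale analysis linking the seasonal
morphotype composition of beach-stranded pelagic *Sargassum* to two oceanic
sub-origins / transport pathways: backward Lagrangian particle tracking on a
year-day surface-current climatology with windage and stochastic turbulence,
clustering of trajectory metrics into pathways, and restricted-permutation
multivariate tests of composition and environment between pathways.  This
note documents the models, their assumptions, the default parameters, and
what the synthetic test harness does and does not establish.

## Lagrangian tracking

Particles are advected by explicit Euler steps at Δt = 6 h, the native
cadence of drifter-derived current products.  The total drift velocity is

    V = V_current′ + w · V_wind10,

where w = 0.005 (0.5% windage, the standard leeway fraction for rafting
material) and V_current′ is the gridded current perturbed per step, per
particle, and per component by a Lagrangian stochastic model:

    u′ = u + c · s · Z_u,   v′ = v + c · s · Z_v,   s = √(u² + v²),

with c = 0.1 and Z independent standard normal draws.  The perturbation
scale is proportional to the local current speed, reflecting that the
gridded climatology is smoother than the real ocean.  Windage is applied to
the unperturbed wind.  Backward tracking reverses the sign of the total
velocity and runs the field's year-day clock backwards; no time-reversed
correction of the stochastic term is attempted (backtracking is understood
as the simple mirror of forward drift).

Displacements convert to degrees on a sphere of R = 6371 km:
Δlat = V_n Δt / (R π/180), Δlon = V_e Δt / (R π/180 cos φ).  Path lengths
accumulate great-circle (haversine) segment distances.  Particles whose
destination cell is land stall in place, are flagged grounded, and stay
frozen; particles reaching the domain edge are frozen there.  Grounded and
frozen particles remain in the ensemble and in the centre-of-mass origin
(the arithmetic mean of endpoint lon/lat, valid because the domain does not
span the antimeridian — asserted).  Both behaviours are configurable.

Each simulation draws its noise from one Philox counter-based generator
keyed by the simulation seed, with all particles' draws taken as one array
per step: rerunning a simulation with the same seed is bit-identical and
independent of particle evaluation order.

Integrator error: Euler at 6 h in these smooth, slowly varying fields gives
endpoint changes of order Δt (first order); the reversibility acceptance
check bounds the accumulated forward–backward error by one grid cell over a
full year.

## Velocity climatology

`currents.build_climatology` grids 6-hourly drifter fixes by cell-mean
binning: each (cell, year-day) holds the mean of all fix velocities falling
in the cell within ±7 year-days (circular window of 15 days, configurable).
Cells left empty are filled from the nearest observed cell up to 3 cells
away, else zero with `n_obs = 0` as a quality flag.  Drogue-off fixes are
included by default (`drogue_only` exposed).  Calendar dates map to a
365-day year with Feb 29 folded onto Mar 1.  Velocity queries interpolate
bilinearly in space and linearly in year-day with wraparound between day
364 and day 0; land cells carry zero velocity, so the interpolated field
tapers to zero at the coast.

## The synthetic ocean

The synthetic module is first-class code, not a fixture: it generates every
input of the pipeline with a planted, recoverable structure.

**Two-pathway current field.** The domain is 62–30° W, 5° S–22° N at 1/4°
(coarser than an operational 1/12° product; resolution is configurable), a
desk-scale analog of the western Tropical Atlantic with a synthetic
NE-South-America coastline.  Two route branches converge on a Barbados-like
target (59.563° W, 13.268° N):

* **Pathway A** — a meandering coastal jet (0.12 m/s, Gaussian cross-section
  of 1.2° e-folding width, meander amplitude 0.6°, wavelength 8°) from an
  equatorial eastern source (≈36° W, 1° N) along the coast, turning north to
  the target.
* **Pathway B** — a direct zonal jet (0.075 m/s) at the target's latitude
  from the north-eastern edge of the domain.

A backtracked particle necessarily crosses seasons, so both branches are
permanent; only the final approach (within a 3° gate of the target, with
speeds ramped to 0.3 m/s there) is seasonally blended between branches
using the regime calendar's weight, smoothed over 10 year-days at regime
boundaries.  The default calendar assigns regime A (coastal approach open)
to year-days 60–218 (March–early August) and regime B to the remainder,
encoding the observed seasonal split of Barbados strandings.

Two deliberate kinematic devices, both documented here because they are the
package's own design choices where reality offers no single answer:

* the planted pathways are pathways of the **total drift** (current + 0.5%
  wind): inside jet cores the current embeds the offset cancelling the
  design windage, so drifting material follows the route axes instead of
  slipping off diagonal segments under the uniform −4 m/s trade wind;
* a weak (0.03 m/s) permanent westward drift is confined to the equatorial
  band (taper centred at 2.5° N), where pathway A is zonal — it flushes the
  bloom-region box in the forward-dispersal experiment without tilting the
  diagonal coastal segment off-axis.

Jet speeds are free parameters (no quantitative speeds are available for
either route); they are chosen so that 365-day backtracks remain inside the
desk-scale domain.  Consequently absolute path lengths (≈3.4 × 10³ km for A,
≈2.6 × 10³ km for B under defaults) are smaller than real-ocean values; only
their ordering and the origin-latitude contrast are meaningful, and those
are what the acceptance checks assert.  A smooth divergence-free claim is
*not* made: the field is a kinematic test harness, not dynamics.

**Drifter fixes.** Synthetic drifters are seeded at random ocean points and
year-days and advected forward by the pure grid current (drifters follow
water, not windage), recording 6-hourly fixes with Gaussian observation
noise (sd 0.02 m/s, configurable) on the sampled velocities.  Land seeds
are rejected and re-seeded with the count logged.

**Morphotype compositions.** Per collection date, 3 clumps are drawn; each
clump's total displacement volume is lognormal (median 250 mL, log-sd 0.3,
≈0.27 kg of wet weed) split by a Dirichlet draw with the date's regime mean
and concentration 30: regime A mean (0.10, 0.15, 0.75) over (S. natans I,
S. natans VIII, S. fluitans III) — S. fluitans III dominance — and regime B
mean (0.08, 0.55, 0.37) — elevated S. natans VIII.  The means are free
parameters chosen to reproduce the qualitative contrast reported for the
two arrival seasons; the January anchor (8/67/25%) is used as a calibration
check in the tests, not as a generator default.

**Environmental fields.** SST decreases monotonically poleward
(28.8 − 0.24·lat °C plus a ±1 °C seasonal cycle and smooth noise), so
equatorial (pathway A) origins are warmer by construction; chlorophyll is
elevated near the coast with smooth lognormal noise.  Fields live on a
46-composite 8-day time axis; land is NaN.

**What the harness does not emulate:** mesoscale eddies, dynamically
consistent currents (no geostrophy or pressure gradients), Stokes drift,
seasonal wind variability, *Sargassum* growth and mortality along the
route, cloud gaps in satellite fields, and interannual variability.
Passing tests therefore demonstrate that the *pipeline* recovers structure
that is present and reachable by these methods — not that the real-ocean
conclusions are reproduced; the study's printed statistics depend on the
real drifter archive and sample table and are out of scope.

## Trajectory metrics and sub-origin labels

Each simulation is reduced to the ensemble mean (±95% CI, mean ± 1.96 sd/√n)
of per-particle travelled distance and of origin latitude.  K-means (k = 2,
z-scored features, best of 10 restarts, fixed seed) partitions the
simulations; the cluster with the larger mean distance is labelled pathway
A.  Pathway A should also have the lower mean origin latitude; if the two
criteria disagree the distance criterion wins and a warning is recorded.  A
manual-override of labels is possible by editing the assignment mapping
before the statistical stages.

## Compositional statistics

Volumes → proportions (relative abundance).  Monthly summaries average
compositions first within date, then within month (each date weighs equally
regardless of clump count), renormalised.  For testing, compositions map to
bivariate isometric log-ratio coordinates in the fixed basis

    z1 = (1/√2) ln(p1/p2),   z2 = √(2/3) ln(√(p1 p2)/p3),

after multiplicative zero replacement at 0.005 (additive log-ratio is
available via `alr_bivariate`).  Distances between coordinate rows are
Euclidean — log-ratio coordinates are signed, so rank-based ecological
dissimilarities would be inappropriate.

**Nested PERMANOVA.** The one-way pseudo-F is computed from the squared
Euclidean distance matrix by the standard distance partition
(SS_total = Σd²/n; SS_within from within-group pair sums; for Euclidean
input this equals McArdle–Anderson Gower-projection partitioning).  The
permutation scheme respects the sampling design: whole dates are reassigned
between sub-origins preserving group sizes, and clumps travel with their
date — dates, not clumps, are the independent replicates.  P-values use the
add-one rule p = (#{F* ≥ F} + 1)/(n_perm + 1) with n_perm = 9999 by
default; exhaustive enumeration over all distinct date-label assignments is
available (and exact) for small designs.  An unrestricted sample-level mode
is provided as an internal cross-check against a standard one-factor
PERMANOVA.

**Dispersion homogeneity.** Betadisper-style: principal-coordinate
embedding of the distance matrix (negative-eigenvalue axes retained with
subtracting squared distances, per the standard construction; absent for
Euclidean input), distance of each point to its own group centroid, one-way
F on those distances, and significance by permuting group labels over the
fixed distances.

**Two-factor environmental PERMANOVA.** Response (SST, √chl), each column
z-scored (temperature and concentration are not commensurable under a
Euclidean metric; standardisation is configurable).  Sequential (Type I)
sums of squares for period (origin at 365 d back vs midpoint at 183 d
back), sub-origin, and their interaction, via hat-matrix projections on
centred coordinates; free row permutation with the add-one rule.  Box
averages use a square of 93,500 km² (side 305.8 km converted to degrees at
the centre latitude) over non-missing cells of the 8-day composite nearest
the historical target date.

## Numerical and degenerate-input choices

* Tie handling in permutation counts uses a 10⁻¹² slack so F* equal to F
  counts as ≥ (conservative).
* A response with zero between-group variance returns F = 0, p = 1.
* K-means on identical metric rows raises a degenerate-clustering error.
* Compositions with a zero part are handled by multiplicative replacement;
  a clump with zero total volume is an error.
* Grid queries outside the domain raise; the tracker instead freezes and
  flags particles (a trajectory must not abort an ensemble).
* Env boxes with no valid cells yield missing records (logged), not
  failures; the factorial design validates that no 2×2 cell is empty.

## Problem sizes

The default study mirrors the field effort: 24 collection dates (2/month;
in March and August sampling falls later in the month, because launches
within ~2 weeks of a circulation handover have genuinely mixed provenance —
the transition weeks are fuzzy in the underlying phenomenon too), 100
particles × 365 days per backtrack at 1/4°, 3 clumps/date, 9999
permutations.  The simulation-based checks use 1000 replicate null datasets
(999 permutations each) for test calibration and 200 replicate draws of
samples and environmental noise — around a single tracking ensemble, whose
cluster assignment is deterministic at the planted separation — for power
and SST direction.  These sizes were chosen as the smallest that make the
Monte-Carlo bands in the checks meaningful.

## Known limitations

* Euler-only reference integration; no RK4 reference in this version.
* The centre-of-mass origin uses arithmetic lon/lat means: adequate within
  one ocean basin, wrong across the antimeridian (guarded by assertion).
* The nested permutation engine assumes every clump of a date shares that
  date's group (validated) and currently enumerates exhaustively only for
  two groups.
* The betadisper permutation fixes distances-to-centroid computed from the
  observed grouping, the common construction; re-embedding per permutation
  is not offered.
* The synthetic harness plants exactly two pathways; the pipeline's k is
  configurable but the labelling semantics (A = longer, more equatorial)
  are specific to k = 2.
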