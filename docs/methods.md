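# Methods

## The model

`leksim` simulates a population of `N` territorial males on the unit
square with periodic boundary conditions (a torus).  Territories are
Voronoi cells: each male owns the region of space closer to him than
to any other male, and two males are *nearest neighbors* when their
cells share a boundary segment.  The population carries a two-level
hierarchy: a fraction `phi` of males are low-ranking and carry weight
`rho` in `(0, 1]`; high-ranking ("hotshot") males carry weight 1.
Because the dynamics depends only on weight ratios, normalizing the
high-rank weight to 1 loses no generality; populations with arbitrary
per-individual weights are constructible for multi-rank experiments,
but only the two-rank model is swept and tested.

At every time step, each male moves to the midpoint between his
current position and the rank-weighted center of mass of his nearest
neighbors,

    x_CM(i) = sum_j w_j x_j / sum_j w_j        (j over neighbors of i),

with neighbor positions unwrapped to their minimum image relative to
the focal male.  At `rho = 1` this is the classical Hasegawa-Tanemura
centering rule, which relaxes a random pattern into a near-regular
polygonal arrangement.  At `rho < 1` everyone is preferentially
attracted to high-ranking neighbors, and the converged configurations
show clusters of low-ranking males around hotshots — the model's
picture of lek formation.

The update is *synchronous*: the tessellation and all the centers of
mass are computed from the configuration at the start of the step and
all males then move at once.  A synchronous sweep is deterministic and
independent of any processing order; equilibrium configurations are
fixed points of the rule either way, but transient durations could
differ under a sequential schedule, which this package does not
implement.

Convergence is declared when the mean squared single-step displacement
(MSD, mean over individuals of the squared minimum-image displacement
between consecutive steps, in squared box-side units) falls below a
threshold.  Defaults follow the full-scale protocol: threshold
`1e-14`, step cap 4,000,000.  Runs that hit the cap are flagged
non-converged and excluded from all aggregates (they produce the
white cells of the parameter maps).

## Geometry

The periodic Voronoi adjacency is computed by tiling translated images
of the points around the box, Delaunay-triangulating the augmented set
(Qhull via `scipy.spatial.Delaunay`), and keeping the edges incident
to the central copy.  Rather than always tiling the full 3x3 grid of
images, only images within a margin band of the boundary are added,
and the result is verified: every Delaunay circumdisk of a simplex
touching a central point must lie inside the tiled window.  If the
check fails, the margin escalates (up to the full tiling), so the
returned adjacency is the exact periodic one at every margin.  The
automatic margin is `4/sqrt(N)` clipped to `[0.15, 0.45]`, with the
full tiling used below `N = 64`.

Two edge cases are handled explicitly.  An adjacency between a point
and one of its own periodic images (possible only for very sparse
patterns whose territory wraps around the torus) is discarded and
logged; the modeled densities never produce it, and self-interaction
is meaningless in the movement rule.  Exactly degenerate inputs that
Qhull rejects are retried once with a deterministic jitter of
magnitude `1e-12`; such configurations are measure-zero and arise
only in constructed tests.

For every generic periodic tessellation, Euler's relation for planar
tessellations with trivalent vertices forces exactly `E = 3N` edges,
so the population-mean neighbor count is exactly 6 — the package's
load-bearing structural law, asserted to `1e-9` throughout the tests.

## Degenerate collapse at small phi and small rho

A finding worth documenting: when the low-rank fraction is small and
the weight asymmetry strong (roughly `phi <= 0.15` with `rho <= 0.2`),
the synchronous dynamics can drive subsets of individuals toward
*coincident* positions.  Down-weighted neighbors contribute little to
their neighbors' centers of mass, so heavier mutually-adjacent
individuals contract toward each other geometrically; once
separations reach the floating-point scale the tessellation
degenerates (Qhull merges coincident sites and some individual loses
all neighbors).  Such runs are aborted and reported as non-converged
with `degenerate=True`; they are excluded from aggregation exactly
like cap-limited runs.  This regime overlaps the white
(non-converging) region of the parameter maps, and whether the
collapse would also occur under a sequential update schedule is left
open.

## Statistics

`rank_stats` tabulates per-class and overall neighbor-count
distributions and means.  Two algebraic identities serve as built-in
self-tests:

* Euler relation: `(1 - phi) <n_HR> + phi <n_LR> = 6` on every
  two-class configuration (`euler_residual`);
* the high-rank advantage `<n_LR>/<n_HR>` equals
  `1 + (1/phi)(6/<n_HR> - 1)` (`advantage_ratio_from_euler`), the form
  implied by the Euler relation; it is cross-checked against the
  directly computed ratio to `1e-9`.

Class differences are tested with a two-sided Mann-Whitney U-test
(`scipy.stats.mannwhitneyu`, exact for small tie-free samples,
tie-corrected normal approximation otherwise), validated in the test
suite against a 10^4-shuffle permutation oracle.

## Goodness of fit

Observed display-site patterns (CSV tables `id,x,y[,label]`; optional
tags are read and ignored) are rescaled from their rectangular survey
window to the unit square by a single common factor (relative geometry
preserved; the factor recorded), tessellated with the same periodic
machinery — eliminating boundary-cell bias — and reduced to a
neighbor-count distribution `T(n)`.  Model distributions `F(n)` per
`(phi, rho)` cell pool the whole-population counts over converged
replicates (field data are not rank-resolved, so both classes pool).
The comparison aggregates counts into five bins
`{n<5, 5, 6, 7, n>7}` and computes the Pearson statistic

    chi2 = N0 * sum_bins (F - T)^2 / F,

where `N0` is the *observed* sample size, referred to a chi-squared
distribution with 4 degrees of freedom (5 bins - 1).  The level-0.05
critical value is 9.49.  Caveat, inherited from the protocol this
mirrors: scanning the map over a parameter grid does not reduce the
degrees of freedom, so the map is a compatibility screen, not a
calibrated simultaneous test.  Whether model replicates should be
pooled or averaged per replicate is not fixed by the protocol;
pooling is used (equivalent in expectation).

`chi2_statistic` itself refuses a model distribution with an empty
bin (the statistic is undefined; the caller is advised to pool bins).
The compatibility map, which must score every cell, instead applies
the natural limit: a bin empty in the model *and* the observation
contributes nothing, while observed mass in a model-empty bin makes
the cell incompatible outright (chi2 = infinity, p = 0).

## Parameter sweep

The canonical grid runs `phi` and `rho` from 0.1 to 1.0 in steps of
0.05 with ten replicates per cell.  Each (cell, replicate) run derives
its own `numpy.random.SeedSequence` from the base seed and the cell
coordinates (as integer counters), so any subset of cells can be
re-run reproducibly and independently.  Aggregation computes means of
per-replicate means with standard errors, pools distributions by
summing counts, and carries unavailable cells (zero converged
replicates) explicitly.

## Desk-scale profile

Full-scale runs (threshold `1e-14`, cap 4e6 steps) at small `rho` take
hours to days; all bundled tests and the acceptance script therefore
use a documented desk-scale profile chosen once as the package's
standard working scale:

* relaxation threshold `1e-10` (squared box units), step cap 2e5
  (`sweep.scaled_config`), with smaller caps in the quickest test
  contexts;
* populations of N = 100 for coarse grid sweeps, N = 200-400 for
  single-cell measurements;
* three replicates per cell instead of ten.

At this profile the qualitative structure of the parameter maps (the
decrease of `<n_HR>` and the growth of `<n_LR>` toward small `rho`,
the advantage ratio in the 1-1.7 band) is preserved; per-cell values
carry more replicate noise than the full protocol, and slow cells near
`rho = 0.1` may be unavailable at the reduced cap, exactly as the
slowest cells are unavailable at the full one.

In the strongly hierarchical corner (`rho = 0.1`, small `phi`) the
time to reach a fixed point is heavy-tailed: some seeds settle within
a few thousand steps while others wander intermittently for over 10^5.
Sampling that corner therefore uses many cheap attempts — independent
seeds run to a small step cap, keeping the runs that converge —
rather than a few long ones; the converged-run statistics are
unaffected by the attempt policy, since every fixed point is a valid
equilibrium of the deterministic rule and non-converged runs are
excluded under either policy.

## Synthetic patterns

The pattern generator (`leksim.patterns`) supplies the observed-data
pathway with stand-ins for field patterns like the ~100-site exploded
leks the goodness-of-fit machinery targets: complete spatial
randomness (uniform i.i.d.), a jittered square lattice (a regular
arrangement with tunable disorder), and model-generated patterns (a
converged simulation's positions, by default with rank labels
stripped to emulate non-rank-resolved field data, with provenance
recorded).  These emulate the *geometry* of display-site data —
point counts, windows, periodic analysis — but not observational
features such as detection error, tag loss or survey-boundary
irregularity; tests passing on them validate the pipeline's
computations, not the field-data conclusions.

## Numerical choices

* Coordinates are dimensionless box-side units in `[0, 1)`; wrapping
  uses `x - floor(x)` with a fold-back for the `1.0 - eps` rounding
  case, and minimum-image displacements live in `[-0.5, 0.5)`.
* The MSD threshold is interpreted in squared box-side units; with
  box side 1 the side-vs-area scaling distinction is numerically
  void.
* The neighbor graph is recomputed from scratch every step
  (correctness over speed; N = 400 is cheap enough).
* Floating-point determinism holds per platform/BLAS; tests compare
  exact equality only within a session.
* Mann-Whitney p-values for the degree samples (heavily tied) use the
  tie-corrected asymptotic path; agreement with the permutation
  oracle is asserted to 0.05 absolute.

## Known limitations

* Only the synchronous update schedule is implemented; transient
  durations (and conceivably the collapse boundary) may differ under
  sequential updating.
* The advantage-ratio surface is only explored at desk scale in the
  bundled tests; cells that require more than the scaled step cap are
  reported unavailable rather than estimated.
* No territory-area statistics; the analysis concerns neighbor counts
  only.
* No Laguerre (weighted) tessellation: weights enter the movement
  rule, not the territory definition.
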