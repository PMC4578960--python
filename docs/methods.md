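# Methods

## Problem and model

The package solves a raster zoning problem from systematic conservation
planning: out of the *configurable* cells of a study area (cells eligible
for allocation, mask `D`), select exactly `Q` cells for ecological
protection. Candidate zonings are binary rasters `x` with `Σ x_i = Q`.
Three objectives are combined:

- **Ecological suitability** `E(x) = Σ_i Eco_i x_i / Q` — mean suitability
  of the protected cells; maximized. `Eco` is a normalized [0, 1] layer,
  typically built from factor rasters (vegetation, terrain, water, soil,
  land use) by weighted linear summation with externally derived (e.g.
  AHP) weights; `beezone.weighted_linear_summation` performs that
  combination step.
- **Development potential** `V(x) = Σ_i Dev_i x_i / Q` — mean urban
  development potential of the protected cells; minimized, both to avoid
  blocking growth and to keep reserves away from urban stress.
- **Compactness** `C(x) = Σ_i Com_i x_i / Q` with
  `Com_i = (# protected cells in the n×n window around i) /
  (# configurable cells in that window)` — mean neighborhood density of
  the protected pattern; maximized. The window is centered on `i`,
  includes `i` itself, and is truncated (not padded) at raster borders;
  a window with no configurable cell scores 0.

The scalarized fitness is `F(x) = w1·E + w2·(1 − V) + w3·C` with
non-negative weights summing to 1; for normalized layers `F ∈ [0, 1]`.
With `w3 = 0` the problem is separable and the exact optimum is the top-Q
cells by the *site score* `s_i = (w1·Eco_i + w2·(1 − Dev_i))/(w1 + w2)`;
the compactness term makes it a genuinely spatial combinatorial problem.

### Window and scoring conventions

Two conventions are under-determined by the problem statement and fixed
here once:

- the compactness window includes the center cell (a protected cell is
  always part of its own neighborhood density), and
- the "quality" of a cell wherever a scalar site value is needed
  (pseudo-random initialization, poor-region selection, density slicing)
  is the site score `s_i` above — the allocation-independent part of the
  objective.

Default window side `n = 3`; exposed in configuration. Layers are
validated to [0, 1] at load; out-of-range values are a hard error rather
than clamped, so preprocessing bugs surface immediately. Coordinates are
0-based `(row, col)`, row 0 at the top.

## The bee-colony optimizer

The optimizer is a discrete artificial bee colony. A *food source* is a
feasible zoning with its fitness and a stagnation counter. Control
parameters: colony size `SN`, stagnation limit `Limit`, cycle count
`MCN`. Defaults (`SN=12`, `Limit=150`, `MCN=1000`, weights
0.34/0.33/0.33) mirror a regional-scale planning run.

Each cycle:

1. **Employed phase.** Every source proposes a neighbor against a
   uniformly chosen other source (replace-and-alter, below) and keeps it
   iff strictly better (greedy retention).
2. **Onlooker phase.** Selection probabilities `p_j = fit_j / Σ fit`
   are computed once, then `SN` roulette draws each apply the same
   neighbor operator to the drawn source. All-zero fitness falls back to
   uniform selection.
3. **Local search.** The cycle-best source undergoes up to `k` swap
   moves, `k` uniform on `swap_count_range` (default (20, 40)). Each
   swap removes the protected cell whose removal costs least and adds
   the unprotected configurable cell whose addition gains most; the pair
   is kept only if the combined exact change improves the objective, and
   the search stops at the first non-improving pair, so fitness is
   non-decreasing. Selecting removal and addition greedily (rather than
   jointly over all ~Q·N pairs) is exact whenever the two windows do not
   overlap and is the only variant that scales; the combined delta is
   always evaluated exactly before acceptance.
4. **Scouts.** Sources whose counter reaches `Limit` are replaced by a
   freshly initialized source. A source's counter resets to 0 in any
   cycle where its fitness strictly improved (in either phase or by
   local search) and increments by exactly one otherwise.
5. The global best is updated from the surviving sources; its trace is
   non-decreasing by construction.

### Initialization

Two methods are mixed (each source draws independently,
`init_pseudo_prob = 0.5`):

- *complete-random*: `Q` configurable cells uniformly without
  replacement — diversity;
- *pseudo-random*: `⌊best_fraction·Q⌋` cells greedily from the top site
  scores (`best_fraction = 0.5`; ties by row-major index), the rest by
  score-proportional roulette without replacement (implemented as
  Efraimidis–Spirakis weighted sampling, which is distributionally
  identical to sequential roulette). If all remaining scores are zero
  the draw degrades to uniform — quality.

Scout replacements use the same mixed initializer.

### Replace-and-alter neighbors

A neighbor of `u_j` informed by partner `u_k` is built in two stages,
each strategy drawn with probability 0.5:

- **R1** copies a random rectangle of `u_k` into `u_j` (position uniform
  over the grid; side lengths uniform on `[1, ⌈dim/4⌉]`, clipped at the
  border).
- **R2** overwrites the region formed by `u_j`'s `m` worst protected
  cells by site score (`m` uniform on `[1, ⌈0.1·Q⌉]`).

The copy generally breaks the quota by some signed amount `d`; the
*alter* stage restores it by toggling `|d|` cells outside the region:

- **A1** picks each toggle to maximize the exact incremental objective
  change (ties by lowest row-major index);
- **A2** picks uniformly among eligible outside cells.

If no eligible cell remains the move is abandoned and the original
solution returned (counted as a degenerate move). Every emitted solution
therefore has exactly `Q` protected cells on configurable positions.

### Incremental evaluation

Both A1 and the swap search need "what does toggling this cell do to
`F`?" for every cell at once. The evaluator maintains, for the current
assignment, the per-cell window count of protected cells `P` (exact
integer arithmetic), the window sum `W` of `x/D` (`D` = configurable
window counts, precomputed per instance), and the three running
objective sums. Single-toggle deltas are then closed-form in `P`, `W`
and the site layers and available as vectorized arrays; applying a
toggle updates an n×n patch. The public `fitness_delta` computes the
same quantity for one protected→unprotected move pair by examining only
the two affected windows; both routes agree with full re-evaluation to
~1e-12 (asserted at 1e-9 in tests).

A single `numpy.random.Generator` seeded from the configuration drives
every stochastic choice in a fixed order, so runs are bit-reproducible.

## Density-slicing baseline

The classical one-pass alternative: threshold the site-score layer so
exactly `Q` configurable cells pass (equivalently the top-Q by `s_i`,
ties by row-major index). Deterministic, optimal for `w3 = 0`, blind to
compactness; it anchors the comparison experiments and serves as the
independent optimum oracle in separable-objective tests.

## Synthetic validation landscape

`gauss_multipeak_surface` builds a 200×200 suitability surface as the
normalized sum of five Gaussian bumps: a central peak (amplitude 1.0,
σ = 25, at cell (100, 100)) and four corner peaks (amplitude 0.5,
σ = 10). The development layer is zero and every cell is configurable,
so the site part of the objective is the surface itself. Calibration
rationale: the surface is radially decreasing around the center, so its
top-1250 cells are automatically the ~1250 cells nearest the center
(radius ≈ 19.95); the binding requirement is that corner values stay
below the central peak's value at radius 20, i.e.
`exp(−400/(2σ²)) > 0.5`, satisfied with margin at σ = 25 (value 0.726).
The top-1250 level set overlaps the radius-20 disk with Jaccard ≈ 0.994,
making the central disk the known optimum while the corner peaks are
local-optimum traps. The validation experiment runs the optimizer with
`Q = 1250`, site weight 0.67, compactness weight 0.33 for 200 cycles and
overlays the result on the disk.

**Known discretization effect.** On the integer lattice the weighted
objective's true optimum is not exactly the rasterized disk: the 3×3
density term rewards smoothing the disk's jagged boundary, and the
converged solution trades ~24 inside-boundary cells (r ≈ 19.8–20) for
~17 cells just outside (r ≈ 20.1–20.6), i.e. ~1.4% of `Q` off the disk,
identically across seeds. This is a property of the instance, not of the
optimizer: the best disk-constrained local optimum has strictly lower
fitness, and no Gaussian center peak can change the outcome (the maximum
gradient any normalized Gaussian attains at radius 20 is ≈ 0.037 per
cell, below the ≈ 0.075 needed to out-price the density gains; an
alternative calibration at the steepest admissible σ = 18.3 yields the
identical 17-cell smoothing). The overlay residual of a converged run is
therefore expected to be on the order of one percent of `Q` —
"discretization of the continuous optimum" — rather than zero.

What the synthetic landscape does not emulate: real suitability maps'
spatial autocorrelation structure, nodata holes, non-trivial
configurable masks, and a meaningful development layer. Tests passing on
it demonstrate optimizer correctness and convergence behavior, not
performance claims about any real study area.

## Evaluation utilities

- `overlay_match` counts protected cells inside/outside a reference
  mask; the non-matched percentage is relative to `Q`.
- `run_overlap` reports the percentage of `Q` protected in *every* one
  of a set of runs (the natural denominator since each run protects
  exactly `Q` cells) plus the per-cell overlap-count raster.
- `landuse_stats` tabulates a zoning against a categorical map:
  per-category regional/protected/unprotected counts (the splits always
  sum to the regional counts) and the three percentage views (share of
  region, share of protected area, protected share within category).

## Numerical choices and degenerate inputs

- Window sums use a separable box filter with zero padding and exact
  integer rounding for counts; incremental updates touch only the
  affected window, and evaluators are rebuilt per neighbor proposal so
  float drift cannot accumulate across cycles.
- Ties in every argmax/sort are broken by lowest row-major index
  (stable sorts / first-maximum argmax), making all deterministic code
  paths reproducible without a seed.
- `Q` larger than the configurable-cell count is a configuration error
  raised before any work; `Q` equal to it forces the unique solution.
- Swap acceptance uses a strict `> 1e-12` improvement threshold so the
  local search terminates on plateaus.
- A repair with no eligible outside cell reverts the move rather than
  emitting an infeasible solution.

## Problem sizes used in the shipped experiments

The validation experiment (200×200 cells, `Q = 1250`, 5 seeds, 200
cycles each) completes in about a minute; enumeration oracles run on
4×4 grids (560 subsets); property sweeps use 6×6–12×12 random instances.
These sizes were chosen so the full suite and the reproduction script
each run comfortably on a single CPU while exercising every code path at
the scale structure of the original experiments.

## Known limitations

- Land units are single grid cells; polygon/multi-cell units are not
  represented.
- The scalarization is a fixed weighted sum; no Pareto-front exploration.
- One colony, serial execution; no adaptive parameter control.
- Mandatory-inclusion constraints (e.g. legally ascertained resources)
  are expressible only by preprocessing the configurable mask, not as a
  model term.
- TIFF I/O carries values only (no georeferencing tags); ESRI ASCII grid
  is the fully supported interchange format.
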