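# Methods

## The problem

A spatial neuron's activity is summarized as a firing-rate map: a dense grid
of spikes-per-second over the binned arena (or a 1D vector over a linear
track).  "Remapping" is any change in that map between sessions or
conditions — the field may move, rotate, scale, split, or only change rate.
The conventional statistic, bin-to-bin Pearson correlation, collapses to
r ≈ 0 as soon as the fields stop overlapping, is swamped by shared noise,
and requires identical map shapes.  This package quantifies remapping with
the Earth Mover's Distance (EMD) family instead: the minimum mass-times-
distance cost of morphing one nonnegative map into the other.

## Distances

**1D closed form.**  For two histograms on a common increasing support, the
EMD is the integral of the absolute difference of their cumulative sums,

    EMD(P, Q) = Σᵢ |F_P(i) − F_Q(i)| · Δᵢ ,

where Δᵢ is the gap to the next support point (1 for unit-spaced bins).
`emd_1d` implements this in O(n); it agrees with the transportation LP to
1e-9 on single-row maps (tested) and with `scipy.stats.wasserstein_distance`
as an independent oracle.

**Exact 2D (LP oracle).**  `exact_emd_2d` solves the transportation linear
program (flow f(x,y) ≥ 0, row sums = a, column sums = b, minimize
Σ f(x,y)·‖x−y‖₂) with `scipy.optimize.linprog` (HiGHS).  Its cost grows
cubically with support size, so it is capped at 1024 support points (32×32)
and serves as the validation oracle, not the workhorse.  Implementation
notes: one constraint row is redundant (the two marginals share a total) and
is dropped; HiGHS presolve is disabled because it misclassifies bins with
~1e-15 mass as infeasibilities.

**Sliced 2D.**  `sliced_emd` projects both maps' bin centers onto L random
directions θ ~ Uniform[0, π), computes the exact weighted 1D distance per
direction by merged-CDF integration over the projected support (no
resampling), and averages.  When both maps share a grid, the projection and
sort are done once per direction on the shared support with a signed weight
difference — the dominant cost is L sorts of n values, O(L·n·log n).

*Slice correction.*  The raw slice average systematically underestimates the
2D distance: a pure translation by d projects to d·|cos θ| with mean 2d/π.
The default `slice_correction="pi_over_2"` multiplies by π/2, which is exact
for translations and a good approximation whenever transport is dominated by
coherent displacement (typical for firing-field remapping: measured max 5%
error against the LP on random Gaussian-field pairs at L = 10⁴).  It remains
an underestimate for incoherent, noise-like differences where opposing 1D
flows cancel within a slice (measured 17–30% low on iid-uniform 8×8
histograms); `slice_correction="none"` returns the uncorrected average.

*Projection count.*  Default 10⁴ for pairwise distances (Monte-Carlo error
under 1%), 10² for localization score maps where thousands of distances per
map are needed and per-value precision matters less.

**Single-point Wasserstein.**  Against a point mass at q every unit of mass
must travel to q, so the plan is forced and the distance is the mass-weighted
mean Euclidean distance, O(n):  EMD(P, δ_q) = Σ_x ‖x − q‖₂ · P(x).

**Mass policies.**  Transport needs equal totals.  `normalize` (default)
maps both inputs to unit mass — the Wasserstein distance, insensitive to
rate remapping.  `scale_to_min` rescales the heavier map to the lighter's
total (the partial-transport convention), keeping raw-rate units.  `error`
refuses mismatches.

## Variants

* *whole-map* — the distance between full maps.
* *field-restricted* — rates outside detected firing fields set to zero;
  isolates field geometry from background.
* *binary* — 0/1 indicator maps of the fields, each normalized to unit
  mass; exactly invariant to any rate rescaling by construction, measuring
  pure dispersion.  A point-cloud analogue (`spike_density_distance`)
  operates on raw spike positions without binning (experimental).
* *centroid distance* — Euclidean distance between two points.
* *region* — field vs an area target (e.g. an arena quadrant) represented
  as uniform unit mass over the region's bins; uniform is the least-
  informative mass model and the choice is deliberate.

## Synthetic fields

Place fields are analytic Gaussians evaluated at integer bin centers
(`amplitude · exp(−½ dᵀΣ⁻¹d)`), optionally elliptical (σ_y, σ_x) and
rotated.  Translation pairs are generated on a 3N canvas and sliced, so
fields near borders are genuinely truncated.  Grid cells are sums of
truncated Gaussian stamps (half-extent `kernel`, default ⌈3σ⌉) on a
hexagonal lattice across a wide canvas (`8N + 2·kernel` per side):
horizontal center spacing s = 2·kernel + gap, row step round(s·√3/2),
alternate rows offset by round(s/2).  Rounding to integer bins keeps maps
bit-reproducible; the test surface for the lattice is its periodicity
(horizontal period s, vertical period two row steps), not a particular
bit-level layout.  Noise is i.i.d. per bin (normal or uniform), seeded, and
clipped at zero after addition because transport carries nonnegative mass;
correlation baselines can be fed the unclipped signed array.

**Canonical noise-pair geometry.**  The two σ=1 pairs on 17×17 maps used in
the noise experiments are pinned down by their no-noise Pearson baselines:
centroids (8,4)/(8,12) give r = −0.0454 (wholly non-overlapping) and
(8,7)/(8,9) give r = 0.339 (partially overlapping).  These constants are
reproduced by the code at run time, not asserted from a table.

**Noise model in the pair experiment.**  `noise_sweep` defaults to a noise
field *shared* by both maps of a pair, modeling a common degradation of the
session (the regime where bin-to-bin correlation is driven toward 1 by the
shared noise while the raw transport distance barely moves — identical
noise mass needs no transport).  With `shared_noise=False` each map gets
independent noise; then the correlation drifts to ~0 instead.  The default
`pipeline="raw"` scores unsmoothed, unnormalized maps with the scale-to-min
policy; `normalized` and `smoothed_normalized` pipelines are provided.  Note
the raw-EMD stability statistic in this condition sits near a 30% relative
shift at noise σ = 0.5 — robust relative to the correlation's ~0.96 shift,
but not a free lunch.

## Field detection and localization

Firing fields are contiguous regions strictly above 20% of the global peak
(4-connectivity by default, 8 optional; ties at the threshold excluded;
`min_area` default 1).  The threshold is relative, so detection is exactly
scale-invariant.  For a noiseless σ=1 Gaussian the 20% radius is
σ·√(2 ln 5) ≈ 1.79 bins: a 9-bin field (center, 4-neighbors, diagonals).

Localization score maps evaluate, for every bin q of the padded map, the
single-point Wasserstein (exact, O(n) per bin) or the correlation between
the map and a one-hot map at q.  Pipeline order: pad (2 zero bins) → smooth
(5-bin kernel, σ=1) → normalize → score; padding keeps border scores
well-behaved and the order is exposed as parameters.  The EMD score surface
is Lipschitz-1 in q and attains its minimum at the spatial median of the
mass — the field centroid for one symmetric field, a weighted compromise
for several.  `peak_region_summary` thresholds the best 20% of bins
(lowest for distances, highest for similarities — orientation is explicit
metadata) and returns the mask, its centroid, and its mean pairwise spread.

## Reference quantiles

Raw distances are standardized against a counterfactual sample (mismatched
cell pairings via the seeded `mismatched_pairs`, or distances to sampled
reference locations via `sample_reference_points`: uniform-random,
rectangular or hexagonal schemes, optional exclusion radius).  The quantile
is the strictly-less count over N (`q = n/N`), interpretable as a one-tailed
p-value; mid-rank tie handling is available but off by default.  Quantiles
of the reference sample against itself fill the grid {0, 1/N, …, (N−1)/N}
exactly for continuous scores (tested at N = 10³).  Within-cell quantiles
for a centered field are systematically larger near the field than at map
edges; this is a property of the construction and is left uncorrected.

## Experiment geometries

* Translation sweep: fixed centered σ=1 field vs a copy at each of N² bins
  (N=17); one shared projection seed across pairs so surface structure is
  geometric, not Monte-Carlo.  The exact-LP surface at N=9 is verified
  8-fold symmetric; the sliced surface at L=10² is symmetric within the
  estimator's ~5%-per-direction Monte-Carlo error.
* Grid-phase sweep: module σ=1, gap 6 (spacing 12 ≤ N−1 so a full
  horizontal period is observable inside the 0..N−1 shift range).
* Scaling: fixed σ=3 on 33×33 vs σ ∈ [0.5, 6]; rate-ratio sweep on
  identical shapes at ratios 0.25–4.
* Rotation: moving field orbits the fixed field's centroid (radius 8 bins,
  33×33).  σ=1.5 keeps the disjoint-field Pearson floor within ±0.05 (at
  σ=3 the field occupies enough of the map that the floor is ≈ −0.11).
  The corrected EMD tracks the chord 2r·sin(θ/2) within 10%.
* Object tracking: σ=1 field at (4,4) on 17×17, objects at the four
  2-bin-inset corners.  The two corners equidistant from the field give
  bitwise-equal single-point distances (exact computation, no slicing).
* 1D decoding: synthetic population of Gaussian tuning curves (σ = 5 bins,
  100 bins, centers tiling the track; optional non-spatial cells and seeded
  rate noise) scored against single-bin, 10-bin-window, or Gaussian (σ=5)
  templates; quantiles from across-cell or within-cell references.  The
  window-vs-single-bin robustness claim is meaningful only for cells whose
  field is away from the template (distances near zero make relative
  comparisons degenerate).

## Numerical choices and degenerate inputs

Negative intensities are rejected at construction everywhere; noisy maps
are clipped at zero by the generator, not by the metrics.  Zero-occupancy
bins get rate 0 (not NaN).  Zero-mass maps cannot be normalized, localized
or transported (explicit errors); all-zero maps yield an empty field list.
Constant maps make correlations undefined: the baselines return NaN with a
warning (never 0).  Smoothing uses a normalized truncated kernel with
zero-value boundaries, so border mass shrinks — documented, and consistent
with the explicit zero-padding of the localization pipeline.  Spearman ties
take average ranks.

## What the synthetic generator does and does not show

The generator reproduces the geometry of remapping — translation, phase
shift, scaling, rotation, noise, rate changes — with analytic fields, so
every expected value is known exactly and estimator error is measurable.
It does not model spike-train statistics (no Poisson sampling in 2D maps,
no theta modulation, no trajectory sampling bias), inter-session
registration error, or the irregular field shapes of real recordings.
Passing tests therefore demonstrate correctness of the metrics and the
claimed robustness orderings under controlled conditions, not performance
bounds on any particular dataset.

## Problem sizes

The validation suite runs the LP oracle at ≤ 8×8 (pairwise checks) and 9×9
(exact sweep surface), sliced distances at 17×17 and 33×33 with L between
10² and 10⁴, 10 noise seeds per condition, and 60-cell 1D populations —
sizes at which every check completes in seconds while Monte-Carlo and
truncation errors stay well below the asserted tolerances.
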