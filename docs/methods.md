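# Methods

## Data model

The sole map currency is a 2D grid of integer **gray levels** in
[0, 100] with the reserved missing code 255 (chosen because it is the
conventional byte nodata and keeps 8-bit I/O lossless; input files may
declare any other nodata value, which is normalized to 255 on read).
Categorical maps use levels as class codes (nominal); numeric maps must
be quantized first. Quantization is equal-width binning of a stated
source range into up to 101 bins mapped to levels 0 … n_bins−1, with
the top bin closed so the range maximum falls in the highest bin; the
mapping is monotone and idempotent on already-quantized data. It is
always an explicit step — nothing in the package bins silently — because
the bin width is an analysis decision, not a file property.

A **zero policy** optionally treats gray level 0 as missing everywhere;
level 0 frequently encodes background or "no data" in quantized
products (e.g. 0 % cover). Exclusion is applied per pixel: an excluded
pixel contributes to no frequency count and voids any adjacency pair it
belongs to.

## Tabulations

Every metric is a function of one or both summaries of a region:

* the frequency distribution `x(i)` over included pixels, with
  `p(i) = x(i)/Σx`, the number of levels present `Ng`,
  `μ = Σ i·p(i)`, `σ² = Σ (i−μ)²·p(i)`, and min/max levels;
* the ordered adjacency matrix `x(i, j)` under the 2-neighbor rule
  (each pixel paired once with the pixel below and the pixel to the
  right; `i` is the upper/left member). Derived: the unordered
  symmetric-complete matrix `x'(i, j) = x(i, j) + x(j, i)` (diagonal
  kept as is; formulas that sum "over j ≥ i" use its upper triangle so
  total mass is preserved), joint and marginal proportions, marginal
  means/variances, the difference distribution `p_{x−y}(k)` over
  `k = |i−j|` and the sum distribution `p_{x+y}(k)` over `k = i+j`, and
  the counts of nonzero levels `Ng` (matrix) and `Nk` (each
  distribution).

A pair needs both members present: a pixel adjacent to a missing or
excluded pixel still counts in the frequency tabulation but contributes
no pair. A full R×C region therefore holds `R(C−1) + C(R−1)`
adjacencies. Counts live in dense 101-slot (101×101) integer arrays
regardless of `Ng`, which makes incremental updates O(1) per element
and keeps `Ng` a derived quantity.

## Metrics

The registry holds 51 metrics with fixed ids and short names, each
declaring the tabulations it needs, its input applicability (nominal /
ordinal / all), its output type and bound, and any required target
parameters (`t1`, `t2` for the focal-adjacency metrics, `k*` for
k-contagion). Conventions:

* logarithms are natural throughout; the evenness normalizers are
  base-free, but the raw entropies need one fixed choice;
* guards produce a **missing** value, never an exception: `Ng > 1` for
  evenness/equitability, `Nk > 1` for difference/sum evenness, `μ > 0`
  for the CV, `σ > 0` for skewness/kurtosis, `σx·σy > 0` for
  correlation, a zero normalizing range for the range-normalized
  similarity metrics, a zero focal denominator for conditional focal
  adjacency, and an empty tabulation for everything;
* the median of an even pixel count is the lower middle order
  statistic, keeping the output an integer gray level; majority ties
  break to the smallest tied level, which is deterministic and
  order-independent;
* `StandardDeviation` is `sqrt(σ²)` and `RootMeanSquare` is
  `sqrt(Σ i²·p(i))` — the radicals that the names, the [0, 100] bound
  and the CV definition imply;
* the three similarity metrics share the numerator `Σ|i−j|·p(i,j)` and
  differ in the normalizing range R: 100 (the full gray scale), the
  gray-level range of the whole input map (computed once from the
  map-wide frequency tabulation before windowing, under the active
  zero policy), or the range of levels present in the window's
  adjacency matrix;
* the focal-adjacency denominators `Σ_j x'(t1, j)` use the full
  symmetric row of `x'` — all adjacencies involving `t1`, diagonal
  counted once;
* k-contagion accumulates integer pair counts with `|i−j| ≤ k*` and
  divides once, so it is exactly non-decreasing in `k*` and exactly 1
  at `k* = 100`;
* kurtosis is treated as ordinal-only (moments of nominal codes are
  meaningless), and sum entropy as unbounded.

## Landscape mosaic

The mosaic metrics classify the window's composition
`(p(1), p(2), p(3))` of gray levels 1–3; they are defined only when
those three proportions sum to 1 (tolerance 1e-9), i.e. when the window
contains no other level — otherwise the result is missing. Two
deterministic partitions of the ternary simplex are provided, both
total and single-valued:

* **19-class**: each proportion graded High (≥ 60 %), Medium (10–60 %)
  or Low (< 10 %); at most one axis can be High. Codes 1–3 are the pure
  corners (a type at 100 %), 4–15 the twelve single-dominant classes
  (dominant axis × the Low/Medium grades of the two minority axes),
  16–18 the two-Medium classes keyed by the Low axis, 19 the
  three-Medium interior.
* **103-class**: the 10-step ternary subdivision of the simplex into
  100 small triangles (55 upward, codes 1–55 row-major; 45 downward,
  codes 56–100) plus the 3 pure corners (101–103). Compositions on a
  lattice line are assigned to the adjacent upward triangle by a fixed
  index rule, keeping the partition single-valued.

Thresholds are closed on the left (0.10 and 0.60 belong to the upper
grade). The code numbering is this package's own canonical order and is
stable across releases; a class legend can be written alongside any
mosaic map.

## Moving-window engine

The window is square with an odd side ≥ 3 so the center pixel is
defined; even sides are rejected. Each output pixel holds the metric of
the window centered there, so output dimensions equal input dimensions.
Windows overhanging an edge shrink to their in-bounds pixels — chosen
over a nodata border to keep a value at every location; this choice is
documented rather than asserted to match any other tool. Fully
missing/excluded windows yield nodata.

The engine slides along each row keeping the dense count arrays
current: moving one column right removes the leaving columns' pixel
counts, within-column vertical pairs and the horizontal pairs whose
left member left, and adds the entering columns symmetrically. Because
only integer counts are carried between positions and every derived
statistic is recomputed per window, there is no floating-point drift
and the incremental map is bit-identical to rebuilding each window from
scratch (`method="scratch"`, kept as a cross-check). The output is a
pure function of (raster, metric, window, policy, parameters), so any
future row/tile parallelization must reproduce the serial map exactly.

Global analysis evaluates the metric once on the whole-extent
tabulation and equals any moving-window pixel whose (shrunk) window
covers the map. The scalogram driver runs one moving-window analysis
per scale of a grid (default 5, 7, …, 45: 21 scales) and reduces each
map over its non-nodata pixels with max, mean, or a quantile.

## I/O

GeoTIFF single-band 8-bit is the primary dialect, via `tifffile`;
georeferencing tags (ModelPixelScale, ModelTiepoint,
ModelTransformation, GeoKey directories, GDAL metadata/nodata) pass
through unchanged so outputs stay registered. A headerless flat binary
8-bit format with explicit dimensions is supported for minimal
workflows. Float-typed bands are rejected with a pointer to the
quantizer. Metric maps are written as float32 (nodata −9999, declared
in the GDAL nodata tag) or as scaled 8-bit for metrics whose outputs
fit a byte: unit-interval metrics as `round(100·v)`, integer and
[0, 100]-valued metrics as `round(v)`, 255 = nodata. Unbounded metrics
— and correlation, whose [−1, 1] range has no faithful byte encoding
under this scheme — refuse byte mode.

## Synthetic data and the oracle

The fixture generator produces the structures the tests reason about:
constants (every metric's degenerate case), checkerboards (all mass at
one gray-level difference), gradients (monotone quantization checks),
seeded random categorical maps with missing holes (the general case),
smooth binned-numeric surfaces (what a quantized cover map looks like),
and block mosaics. Same recipe and seed always give the identical
raster, so no fixture is stored. What these fixtures do **not**
emulate: spatial autocorrelation structures of real land-cover mosaics,
georeferencing, large extents, or anisotropy — passing tests show the
*computations* are right, not that any ecological interpretation is.

The oracle evaluates every metric by literal formula transcription over
explicitly enumerated pixel and pair lists (Python loops and dicts,
deliberately slow, no shared code with the dense engine). Engine/oracle
agreement within 1e-9 relative over all 51 metrics on seeded random
fixtures — including missing pixels and zero exclusion — is the
package's primary correctness evidence; the moving-window engine is
separately checked against per-window oracle evaluations and against
its own scratch-rebuild path.

## Problem sizes in the test suite

Correctness properties are exercised at sizes where the brute-force
oracle is exact and fast: 15×15 regions for the full 51-metric sweep
(26 fixtures), 40×40 maps with a 7×7 window for
incremental-versus-scratch identity across one representative metric
per family, and 12×12 maps for per-pixel oracle comparison. These sizes
are the package's own choice of smallest-sufficient evidence: every
property checked is size-independent (exact integer counting, exact
formula agreement, bit-identity), so larger fixtures would add runtime
without adding information.

## Known limitations

* Only the 2-neighbor (rook, one-pass) adjacency rule: no diagonal
  neighbors, no distance-lagged or angle-resolved co-occurrence.
* No patch-based metrics (area/perimeter/shape) and no surface
  metrology.
* The mosaic code numbering is canonical to this package; users
  comparing against other mosaic products need a conversion table.
* Maps must fit in memory; no tiling of very large rasters.
* The engine is serial; the parallelism contract (bit-identical
  row-partitioned execution) is stated and tested as a purity property,
  not exploited.
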