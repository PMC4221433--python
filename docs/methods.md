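# Methods

## Normalization

Both normalization modes rescale the whole matrix with its *global* minimum
and maximum — never per row — so the color scale is comparable across the
entire figure:

* linear: `NV = (OV − Min)/(Max − Min)`
* log: `NV = (log_a OV − log_a Min)/(log_a Max − log_a Min)`, defined only
  when every value (hence Min) is strictly positive.

A constant matrix (Max = Min) is rejected; equality is tested exactly, with
no epsilon, because inputs are finite parsed decimals. The log base
defaults to 2, with 10 and e as named shortcuts and any positive real ≠ 1
accepted. Because the base cancels in the ratio, the normalized output is
base-independent to rounding error (asserted at 1e-12 in the tests); the
base matters only for how the colorbar is annotated. One genuine numerical
edge exists: two distinct floats can have identical floating-point
logarithms (e.g. values differing by one ulp near 1e-6), making the log
denominator zero; this is reported as the same constant-matrix error rather
than producing NaNs. Z-score, quantile and row-wise scalings are
deliberately out of scope.

## Color lookup table

A scale of k ≥ 2 RGB anchors is discretized into exactly 768 rows — a
256-level color mode times the three default anchors. The 767 inter-row
steps are split as evenly as possible among the k − 1 segments, remainder
steps going to the earlier segments, so every anchor lands exactly on a
boundary row (with the default tricolor, black sits at row 384).
Interpolation is linear per channel in RGB space with round-half-up to
integers; round-half-up is also used when a normalized value selects its
nearest row, because it is deterministic and locale-free. Values outside
[0, 1] are an error rather than clamped — normalization already guarantees
the range, so an out-of-range value indicates a caller bug worth surfacing.
The green–black–red default follows the microarray convention
(down-regulated → unchanged → up-regulated) and is fully overridable with
any list of hex anchors. Perceptually uniform spaces and diverging scales
centered on a user value are out of scope.

## Distances

Seven metrics, all implemented from first principles (scipy serves as an
independent oracle in the tests, never as the implementation):

| metric | definition | range |
|---|---|---|
| euclidean | √Σ(xᵢ−yᵢ)² | [0, ∞) |
| squared_euclidean | Σ(xᵢ−yᵢ)² | [0, ∞) |
| manhattan | Σ\|xᵢ−yᵢ\| | [0, ∞) |
| maximum | maxᵢ\|xᵢ−yᵢ\| | [0, ∞) |
| pearson (default) | 1 − r | [0, 2] |
| spearman | 1 − ρ (average ranks for ties) | [0, 2] |
| kendall | 1 − τ_b | [0, 2] |

Correlation distances are 1 − coefficient, not (1 − coefficient)/2: 0 means
perfectly correlated profiles, 2 perfectly anticorrelated. Kendall uses the
tie-corrected τ_b by direct O(n²) pair counting — expression matrices
contain ties, and a tie-naive τ would silently miscount; vector lengths in
heatmap work are small enough that the merge-sort optimization buys
nothing. A constant vector under a correlation metric is an error (the
correlation is undefined) with advice to drop or jitter the flat row;
silently substituting a distance would corrupt the clustering. Results are
floored at exactly 0 to absorb round-off at perfect correlation.

## Hierarchical clustering

Naive O(n³) agglomeration directly from the linkage set-definitions —
average = mean of all cross-pair distances (UPGMA, unweighted, not WPGMA),
minimum = closest cross pair, maximum = farthest cross pair — rather than
Lance–Williams recurrences. The direct form is transparent, trivially
checkable against a brute-force oracle, and fast enough for the intended
scale (≤ a few thousand leaves). All three criteria are reducible, so merge
heights are non-decreasing; single-linkage heights equal the sorted edge
weights of the minimum spanning tree, and both properties are asserted in
the tests.

Tie-breaking is deterministic: among pairs with equal linkage distance, the
one whose (smaller, larger) pair of minimum original leaf indices is
lexicographically smallest merges first. So that exact ties are actually
detected, the average linkage is computed with exactly-rounded summation
(`math.fsum`), making the mean independent of the order cross pairs are
visited.

Leaf order is a depth-first traversal placing, at every merge, the child
with the smaller minimum original leaf index on the left — deterministic
and crossing-free. `cut_tree(k)` undoes the last k − 1 merges and numbers
the components 0..k−1 by first appearance along the leaf order. Optimal
leaf ordering (Bar-Joseph), Ward linkage, bootstrap clustering and
automatic k selection are out of scope.

## k-means

Lloyd iterations with a pluggable assignment metric: initial centroids are
k distinct rows sampled with the caller's seed (a required, logged
parameter — no hidden global randomness); points are assigned to the
nearest centroid with ties to the lowest index; centroids are recomputed as
arithmetic means under every metric. An emptied cluster seizes the point
currently farthest from its assigned centroid. Convergence (unchanged
assignments) is guaranteed only under squared Euclidean distance, where the
recorded per-iteration cost is non-increasing; `max_iter` (default 100)
bounds every run and the result records the iteration count and full cost
trace. A centroid that becomes constant under a correlation metric aborts
the run with advice to use a geometric metric.

## Tabular input and output

Sheet coordinates are 1-based inclusive at the module boundary (matching
how users read spreadsheets); everything internal is 0-based. Numeric
parsing accepts integer, decimal and scientific notation with `.` as the
decimal mark; no locale handling. Ragged delimited rows are padded with
empty cells. Blank or textual cells inside a selected data area are a hard
error naming the coordinate — no imputation. The auto-fill convention takes
the first row as column (X-axis) titles and the first column as row
(Y-axis) titles. Duplicate labels are preserved verbatim. Writing uses
`repr`-precision decimals so write → read → auto-fill is an exact identity.
CSV follows RFC-4180 quoting; TSV has no quoting and rejects literal tabs
inside fields. Zip-based Excel files (.xlsx, and .xls files that are
actually xlsx) load through openpyxl, first worksheet only; legacy binary
BIFF .xls is reported with a clear re-save-as-xlsx message, as no reader
for that format is a dependency of this package.

## Rendering and export

The canvas is assembled from closed-form integer components (margins,
optional dendrogram gutters of fixed 48 px depth, the cell grid, label
areas measured from the bundled font, optional colorbar), so total size is
exactly testable for every flag combination. Raster origin is top-left with
row 0 at the top; cell rectangles are half-open so adjacent cells share no
pixels, and each probed cell center carries exactly the LUT color of its
normalized value. Dendrogram branch positions are proportional to merge
height, scaled to the gutter depth. "Rotation" is transpose (axes, titles
and gutters swap) plus a column-label angle of 0/45/90°; free-angle canvas
rotation is underspecified and excluded. The colorbar ticks show the
original-scale Min and Max (plus the log base in log mode) because
normalized units are meaningless to readers.

Figures are composed once at the 72 dpi reference scale; export resamples
by nearest neighbor so cell colors survive exactly. Canvas sides are padded
to a multiple of 6 px, which makes the 72/300/600 dpi presets land on exact
integer scalings (300/72 = 25/6) — pixel dimensions then scale exactly
linearly with dpi at fixed physical size, including the 2× step from 300 to
600 dpi. Text uses the imaging library's bundled font at a fixed size, PNG
is written at a fixed compression level and TIFF uncompressed, with no
timestamps — two exports of the same figure are byte-identical, and the
whole CLI pipeline is byte-deterministic under a fixed seed. Vector
formats, interactive canvases and cell-text annotation are out of scope.

## Synthetic data

The generator plants g row groups with orthogonal step profiles: the
columns are split into g blocks and group i is elevated by
`effect × noise_sd` on its own block, zero elsewhere; rows add i.i.d.
Gaussian noise. This is the simplest structure that exercises every metric,
including the rank-based ones (tie injection — rounding to one decimal —
additionally exercises the average-rank and τ_b paths). It does not model
negative-binomial count noise, library-size effects, or correlated genes,
so passing recovery tests demonstrate algorithmic correctness on separable
structure, not performance on real RNA-seq data. Defaults (60 rows × 6
columns, 3 groups, effect 10, unit noise) give a regime where signal
dominates noise: hierarchical clustering with Pearson distance and average
linkage recovers the planted partition with mean adjusted Rand index ≥ 0.9
over 20 seeds, which the test suite and acceptance script both recompute.
An optional positive shift raises the minimum to 0.1 so the log mode is
exercisable.

## Pipeline defaults and reproducibility

Config precedence is built-in defaults < YAML config file < CLI flags;
unknown config keys are an error, never ignored. Defaults are linear
normalization, Pearson distance, average linkage, and no clustering unless
requested. Every run writes a sidecar JSON report with all effective
parameters, the Min/Max, the seed and the leaf orders; the report alone
suffices to re-run the pipeline identically.

## Problem sizes

The test suite and acceptance script use matrices of up to 60 × 6 for
recovery experiments, n ≤ 8 items for exhaustive brute-force oracle
comparisons (100 random instances across all 21 linkage × metric
combinations), and 20-seed replications for stochastic checks — sizes at
which the naive O(n³) agglomerator and O(n²) τ_b are instantaneous and
exhaustive oracles remain feasible.
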