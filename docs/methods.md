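# Methods

## Scope and data model

`phenocur` operates on indexed image collections: binary plant masks
(8-bit PNG, nonzero = plant) for the temporal and perspective families, and
single-channel or RGB modality images (visible, infrared, fluorescence) for
the intermodal family. Every record is keyed by species, treatment, plant,
integer time index, and either a side-view angle (0°/72°/144°/216°) or a
modality — never both, because each phenotype family varies exactly one
axis while the others stay fixed. Calendar dates are carried as metadata
only; all analysis runs on the integer time index. Coordinates are 0-based
`(row, col)` with the origin at the top-left.

Masks within one plant/view sequence must share dimensions. This encodes
the fixed-camera acquisition geometry; a dimension mismatch is an error,
never a silent resize, because resampling a mask changes areas and
component structure — the very quantities being measured.

## Temporal phenotypes

`Change⁺(t) = max(S_{t+1} − S_t, 0)` and `Change⁻(t) = max(S_t − S_{t+1}, 0)`
are computed element-wise on {0,1} masks, giving the exact decomposition
`S_{t+1} = (S_t \ Change⁻) ∪ Change⁺` with `Change⁺ ∩ Change⁻ = ∅` and area
conservation `|S_{t+1}| − |S_t| = |Change⁺| − |Change⁻|`. Decay and
occlusion are deliberately conflated: a disappearing pixel may be lost
tissue or a leaf moving in front, and both are treated as signal.

Connected components use 8-connectivity (edge or corner contact). Labeling
is delegated to `scipy.ndimage.label` with a full 3×3 structuring element,
which assigns ids in raster-scan order of each component's first pixel, so
results are deterministic; the test suite checks the induced partition
against an independent breadth-first flood fill. Centroids are unweighted
means of member pixel coordinates.

`Dispersion⁺` is the mean, over Change⁺ components, of the Euclidean
distance from each component's centroid to the centroid of its nearest
*other* component. Choices made here:

* With fewer than two components the nearest neighbour is undefined and the
  value is **missing** (NaN), propagated as absent through aggregation.
  Reporting 0 would fabricate "perfectly clustered" evidence.
* Nearest-neighbour ties cannot affect the value (tied distances are
  equal), so no tie-break policy leaks into the statistic.
* Distances are plain Euclidean in pixel units. The statistic is therefore
  translation-invariant and scales linearly when all centroid coordinates
  are scaled — both are property-tested.
* No negative-change analogue is computed; dispersion is a descriptor of
  growth placement.

For small component counts (≤ 64) nearest neighbours come from an exact
pairwise scan; beyond that a k-d tree query (k = 2) gives the same answer
in O(k log k). Real change masks can contain 10³–10⁵ components, which is
why the tree path exists.

## Perspective phenotypes

Silhouette extents are tight bounding boxes (`max − min + 1` over
foreground rows/columns). An empty silhouette at any view aborts that time
point as missing — a zero ratio would be a fabricated observation. The
model idealises equal heights across simultaneous views; real silhouettes
deviate by a few pixels, so the shared height h is taken as the **maximum**
over views (the least-occluded estimate, which reduces to the common value
whenever the idealisation holds), and the per-view height spread is
reported as a diagnostic column so users can see how far the assumption is
stressed. The identity `TWR = TARmin / TARmax` then holds algebraically
and is asserted to 1e−12 in tests.

The single-view baseline aspect ratio is height/width of the bounding box:
with this orientation an upright plant in vertical growth exceeds 1, which
matches how the trajectory behaves for tall species mid-season.

## Intermodal phenotypes

Both bounding-box crops are resampled bilinearly to the lower-resolution
crop's shape (fewer total pixels; ties keep the first crop's shape), the
foreground masks are resampled the same way and re-binarised at 0.5, and
paired intensities are read in raster order over the mask intersection
B₁₂. At least two overlap pixels are required. Alignment is purely
scale-based: the acquisition geometry keeps the plant registered across
modalities, so no spatial registration is attempted. RGB visible images
are reduced to ITU-R BT.601 luminance by default; per-band analysis is a
caller-side choice. Modality images carry no ground-truth masks, so the
default foreground rule is intensity > 0 (black background), with the
threshold exposed.

IC is Pearson's r, computed as `S_xy / √(S_x² S_y²)` from the sample
covariance matrix so that IC(X, X) is exactly 1 in floating point; values
outside [−1, 1] by more than 1e−12 are an internal error, smaller residue
is clipped. A constant channel makes r undefined: the value is reported
missing, never 0 (0 would claim "measured no relationship").

IMI uses 64 equal-width bins over [0, 255] for both marginals and the
64×64 joint histogram, entropies in bits with 0·log 0 := 0. The binning is
fixed rather than range-adaptive so entropies are comparable across time
points; 256 integer intensity levels fall exactly 4 per bin, making the
uniform-input entropy exactly 6 bits. By construction IMI = H(X) + H(Y) −
H(X,Y) ∈ [0, min(H(X), H(Y))] up to float residue, is symmetric under
modality swap, and IC is invariant under positive affine rescaling of a
channel before quantisation — all property-tested. IC/IMI are computed
over plant-overlap pixels only by default; a `full_box` flag switches to
the whole common bounding box for sensitivity analyses.

Note that histogram MI on finite samples is biased upward: independent
channels give IMI ≈ (m−1)(n−1)/(2N ln 2) rather than 0, decaying as the
overlap N grows. The test suite checks this decay rather than pretending
the bias away.

## Group statistics

The replication unit is the plant. Each plant's per-time series is
collapsed to its arithmetic mean with missing values excluded from both
numerator and denominator; an all-missing plant is excluded from the test
with a warning. Groups are compared with Welch's unequal-variance t-test
(two-sided p from the Student-t tail at Welch–Satterthwaite df). Two
degenerate cases are defined explicitly: both groups constant and equal
gives t = 0, p = 1; both constant and unequal is an error rather than an
infinite statistic. Two-sided p-values are used throughout, and no
multiple-testing correction is applied — the number of tests run is
reported so users can apply their own. Time-resolved summaries use
t-based confidence intervals per time point (mean only when a single
replicate remains).

## Synthetic scenes

The generator exists so that every phenotype can be checked against
construction-time truth rather than against another implementation.

*Temporal scenes* start from a centred base blob and, at each step, remove
previously planted components (exact negative change) and add new blobs
(exact positive change). Every placement enforces a Chebyshev gap ≥ 2 px
from all other foreground **including pixels vacated in the same step** —
without the latter, a new blob overlapping a just-removed region would have
part of its area already present at time t and the observed Change⁺
component would be clipped. The gap makes 8-connected merging impossible,
so planted counts and largest areas are recovered with integer equality.
Rectangular blobs hit their requested area exactly (⌈√A⌉-wide rows plus a
partial row); disk blobs are rendered and then measured, and the measured
area is what the truth log records.

*View scenes* render solid rectangles of prescribed height and per-view
widths, so bounding extents are exact by construction.

*Modality pairs* draw foreground intensities from a bivariate standard
normal with the target correlation ρ, mapped linearly to integer
intensities 1–255 (0 is reserved for background) via `128 + 40z` with
clipping. Quantisation and clipping attenuate |ρ| slightly, which is why
recovery tests use a ±0.05 band at ≥ 2000 overlap pixels; ρ = 1 with no
noise produces identical channels and hence IC exactly 1. Cohorts with
three modalities use a Cholesky factor of the 3×3 pairwise correlation
matrix.

*Cohorts* emulate a two-treatment experiment: by default 8 control + 8
drought plants, 6 time points, 96×96 px frames, a 150 px base plant, 2–4
growth events per step with areas uniform on [20, 60] px, and a 0.3
probability per step of one decay event. Drought multiplies every
growth-event area by a suppression factor (default 1.0 = null). These
sizes keep a 50-cohort power or calibration study under a minute on one
CPU while leaving the Welch test on plant-level means properly powered at
suppression 0.3. One global seed drives everything; per-plant seeds are
derived by a CRC32 hash of the plant id mixed with the global seed, so the
cohort is reproducible and insensitive to plant ordering.

What the generator does **not** emulate: real canopy geometry (blobs are
phantoms, not leaves), occlusion dynamics, segmentation noise at mask
boundaries, correlated event placement over time, or inter-view
consistency of a single 3-D plant. Passing tests therefore demonstrate
that the *measurement pipeline* is exact and the *statistical protocol* is
calibrated and powered — not that the phenotypes separate treatments on
any particular real dataset.

## Numerical and interface choices

* CSV output uses `%.12g` formatting so repeated runs are byte-identical.
* Change-overlay diagnostics (green = Change⁺, red = Change⁻ over a gray
  silhouette) and mean ± CI summaries are the only plotting-adjacent
  outputs; no styled figures are produced.
* The temporal family defaults to the 0° view on multi-view datasets
  (configurable); perspective statistics use all available views at a time
  point.
* Errors name the offending plant/time/view so batch runs over large
  cohorts are debuggable from the log alone.

## Known limitations

* Histogram-MI bias (above) makes small-overlap IMI values incomparable
  with large-overlap ones; compare like with like.
* Dispersion⁺ on masks with very many single-pixel components is dominated
  by nearest-neighbour distances of noise specks; no size filtering is
  applied by design (occlusion and overlap are treated as signal), so
  upstream mask quality matters.
* The equal-height idealisation for perspective ratios is only diagnosed
  (height spread), not corrected.
* Aggregate-then-test discards temporal structure; transient treatment
  effects that cancel over a season are invisible to the protocol by
  construction.
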