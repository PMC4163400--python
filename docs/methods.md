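# Methods

This note records how each stage of the pipeline is defined, the parameters
that matter, what the phantom generator does and does not emulate, and the
numerical choices made where the published-style description leaves room.

## Preprocessing

RGB input is reduced to grayscale by channel averaging followed by min–max
normalization to [0, 255]; a constant image maps to all zeros (divide-by-zero
guard). Grayscale input skips the averaging but is still normalized.
Intensities are carried in floating point and only quantized to 8 bits where
a histogram is needed or at export.

Denoising is explicit Perona–Malik diffusion on a 4-neighborhood: each sweep
adds `time_step · Σ_d g(∇_d, σ)·∇_d`, with `∇_d` the per-neighbor finite
difference (border replicated, so no flux crosses the frame) and `g` Tukey's
biweight. Defaults: `iterations = 80`, `sigma = 4.5` (the regime the method
was designed in), `time_step = 0.20`. The time step and neighborhood are
discretization conventions of this implementation; any value in (0, 0.25]
satisfies the explicit-scheme maximum principle, which the tests verify as
range preservation. With σ = 4.5 the scheme freezes any difference above
4.5 intensity units, so tissue interiors flatten over many iterations while
tissue boundaries are preserved essentially unchanged.

## Outer contour

`entropy_threshold` is Kapur's criterion: the level t maximizing the sum of
Shannon entropies of the class-normalized histograms (≤ t) and (> t), scanned
over all 256 levels, ties resolved to the smallest maximizer, levels leaving
a class empty excluded. Object polarity is decided by which class's mean
intensity differs most from the image-border mean, handling bright-on-dark
and dark-on-bright conditions alike. The binary object is the largest
8-connected component, hole-filled.

Known limitation: on near-noiseless images with extremely tight histogram
peaks, Kapur's criterion can prefer a level that slices a thin tail off a
peak. Such images have much less intensity spread than real microscope
frames; the guard below confines the effect in refinement, and the global
criterion is left exact (it is oracle-tested).

Refinement for low-contrast images: 8 rays at 45° steps from the mask
centroid; the intersection is the last foreground→background crossing
(robust to interior holes; leaving the frame counts as background). At each
contour point a local entropy threshold is computed in a disc of radius D̄/4.
A local level that leaves less than 5 % of its disc on either side is
replaced by the global level — a threshold that does not partition its
neighborhood carries no contour information. The eight (location, level)
pairs are interpolated by multilevel B-spline approximation: a coarse 4×4
cubic lattice fitted by the standard local least-squares update, then
repeatedly doubled and refitted on the residuals until every control point
agrees within 1 intensity unit. The evaluated surface is clamped to the range
the local levels span (the spline is unconstrained away from its eight
control points). The refined mask comes from pixelwise comparison against
the surface, with the global polarity.

When refinement runs: always for image type B; in `auto` mode when the
coefficient of variation of the object's boundary intensity exceeds 0.25,
measured on the boundary of the mask eroded by 2 % of the image side —
sampling the raw contour would measure the edge ramp itself and saturate the
trigger on every image.

Contour smoothing Gaussian-filters the mask indicator at `smooth_sigma`
(default 2 px) and re-binarizes at 0.5, producing the expected slight
shrinking and removing 1-px spurs.

## Flow-line partitioning

The gradient magnitude uses central differences with edge replication. For
partitioning the pipeline quantizes the gradient surface to integer levels
(it is an 8-bit intensity image in this data model); this lets flat areas
form plateaus and produces large homogeneous primitive regions instead of
noise-scale fragments. Descent steps to the strictly smaller 8-neighbor of
minimum value; among ties the last neighbor in a fixed row-major scan of the
3×3 window wins (the reference order is pinned and tested — any fixed order
satisfies the recursion). Terminating pixels that are 8-adjacent and
equal-valued are unioned, so plateaus become single regions. The recursion is
evaluated by pointer doubling, which provably yields the same labels with
logarithmic depth. Region statistics (256-bin histogram, entropy in bits,
centroid, extrema, boundary length as 4-adjacent unlike-label pairs,
adjacency) are computed vectorized.

## MDL clustering

Seeds: a circular kernel (radius 8 px, the expected epithelial tube
half-width scale) slides outward along each ray while its center is inside
the outer mask; the winning position minimizes the kernel mean intensity
(ties → nearest the centroid). The seed is anchored at the darkest pixel
inside the winning kernel: with a kernel wider than a thin branch, the
min-mean center may itself sit on mesenchyme, and anchoring guarantees the
seed's primitive region is epithelial. Seeds in the same region deduplicate;
deduplication down to a single seed is allowed (it means the epithelium
already forms one region), while fewer than two rays producing any candidate
is an error.

Growth: `G = nR_n H(R_n) + nC_i H(C_i) − nC_new H(C_new) + b1 + nb·b2`, with
entropies in bits recomputed from pooled 256-bin histograms (never averaged),
`b1 = ceil(log2(W·H))`, `b2 = 3`, and `nb` the count of shared 4-adjacent
boundary elements (each inter-region edge counted once per region pair). At
each step the candidate with the largest positive gain anywhere is merged;
ties break by smaller region id then smaller cluster id. Candidates must lie
inside the outer mask and their query window (the `window_max_regions = 100`
nearest regions by centroid) must reach the cluster. Adjacent clusters whose
mutual gain is positive union immediately, the smaller one treated as the
query (the formula is symmetric, so the choice is a convention). Each merge
reduces the total description length by exactly G, which the greedy log
verifies.

The raw cluster union is then regularized into the epithelial object:
morphological closing with a disk at the seed-kernel radius bridges sliver
arcs the greedy merge left unassigned (their ramp-heavy histograms make
their gains marginal), the same Gaussian smoothing used on the outer contour
removes boundary raggedness, and components below 5 % of the foreground are
dropped as merge debris. Holes are deliberately not filled — the epithelial
network may legitimately enclose lumina. `grow_clusters` itself returns the
raw union, preserving its stated contract.

## Skeleton and buds

Thinning uses topology-preserving morphological skeletonization to a 1-px,
8-connected skeleton; branches shorter than 3 px (`min_spur`) are pruned as
boundary-noise artifacts, except on junction-free skeletons. Endpoints have
one skeleton neighbor, branch pixels three or more; each endpoint's parent is
the first branch pixel reached walking through degree-2 pixels, or a sentinel
on a junction-free path. A junction is a connected clump of branch pixels:
endpoints whose parent pixels fall in the same clump share one junction (the
walks from different arms stop at different pixels of the same clump, so
pixel-level identity would over-count).

An endpoint qualifies as peripheral when its Euclidean distance to the
nearest outer-contour pixel (via a distance transform) is below 25 % of the
outer mask's bounding-box height ("the axis that transverses the lung object
vertically" read as bounding-box height). The default count is the number of
distinct parent junctions over qualifying endpoints, sentinel endpoints each
counting themselves; `count_mode="endpoints"` exposes the alternative reading
of counting the tips directly. Both conventions are genuinely defensible;
distinct parents is the default because sibling tips of one terminal
bifurcation represent a single budding event.

## Morphometry

Areas are foreground pixel counts, scaled by (40 µm)² for physical units.
Perimeters are the length of the boundary polygon traced through boundary
pixel centers by radial-sweep (Moore neighbor) tracing: axial steps count 1,
diagonal steps √2; interior holes do not contribute; a 10×10 square measures
36 px. DSC is reported in percent; the Dice of two empty masks is undefined
and raises. The epithelial mask is clipped to the outer mask before
reporting (logged when pixels were dropped).

## Phantom generator

The generator emulates the image class the measurement chain is built for:
one explant per 768 × 576 frame (40 µm/px), bright mesenchyme (mean 180) on a
dark background (mean 30) with darker epithelial tubing (mean 60), additive
Gaussian noise (sd 6), and two lighting regimes — type A (high contrast) and
type B with a linear illumination ramp (40 units across the frame) and an
exponentially decaying rim shadow (35 units). The imaging model is: structure
blur 1.2 px (soft tissue boundaries under the stereo microscope), noise, then
0.8 px optical/sensor blur so captured noise is spatially correlated, as the
published diffusion regime (σ = 4.5, 80 iterations) presupposes — pixel-white
noise of this amplitude would freeze under the Tukey function and no
parameter of the method could remove it.

Epithelial geometry: an annular airway loop (lobed ring) with
`n_buds_target` finger-like terminal buds attached at well-separated points,
each reaching toward the rim. Shapes are rasterized from signed distance
fields blended by a soft minimum, which fillets the junctions — a hard union
leaves cusps that skeletonize into spurious branches. `n_generations` (the
culture-day proxy, 1–4) modulates loop radius, wall thickness and finger
length; at `n_generations = 1` the epithelium degenerates to a single
unbranched tube whose distal tip is the one bud (the hull gains a basal body
so the proximal end is not peripheral). The outer hull is the dilation of
the tubing by 6 % of the frame side, smoothed and hole-filled.

This geometry was chosen over a recursively bifurcating tree for one
decisive reason: in a bifurcating tree sibling terminal tips always share
their parent junction, so no single ground-truth number can equal both the
count of qualifying endpoints and the count of distinct parents — the truth
would depend on the counting convention. With one finger per junction on a
closed loop (which itself has no skeleton endpoints), both conventions
provably equal `n_buds_target`, and the generator's validation asserts every
tip is peripheral under the default 25 % filter. Feasibility:
`n_buds_target ≤ 1` for one generation, else `min(2^n_generations, 10)`
(angular packing of fingers on the loop).

What the phantoms do not emulate: real tissue micro-texture, partial-volume
and depth-of-field effects, debris and bubbles in the culture medium,
multiple lobes, and the drastically increasing architectural complexity of
late culture days. Passing the recovery tests therefore demonstrates the
pipeline's correctness on well-posed explant images, not its performance on
every real-world frame; on real late-day images both manual raters and the
method are known to disagree substantially more.

The day profiles used by `generate_suite` (branching depth, bud count) are
(2, 2), (3, 3), (3, 4), (4, 6), (4, 8) for days 1–5, giving non-decreasing
bud medians over the culture period. The end-to-end evaluation in the test
suite uses 3 phantoms per day at the full acquisition frame, which completes
in about a minute on one CPU.

## Degenerate inputs and tie-breaks (summary)

- Constant image: grayscale normalization yields zeros; global segmentation
  raises a segmentation failure.
- Entropy threshold: smallest maximizing level; single-intensity histogram
  raises.
- Flow descent: last-in-scan-order neighbor among tied minima; plateau
  pixels union by equal-value adjacency.
- Merge ties: smaller region id, then smaller cluster id.
- Seed kernel ties: position nearest the centroid.
- Dice of two empty masks: undefined, raises rather than returning a number.

## Known limitations

- The MDL gain is marginal for regions whose histograms are dominated by
  edge-ramp pixels; the closing step absorbs the resulting sliver arcs, but
  a future refinement could model ramps explicitly.
- Kapur thresholding misbehaves on near-noiseless synthetic images (tight
  histogram peaks); out of scope for real microscope frames.
- One explant per frame is assumed throughout.
- The bud count is reported without hierarchy; generation-number analysis of
  the airway tree is out of scope.
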