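# Methods

This note records the models behind each module, the parameters that
matter and their defaults, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know about.
Every number quoted here is computed by the test suite or the analysis
scripts; none is asserted from memory.

## The tube model of a mitochondrial network

A network is a graph: tubular **edges** of half-width (radius) *r*,
**endpoints** of degree 1, **branchpoints** of degree ≥ 3. Surface areas
follow the cylinder + hemisphere model: an edge of length *l* carries
lateral area `2πr·l`; each endpoint carries a cap `2πr²`. Branchpoints
lie on edge tubing and carry no area of their own, so area fractions are
normalized over endpoints and edges only — the two classes the
preference statistic compares. A single graph-wide radius (the
length-weighted mean of per-edge radii) enters both formulas, mirroring
the use of an average mitochondrial width; per-edge radii are retained
on the graph for inspection. For a single tube the endpoint area
fraction reduces algebraically to `2r/(2r+l)`.

Defaults: `tube_radius_nm = 250` (tube width ~500 nm, the width of a
mitochondrion), `pixel_size_nm = 45` (so a 3-pixel detection kernel is
135 nm).

## Location preference statistics

With `n_end`, `n_edge` pit counts, `p = n_end/(n_end+n_edge)`:

* uncorrected odds `p/(1−p)`, χ² against a 50/50 null (df = 1, no
  continuity correction by default; Yates available via a flag — the
  convention is stated because printed χ² values in the literature often
  cannot be reconstructed without the raw per-class counts);
* corrected odds ratio `OR = [p/(1−p)]·[a_edge/a_end]`, i.e. observed
  odds divided by the odds expected under uniform-per-area placement;
  preference percentage `100·OR/(1+OR)`; χ² against the area-weighted
  null when counts are available.

χ² upper tails use the regularized incomplete gamma
(`Q(df/2, χ²/2)`); the tests check df 1–5 over χ² ∈ [0.5, 80] against
independent numerical quadrature of the χ² density at 1e-10 relative
tolerance. p-values display at 2 significant figures with a
`< 2.2e-16` floor; full precision is kept in JSON outputs.

## The synthetic scene generator

The generator exists so that every downstream operator can be validated
against planted truth. It emulates:

* tree-shaped tubular networks grown segment-by-segment with gentle
  heading jitter; components are rejected and resampled (≤ 100 tries) if
  they leave the field or come within 3 tube radii of an already-placed
  component, so truth areas stay exact;
* class-weighted spot placement: class probability ∝ weight × class
  area (endpoints/branchpoints: caps `2πr²`; edges: `2πr·l`), a
  detachable **free fraction**, positions uniform within the chosen
  class region;
* imaging: PSF-blurred tubes in the anchor (membrane) channel, a thinner
  (0.8 r) core in the matrix channel, analytic Gaussian puncta plus a dim
  (0.15×) tube term in the hook channel; Poisson photon noise and
  Gaussian read noise. Defaults: `psf_sigma_nm = 90`, spot amplitude
  200, tube amplitude 120, background 10, read noise 2 — a mid-range
  confocal regime where puncta are ~10× brighter than the diffuse
  rerouted-hook signal;
* profile triplets (per-channel 1-D Gaussians with planted offsets
  −80 nm anchor, −180 nm matrix relative to the hook peak) and
  elliptical double-membrane contour pairs (outer diameter 120 nm,
  intermembrane distance 15 nm, axis ratio 1.2, 2 nm point noise).

**Placement tolerances.** Planted class labels must agree with the
nearest-node assignment rule under pixel-level localisation error, so
node spots jitter within 0.3 r of their node and edge spots exclude a
1.8 r zone around nodes (lateral jitter ≤ 0.4 r); free spots keep 2.5 r
clearance from every tube axis. Class *probabilities* are unaffected —
the mixture law (frequency ∝ weight × area) is verified at n = 30 000
with closed-form expectations — only the within-class position
distribution is trimmed at the class boundaries.

**What is not emulated:** photophysics (bleaching, blinking), 3-D PSFs
and axial structure, time-lapse dynamics (fission/fusion), tube-radius
variability within a network, non-tree topologies (loops), and spatially
varying background. Consequently, passing tests demonstrate that the
operators are correct for resolvable puncta on tubular networks under
Poisson+read noise; they do not certify performance on crowded scenes
(overlapping pits merge and are counted once — visible as a downward
bias of the recovered odds ratio at high endpoint weight), out-of-focus
structure, or labeling artifacts.

All generators draw from one `numpy` Generator seeded per call; seeds
are required fields, never implicit, and everything is bit-reproducible
for a fixed (spec, seed).

## Spot detection and segmentation

Detection is the particle-analysis recipe: difference-of-Gaussians
band-pass at the kernel scale (kernel 3 px = 135 nm as FWHM; second
scale 2×), threshold, connected components, then area and circularity
filters (defaults 0.03–1.5 µm², circularity `4πA/P²` in 0.4–1.0; an
endocytosis preset ships with 0–1 µm² and 0.3–1.0). Numerical details:

* **Perimeter** is measured on the marching-squares boundary polygon
  after periodic moving-average smoothing (window 5): the raw pixel
  polygon overestimates smooth-curve length by several percent. A large
  disc then measures circularity within 0.05 of 1.0 and a square within
  0.05 of the hand value π/4. Circularity is capped at 1.0 on report;
  a single-pixel component (zero perimeter) counts as a disc.
* **Automatic thresholds** (Otsu, IsoData) are guarded by a robust noise
  floor (median + 4×1.4826·MAD of the unclipped band-pass): histogram
  splits on noise-only fields would otherwise manufacture thousands of
  false components. Numeric thresholds are taken literally.
* **Centroids** are intensity-weighted (sub-pixel); records are sorted
  by position for determinism.

Segmentation smooths (σ = 1 px) and thresholds; the default `half_max`
method — midpoint between the median (background) and maximum of the
smoothed image — places the mask boundary at the edge-spread-function
half level, i.e. at the true tube edge under symmetric PSF blur, where
Otsu sits systematically lower and widens tube masks by about a pixel.
Otsu/IsoData/numeric remain available. Objects below 0.1 µm² are
removed.

A spot is **free** when its centroid lies farther from the
(matrix-channel) mask than its own radius — equivalently, outside the
mask dilated by one spot radius. With zero spots the free fraction is
reported as missing, not 0. **Colocalization** matches greedily by
ascending pairwise distance under a 2-px cap, each spot used once; the
matched count is symmetric in the argument order. **Density** is spots
per 100 µm² of mask area.

The end-to-end study pipeline uses a numeric band-pass threshold of 20
(a manual-threshold equivalent): under the default imaging model
punctum responses are ~66 band-pass units and diffuse/tube-end
responses ~5, so any value in between separates them the way manual
thresholds do in cell images.

## Skeleton graphs from masks

Masks are skeletonized; skeleton pixels with one neighbour are
endpoints, clusters of pixels with ≥ 3 neighbours are branchpoints,
chains between them are edges. Accuracy-relevant steps, each with a
geometric rationale:

* **Chain smoothing** (moving average, window 5, ends fixed) removes the
  8-connected staircase whose raw arc length runs a few percent long.
* **Tip extension**: skeletonization retracts tube tips, so each
  terminal chain is extended along its local direction to one radius
  short of the mask boundary — the cap center of a stadium-shaped tube.
* **Radius** is the mean Euclidean distance transform along the chain
  minus 0.5 px (the raster boundary sits half a pixel beyond the last
  foreground pixel center).
* **Spur pruning** removes terminal edges shorter than one tube radius
  (estimated from the EDT median if not given); junctions left with
  degree 2 are merged away and node classes are re-derived from final
  degrees. A mask with no elongated structure (e.g. a filled disc)
  yields a degenerate zero-edge graph with a warning.

On rendered noiseless tubes these steps recover edge length within ~2%
and radius within ~6% (under default noise, ~8%); the tests enforce the
5% / 10% contract. Isolated skeleton cycles (no node pixels) are ignored
— generated networks are trees.

**Location assignment**: a spot farther than a dilation distance
(default 135 nm) outside the mask is free; otherwise it takes the class
of the nearest endpoint/branchpoint node within
`assignment_radius_factor` (default 1.0) tube radii, an exact tie going
to endpoint (the hypothesis class; ties are measure-zero); otherwise
edge. Counts partition the input exactly.

## Profiles and vesicle contours

Gaussian fits (`baseline + A·exp(−(x−c)²/2σ²)`) initialize from moments
(baseline = min, amplitude = range, center = intensity-weighted mean,
σ = weighted SD floored at the sample spacing) and use bounded
least squares; a flat trace returns a non-converged result rather than
raising. Ensemble averaging shifts each profile so the reference
(hook) peak sits at 0, excludes (and counts) profiles whose reference
fit fails, and linearly interpolates onto a symmetric common grid at the
finest input spacing, restricted to the common support so no
extrapolation occurs. Widths are reported both as σ and FWHM
(= 2√(2 ln 2)·σ); which one a given published "width" denotes is often
unstated, so both are emitted.

Contours are centered and rotated so the largest-variance principal
axis lies along y = 0 (proper rotation; the 180° ambiguity is fixed by
requiring the first point at x ≥ 0; collinear input is an error). The
**outer diameter** is the mean of the two principal extents computed
from second moments, `2√(2·var)` per axis: for an ellipse sampled
uniformly in angle this equals the geometric extent exactly, and unlike
raw min/max spans it is not extreme-value biased by tracing noise
(raw spans overestimate by ~4 nm at 2 nm point noise with 100-point
contours; they remain available as `extent_method="feret"`). The
**intermembrane distance** is the mean distance from inner points to
the outer contour polyline (it carries a small negative bias, ~1–2 nm
at 2 nm point noise, from measuring to the nearest point of a jagged
polygon); crossing contours are an error.

## Energetics

`G_bending = 8πκ/(4πr²) = 2κ/r²` (k_BT nm⁻²); the identity of the two
forms is property-tested to machine precision. The formation cost of an
n-membraned vesicle defaults to the per-membrane convention
`n·(2κ/r² + γ)`: with κ = 15 k_BT, γ = 0.0025 k_BT nm⁻², r = 60 nm and
n = 2 this gives 0.0217 (≈ 0.022) k_BT nm⁻², which is the convention
consistent with the published total; the literal single-tension variant
`n·2κ/r² + γ` (= 0.0192) is available via `tension_per_membrane=False`.
Unquantified contributions (cargo crowding, inter-membrane coupling)
enter as an optional additive density, default 0. The clathrin budget
is 0.08 k_BT nm⁻²; feasibility is `budget ≥ cost` with the margin
reported, and a sweep helper grids (κ, γ, r, n). A coated pit (r =
60 nm) curves ~4× tighter than a mitochondrial endpoint (r = 250 nm).

## The end-to-end study

`RunConfig` composes all stage specs under one master seed; per-stage,
per-scene seeds are SHA-256 hashes of `(master, stage, index)` reduced
below 2³¹, so stages can be rerun in isolation. Each scene is generated,
rendered, detected, segmented (matrix channel → free-spot mask; anchor
channel → tube mask for the skeleton graph, matching how the membrane
and matrix markers are used on real images), skeletonized, assigned and
pooled; the corrected odds ratio gets a percentile bootstrap interval
(default 1000 label resamples). Reports contain no timestamps, so
identical configs produce byte-identical reports.

**Problem sizes.** The recovery study uses 10 scenes of 10 mostly
unbranched mitochondria (≈ 20 endpoints) in a 46 µm field with 10 spots
per scene. The spot budget keeps per-endpoint occupancy low — roughly
one pit per occupied endpoint, as in cells — because two pits on the
same endpoint merge into one detection and deflate the recovered odds
ratio; at endpoint weight 47.5 a mild residual deflation remains
(recovered ≈ 36 pooled across scenes) and the planted weight is
recovered within the bootstrap interval, as it is at weights 1 and 5.

## Known limitations

* 2-D only: scenes, masks and graphs are planar; the statistics depend
  only on areas and counts, which the 2-D tube model carries, but true
  3-D network geometry (z-overlap, axial blur) is not represented.
* Crowding: overlapping puncta are detected once; recovery of placement
  weights degrades gracefully (bootstrap intervals still cover) but the
  point estimate biases low as occupancy rises.
* The colocalization estimator deliberately reproduces the greedy
  capped-distance definition, which underestimates when one channel is
  much denser than the other.
* Skeleton radius inherits the segmentation boundary (~±6%); area
  fractions from images are correspondingly approximate, while
  truth-graph area fractions are exact.
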