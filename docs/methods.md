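# Methods

`marginmap` re-implements an intraoperative margin-assessment workflow
for Mohs micrographic surgery (MMS) as a tested library: gross-specimen
3D measurement with grossing/inking recommendations, whole-slide-image
(WSI) preprocessing and patch-graph prediction, ink-based section
orientation, and optimal-transport mapping of histological findings onto
the surgeon's hand-drawn tumor map.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Conventions

All angles are degrees under a single clock convention defined in
`inkorient`: image coordinates have x right and y down; 0° points up on
screen; angles increase clockwise.  A correctly laid section — blue ink
at 12 o'clock, red at 6 — has a blue→red line angle of 180°.
`relative_angle(a, b)` is the signed smallest rotation taking `b` onto
`a`, in [−180, 180).

## Slide preprocessing (`slideprep`)

The tissue mask is a filter chain: near-white removal (mean RGB > 235),
removal of large low-saturation objects (saturation < 0.08, area > 10⁴
px — scanner text and pen), binary closing + Gaussian blur +
re-threshold, then small-object/small-hole removal (64 px²).  All
cutoffs live in `MaskParams`; the defaults match the synthetic fixtures'
contrast and are deliberately conservative for real H&E material.

Patches are non-overlapping squares (default 256 px, stride = size,
addressed by top-left corner) kept when their tissue fraction is at
least `min_tissue_frac` (default 0.5 — the threshold itself is a free
parameter of the protocol and is surfaced in every config).

Sections are connected components of the patch-center radius graph at a
large radius (4096 px for 256-px patches), pieces at a small radius
(512 px); both scale linearly with patch size.  When a section shows
fewer pieces than the grossing protocol expects, its largest candidate
piece is split by spectral clustering (RBF affinity with bandwidth =
piece radius, k = deficit + 1, fixed seed) and the step repeats until
the expectation is met.  Observing *more* sections than expected raises
an error rather than silently merging — the condition indicates either
a wrong expectation or fragmented tissue, and both need a human.

Hole/tear candidates come from an alpha shape per piece: Delaunay
triangles of the patch centers whose circumradius is below 1/alpha
(default alpha = 1/(2·patch) → 512-px circumradius) are unioned, which
outlines the piece while bridging tears open to the boundary.  The
shape is dilated by a quarter patch before the containment test: the
alpha shape runs through patch *centers*, systematically half a patch
inside the true tissue rim, and the quarter-patch dilation cancels that
discretization offset without swallowing marginal rim cells (a clean
convex piece still yields zero candidates).  Grid cells inside the
dilated shape but absent from the tissue set join the `macro_map`
configuration flagged as hole candidates; `macro_map` is a superset of
`tumor_map` by construction.

## Ink orientation (`inkorient`)

Tissue edges are localized by a Sobel gradient of the mask, dilated to a
band (default 16 px) and cleaned by opening.  Ink is detected per color
by HSV thresholds intersected with the band, then connected components
below 50 px are discarded as spurious applications.  Ink outside the
band — interior seepage, pen — is never credited.  Default HSV ranges
(hue in degrees): blue 200–260, red 0–15 ∪ 345–360, saturation ≥ 0.35,
value ≥ 0.2; thresholds of this kind are normally tuned per scanner by
a sensitivity sweep, so all ranges are configurable.  Centroids are the
mean, coordinatewise median, or 10%-trimmed mean of the surviving
pixels; the blue→red centroid line defines the section's clock angle.
On rendered fixtures with random rotations the recovered angle is
within 5° of truth in ≥ 90% of sections and rotation of the raster is
equivariant to within 1°.

## Patch models (`patchnet`)

The prediction stack is CNN embeddings → radius graph → graph-attention
network (GAT), with two tasks: `tumor_map` (tumor / benign /
inflammation — a patch containing both tumor and inflammatory cells is
labelled tumor, and modeling inflammation as its own class is retained
because tumor–inflammation context is informative) and `macro_map`
(hole-tear / fat / epidermis / dermis).

The networks are implemented on a small vectorized reverse-mode
autodiff engine (`_autodiff`, `_nn`) written for this package; gradients
are verified against numerical differentiation in the test-suite.  The
default backbone is a four-block stride-2 convolutional classifier over
32×32 inputs with a 64-dimensional global-pooled embedding; a deeper
backbone (e.g. a residual network with 2048-d embeddings) is a config
choice, not a code change — the backbone is an acceleration/capacity
detail, not the method.  Training follows the reference recipe: CNN
batch 32, lr 1e-4, 100 epochs; GAT layers 32/32/64 (single head)
interspersed with DropEdge 0.2 and Dropout 0.2, batch 16 graphs, lr
1e-2, 1500 epochs; Adam under cosine annealing throughout; every run is
seeded and bit-reproducible.  Dropout is applied between graph layers
only, not to the raw embeddings.  The `desk()` profile differs only in
epoch counts (CNN 40, GNN 400) so that the full pipeline trains in
tens of seconds on one CPU.

Graphs connect nodes (patch centers or nucleus centroids — the
machinery does not care) within a radius; edges are undirected, without
self-loops in storage (self-loops are added inside the GAT).
Predictions are permutation-equivariant and translation-invariant by
construction, and both properties are asserted exactly in tests.

Prediction propagation is a fixed-weight message pass: a query point
averages the probabilities of nodes within the graph radius with
inverse-distance weights (exact hit → that node's row); queries with no
node in radius are flagged missing, never extrapolated.

Follicle docking: hair follicles mimic basaloid tumor nests, so tumor
probabilities are docked near detected follicles.  Around each patch
three concentric circles of 128/256/512 px are drawn; the penalty is
the convex combination Σ wᵢ·overlapᵢ of the circles' follicle-overlap
fractions with weights (0.6, 0.3, 0.1) — normalized to sum to one and
decreasing with radius, weighting proximity most — and the adjusted
probability is p·(1 − penalty).  The reference description fixes only
the circle radii and the ordering of the weights; the convex
combination is this package's reading of the 0–1 normalization, and the
weights are configurable.  Overlap uses exact polygon clipping
(buffered circles at 64 segments per quadrant).

Evaluation: pooled ROC AUC or macro-AUC (per-slide AUC averaged with
equal slide weight, slides lacking a class skipped with a warning), and
a cluster bootstrap (resampling slides with replacement, 1000
replicates, percentile interval) for confidence intervals.

## Gross 3D (`gross3d`)

The photogrammetric reconstruction itself is external; this module
consumes point clouds and turntable frames.  Frame segmentation is
intensity thresholding + connected components + size filter, with
optional 1-in-10 frame subsampling to bound reconstruction cost.
Trajectory filtering exploits the fact that only the revolving specimen
traces an ellipse across frames: a RANSAC ellipse over detection
centroids rejects static distractors; inlier scoring uses unique
centroid positions so a distractor repeated in every frame cannot
outvote the specimen.  Scale calibration fits a RANSAC ellipse to
Scharr edges of the turntable rim; scale = known diameter / fitted
major axis, since an obliquely viewed circle preserves its diameter
along the major axis.  The ellipse RANSAC wrapper tolerates degenerate
minimal samples (collinear points make the conic fit complex-valued).

Orientation: k-NN outlier removal (mean 8-NN distance beyond
mean + 2 sd), PCA pre-alignment (smallest-variance axis to z), a
density-based flip test (the dense flat cut face must be at the
bottom; bands anchored at robust quantiles), RANSAC plane fit over the
lowest 20% of points with inlier threshold 2× a local-spacing noise
estimate, rotation of the plane normal onto −z, translation of the
centroid to the origin, and — when suture-colored points (default dark
navy, HSV-configurable) are found — an in-plane rotation taking the
suture direction to +y.  Without a suture the in-plane rotation is left
at zero and flagged rather than guessed.

Measurement: L/W/H are the maximal y/x/z extents in cm.  The default
estimator is noise-robust: the raw max inflates like σ√(2 ln n) with
point count, so each bounding face is located instead by an iterated
re-centered median window (window 8σ̂, refinement ±2.5σ̂, σ̂ from a
one-sided MAD over the flat bottom face — one-sided because only the
region below the face plane is contamination-free).  Suture-colored
points are excluded from measurement; the thread is not tissue and is
removed before grossing.  On ten boxlike fixtures at 0.02 cm noise the
recovered extents are within 2% of truth with an MAD of ~0.006 cm;
the study-scale comparison against manual calipers (~0.29 cm MAD) is
not reproducible without the original videos.

Grossing plans: Mohs mode draws the 12→6 blue/red line, adding a black
bisection line at y = 0 with a blue-red pair per half when the length
exceeds `slide_fit_cm` (default 2.0 — the trigger length is not
specified by the protocol and is a config choice).  Breadloaf mode
places side-to-side cut lines spaced `spacing_cm` (0.5–1.0 cm; values
outside warn) symmetric about the centroid, left halves blue, right
halves cycling red/yellow/green/purple/orange so multiple pieces can
share a cassette.

Surface refinement resamples z and RGB on a regular x-y grid by
radius-neighbor averaging; cells without neighbors are omitted.

## Tumor mapping (`sitemap`)

A section is a 2-D point cloud of patch centers carrying class
probabilities.  It is registered to the surgeon's template ellipse by
minimizing the order-2 sliced Wasserstein distance to a fixed uniform
sample of the ellipse interior (n_target = max(1024, n); the target
sample is drawn once per run, not re-sampled per iteration).  The 1-D
transport along each direction is computed exactly on the merged
quantile grid of the two empirical distributions.

The descent first applies a shape-preserving affine pre-alignment
(centroid to the ellipse center, isotropic std-matched scale), then for
300 iterations matches sorted projections along 64 fresh random
directions and relaxes every point toward its matched target quantile.
The step is a dimensionless relaxation factor (default 1.0, decayed by
0.98 per iteration) multiplying the raw quantile-matching displacement
— i.e., plain gradient descent on the squared sliced distance.  A
normalized fixed-length step was rejected: it moves points already at
the optimum by a full step length, breaking the fixed-point property
(uniform points should stay put up to sampling noise), whereas
raw-displacement relaxation converges geometrically and leaves a
uniform cloud essentially unmoved.  Probabilities are carried through
transport unchanged; point count is conserved; reported distances use
512 projections.

The final rotation about the ellipse center is
`relative_angle(template line, morphed section line)`, matching the
template's blue/red marks; a section with a missing ink line raises an
error instructing manual orientation instead of guessing.  Density
overlays are Gaussian KDEs (Scott's bandwidth by default) over the
transported points weighted by a class probability, max-normalized so
thresholds cut in [0, 1]; contour area is monotone non-increasing in
the threshold.

Concordance between surgeon-drawn and algorithm-generated maps is a
proportion with a Jeffreys Beta(0.5, 0.5) prior: k concordant of n
cases gives the posterior Beta(0.5 + k, 0.5 + n − k), summarized by its
2.5/50/97.5% quantiles (exact, via the regularized incomplete Beta
inverse).  For 28 concordant of 28 cases this yields a 99.2% point
estimate with a 91.5–99.9% credible interval.

## Synthetic studies (`synthfix`) — what they do and do not show

Every generator is a pure function of spec + seed and returns the input
plus machine-readable ground truth, so downstream operations are scored
without re-deriving truth from pixels.

*Sections* are blobby polygons with low-amplitude texture and speckle;
tumor regions carry darker, higher-frequency speckle so a small CNN can
separate the classes; inks are saturated 8–16 px bands on the outer
boundary at known clock positions; holes, boundary tears, follicle
disks and conjoined lobes are available per spec.  *Specimen clouds*
sample a box surface (dense flat bottom), add Gaussian noise (default
0.02 cm), apply a rigid transform, and color a suture marker at a known
clock position.  *Turntable frames* show a dark blob revolving on an
elliptical path over a rimmed table, with optional static distractors.
*Map templates* carry a black ellipse with blue/red marks.

The contextual-label node dataset places nodes on a jittered grid with
an iid latent z per node; the label thresholds
(1−g)·zᵢ + g·mean over the closed neighborhood of z at zero, and
features are z embedded in d dims plus noise (default sd 0.2, an SNR
of 5:1).  At g = 0 labels are independent of neighbor features; at
g = 1 they are a pure neighborhood average, so context helps by
construction.  Two of these defaults are deliberate: the closed
(self-inclusive) neighborhood and the 5:1 SNR keep the task within the
representable range of a three-layer attention network, whose repeated
aggregation necessarily smooths over ~3 hops — with an open
neighborhood or noisier features even the noise-free smoothed oracle
cannot reach the intended operating point (held-out AUC ≥ 0.9).

What passing these fixtures does *not* show: real H&E stain variation,
scanner artifacts, out-of-focus regions, genuinely ambiguous
tumor/follicle morphology, photogrammetric reconstruction failure
modes, or ink colors degraded by processing.  The fixtures validate the
geometry, the statistics, and the learning machinery — not clinical
performance.

## Problem sizes

The test-suite and the demo pipeline run at desk scale by choice:
64-px patches on ~1024² rasters (a few dozen to a few hundred patches
per slide), 4 train / 2 test slides for the learning experiments,
4000-point clouds, and 10–20 seeds per property suite.  All sizes are
plain parameters; the full-scale configuration (256-px patches,
2048-d embeddings, full epoch counts) is expressible through the same
configs.

## Known limitations

* SVS/pyramidal WSI reading is out of scope; rasters are PNG/TIFF at
  one working level.
* The follicle and nucleus detectors are consumed as masks, not
  trained here; the cell-graph classifier reuses the patch-graph
  machinery rather than being a separate model.
* GrabCut-style refinement of frame segmentation is not implemented;
  the thresholding path is the supported one.
* The spectral split assumes the piece-count expectation is correct;
  an over-count of sections errors out deliberately.
* Sliced-Wasserstein morphing preserves relative positioning only
  approximately (rank correlation of pairwise distances ≥ 0.8 on
  fixtures), and angular positions through the morph are accurate to
  roughly ±12° at desk scale — adequate for the 15° orientation
  tolerance used clinically, but not exact.
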