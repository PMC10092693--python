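# Methods

`mitoquant` quantifies the 3D morphology of fluorescently labelled
mitochondrial networks in confocal z-stacks: it enhances and segments
tubular structures, reduces them to a skeleton graph, and summarises each
cell's network with the standard connectivity metrics (total length, node
and edge counts, junction types, average degree, PHI, connectivity score).
A companion phantom generator produces synthetic stacks with exact ground
truth, so every stage of the pipeline is validated against known geometry.
This note records the models, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## Raster model and coordinates

All images are `(z, y, x)` grids with physical voxel spacing in µm; the
physical coordinate of a voxel is `index × spacing` per axis.  The default
spacing (0.104 µm in-plane, 0.72 µm z-step) reflects spinning-disc
acquisition with a 25× objective plus magnifying tube lens; anisotropy of
~7× between z and xy is the central geometric fact the pipeline must deal
with.  Spacing is supplied by the user or a sidecar file — TIFF resolution
tags are treated as advisory, because acquisition metadata is unreliable
across dialects.

Per-slice registration corrects in-plane drift during z-stack acquisition
(e.g. from heartbeat-driven tissue motion).  The model is translation-only:
sequential phase correlation between neighbouring planes, chained to a
reference plane, applied with subpixel linear interpolation.  Translation
suffices for drift and jitter and — unlike rotational or elastic models —
cannot distort lengths.  For two-channel stacks the shifts computed on one
channel are applied identically to the other.  Shifted planes use a
reflective boundary fill; a constant fill leaves dark bands that bias any
subsequent correlation (this is visible as a failure of registration
idempotence).

## Tubular enhancement and segmentation

The mitochondria channel is resampled to isotropic voxels (linear
interpolation, finest spacing component) before any Hessian analysis or
thinning: eigenvalue analysis on a 7:1 anisotropic grid systematically
biases orientation estimates toward the coarse axis.

Enhancement is a multiscale Hessian-eigenvalue tubularity (vesselness)
filter for bright curvilinear structures, taking the per-voxel maximum over
scales sampled uniformly in `[min_scale, max_scale]` (in-plane voxel units;
default 1.0–2.5 over 6 scales, spanning tube radii of ~1–2.5 voxels; a
narrow 1.5–2.0 × 6 set helps weak-signal stacks).  Before filtering, the
image is smoothed with a 1-voxel Gaussian: structure below the optical PSF
is noise by definition, and unsmoothed shot noise — especially once
z-resampling stretches it into short axial streaks — otherwise reads as
fine-scale tubularity.  The response is rescaled to `[0, 1]`.

Segmentation thresholds the response with a local adaptive rule (voxel >
mean over a block of half-width 10 voxels, plus a small offset) combined
with a global floor that suppresses flicker in empty regions.  The floor is
noise-adaptive by default: the image noise is estimated robustly
(wavelet-detail sigma, computed on the *original* stack — isotropic
resampling correlates the noise and hides it from the estimator),
normalised by the bright-signal level, and mapped to a floor between 0.10
(clean images, keeping dim tubule segments) and ~0.17 at peak SNR 5 (where
shot-noise ridges in the response reach ~0.13 and would otherwise attach
spurious outgrowths to the tubule halo).  Connected components smaller than
0.15 µm³ are then removed — a physical, spacing-independent floor far below
any real tubule fragment (a 0.4 µm stub exceeds it) but above noise blobs.
The resulting mask deliberately includes
the blurred halo of each tubule: the halo is harmless for skeletonization
and makes dim tubule segments robust.  When a voxel-accurate mask is needed
(e.g. for voxel-level benchmarking), `segment_mitochondria` can refine the
mask to the full-width-half-maximum support of the intensity image — the
standard definition of object extent in fluorescence — at the cost of
sensitivity to dim segments near bright junctions.

For mask benchmarking, the ground truth is the image-space tube support:
the half-maximum region of the noise-free rendering.  A geometric
radius-`r` ball around the true curve is not an attainable reference — the
imaged tube is ~0.6× the geometric radius laterally and ~1.5× axially once
the Gaussian profile and the anisotropic PSF are accounted for.

## Skeletons and skeleton graphs

The binary mask is thinned with the standard topology-preserving 3D
medial-axis algorithm on the isotropic grid, and the skeleton stays on that
grid with its own (isotropic) spacing: mapping a one-voxel-wide curve back
onto a grid with a 7× coarser z-axis destroys both thinness and topology,
while keeping the isotropic spacing preserves all metric quantities.

Graph extraction uses 26-connectivity throughout.  Skeleton voxels with a
neighbour count other than 2 are node voxels; mutually adjacent node voxels
merge into a single node at their centroid (thinning routinely emits 2–3
adjacent branch voxels at one true junction).  Maximal degree-2 chains
become edges whose polylines run through the voxel centres, with length
measured along the polyline (not the endpoint chord) — the "total network
length" semantics.  Isolated cycles receive one synthetic degree-2 anchor
node carrying a self-loop, so loops (which are real in these networks)
contribute length and component membership; anchors are excluded from the
free-end/junction tallies and from `n_nodes`.  Chain tracing visits voxels
in lexicographic (z, y, x) order, so output is reproducible bit-for-bit.

Two post-processing passes stabilise graph topology against digitization
jitter, both with thresholds at the scale of the optical resolution:

* **Spur pruning** removes terminal edges shorter than 0.5 µm whose inner
  endpoint is a junction.  Thinning emits such spurs at junctions and tube
  ends; they are artifacts, and whether a given spur appears flips with
  sub-voxel intensity changes.  Contraction of the leftover degree-2 node
  merges the flanking edges (including the small intra-junction gap, which
  slightly improves length accuracy).
* **Junction merging** collapses junction–junction edges shorter than
  0.3 µm: a 4-way crossing is resolved by thinning inconsistently as one X
  node or two nearby Y nodes; collapsing sub-resolution edges canonicalises
  both to the X form.

Both passes are enabled in the pipeline defaults and exposed as standalone
functions; raw `build_graph` output is untouched for voxel-level oracle
comparisons.

## Network metrics

* `avg_degree` is the graph-theoretic mean degree (sum of degrees over all
  graph nodes, a self-loop counting 2).  This is a deliberate sharpening of
  the looser "average number of edges per node" phrasing: it is the
  standard definition and is monotone in connectivity.
* `phi` is the total edge length of the length-largest connected component
  divided by total length (PHI is a length ratio, so "largest" means
  largest by length, not node count); `phi = 1` iff the network is one
  component.
* `conn_score` defaults to the surrogate formula
  `phi × avg_degree × avg_edge_length_um`.  The published connectivity
  score is defined in external analysis scripts whose exact formula is not
  restated here; the surrogate increases strictly in each factor, separates
  fragmented from filamentous phantom cohorts perfectly, and is pluggable
  (`SCORE_FORMULAS`) so another definition can be dropped in without API
  change.  The fragmentation threshold default of 3.0 is honoured but is
  formula-dependent and must be recalibrated if the formula is replaced.
* Phenotype call: `fragmented` iff `conn_score < threshold` (strict).

Degenerate cases: an empty graph reports zero counts and missing (NaN)
ratios; constructed ground-truth graphs may contain degree-2 "passthrough"
nodes (e.g. bridge endpoints after network expansion) which count toward
`n_nodes` but toward no junction category.

## Phantoms

The generator emulates a single secondary-islet cell (or a small cluster of
1–4 touching cells) with curvilinear mitochondrial tubules placed in the
peripheral band of each ellipsoidal cell — mitochondria in these cells sit
at the cell periphery, which is also exactly what makes the multi-cell
masking problem hard (adjacent cells' mitochondria end up closely apposed
across the contact plane).

Tubules are bounded-curvature random walks (coarse 0.6 µm control steps,
cubic-spline resampled at 0.15 µm) with radius 0.4 µm — inside the
0.2–0.5 µm range of real mitochondrial tubules and above the
rasterizability bound of half the coarsest spacing component.  Default: 12
tubules of 2–6 µm per cell (~45–50 µm of network), matching the tens of
micrometres of network seen in these cells.  Topology modes: `filamentous`
fuses tubules into one component via 3-way junctions (each new tubule
starts at an interior point of an existing one); `fragmented` leaves them
disjoint; `expanded` adds bridges.  All randomness derives from one integer
seed through `SeedSequence` spawning (stream 0 geometry, stream 1 rendering
noise).

Interventions model the two treatment phenotypes:

* `fragment_network` excises intervals (default 2× tubule radius) at
  positions uniform along edge arc length.  An interval that reaches a
  junction-side edge end detaches the edge there — the junction loses a
  tubule, as in fission at a branch point — while cuts that would nibble a
  free end are shifted inward.  On acyclic networks every cut adds exactly
  one component.  This placement rule is what lets fragmentation reduce
  3-way junction counts, which purely interior cuts can never do.
* `expand_network` adds straight bridges between not-yet-adjacent node
  pairs of the same cell (ellipsoid convexity keeps them inside): length
  and edges rise, node count is unchanged — the oxidative-stress signature.

Rendering: exact distance to the polylines (KD-tree over dense curve
samples) maps through a Gaussian cross-section (σ = radius/2), anisotropic
PSF blur (σ 0.15 µm lateral, 0.45 µm axial — typical spinning-disc
confocal), peak normalisation, then Poisson photon noise and additive
Gaussian read noise over a constant background.  Defaults (background 0.05,
read σ 0.08, photon scale 120) give peak SNR ≈ 7, a well-exposed stack;
`noise_for_snr` splits the target noise variance evenly between shot and
read components.  The membrane channel renders each cell's boundary shell
(σ 0.3 µm) the same way.

What the phantoms do **not** emulate: tissue autofluorescence gradients,
depth-dependent PSF broadening and attenuation, uneven labelling between
cells, sample drift (stacks are static), and true fission/fusion dynamics.
Passing phantom tests therefore demonstrates correctness of the geometry,
graph and statistics machinery under a realistic noise/PSF model — not
robustness to every real-tissue artefact; the registration and
noise-injection stages address the two most important real-data effects
separately.

## Cell segmentation, morphometry, cluster analysis

The interactive membrane-tracing workflow that inspired this stage (region
growing, live-wire, manual edits) is replaced by a reproducible, scriptable
equivalent: edge-preserving sigma filtering (mean of neighbours within
2 × global σ of the centre) plus a median pass, then marker-controlled
watershed with the membrane as ridge, one seed per cell (snapped off
ridges, with a warning), and the image border as background marker.  Labels
are smoothed by a per-label, merge-free morphological closing with a
spacing-aware ellipsoid (default radius 3 voxels in the cluster pipeline —
wide enough to keep the membrane-adjacent blur shell of peripheral
mitochondria inside the mask); contested voxels go to the nearest label.

Morphometry: volume is voxel count × voxel volume; the 3D Feret diameter is
the maximum pairwise distance between voxel centres under anisotropic
spacing, computed over boundary voxels via their convex hull (exact — the
maximum is attained at hull vertices; an O(n²) scan is the test oracle).

Per-cell extraction copies in-mask voxels verbatim and replaces the outside
with Gaussian noise fitted to the stack's own background (1st–20th
intensity percentiles) unless given explicitly.  A constant (σ = 0) fill is
allowed but warned against.  Honest finding from the validation
experiments: this package's segmentation is *insensitive* to the zero-fill
cliff (measured mask-F1 change ~0.003) because it thresholds a
contrast-normalised response locally with a floor and a minimum component
size, whereas the degradation that originally motivated noise injection
arises when a global threshold is estimated over a mostly-zero masked
image.  The injection step is retained for interoperability and because it
is the statistically faithful way to simulate a single-cell acquisition.
Known limitation (seen on phantoms and inherent to mask-based assignment):
when a neighbouring cell's tubule hugs the shared boundary, its blur
contamination inside the mask can be segmented as real signal.

## Cohort statistics

Two groups: unpaired two-sided t-test, Student's (equal variance) by
default with Welch behind a flag — "unpaired t-test" without qualification
means the pooled-variance form.  Three groups: one-way ANOVA.
Metric-vs-Feret relations: ordinary least squares with the slope p-value
from the standard t statistic (for simple OLS this equals the model
F-test).  Box summaries: median, linearly interpolated quartiles (25–75%),
full-range whiskers — quartile conventions differ across ecosystems, so the
interpolation rule is fixed and tested.  No multiple-testing correction is
applied by default (per-panel p-values); Holm adjustment is available.

## Validation experiment design

The validation suite (`tests/test_acceptance.py`, recomputed by
`scripts/acceptance.py`) runs at deliberately modest problem sizes — single
cells on 20×128×128 grids, two-cell clusters on 20×128×200, 40–50 seeded
replicates for the signature experiments — chosen so the full suite
completes on one CPU while keeping tube radii ≥ 2 in-plane voxels and the
stated SNR conditions.  Two designs deserve explanation:

* **Expansion baseline.** The expansion signature requires PHI to increase,
  which is unobservable from the PHI = 1 ceiling of a fully fused network.
  Control cells in reality carry a dominant network plus a few discrete
  units, so the baseline is a filamentous phantom with 3 seeded cuts
  (PHI < 1 by construction).
* **Cluster fidelity.** The two-cell experiment uses a high-SNR phantom and
  a paired-noise comparator (the single-cell reference image carries the
  identical noise residual as the cluster image), so that the comparison
  isolates the masking/extraction effect rather than independent noise
  realizations or photon-noise run-to-run variation.

## Known limitations

* The connectivity score is a surrogate; absolute score values (and the 3.0
  threshold) are not comparable to other tools' scores.
* Fragment gaps below the axial resolution (~2 µm at this PSF) are not
  resolvable in rendered images; graph-level fragmentation experiments are
  therefore the authoritative test of the intervention machinery, and
  image-level fragmentation phantoms must use sparser, shorter tubules.
* Registration is translation-only and in-plane; rotational drift is out of
  scope.
* The watershed cell segmentation assumes a closed, reasonably bright
  membrane shell; gaps in membrane labelling will leak basins.
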