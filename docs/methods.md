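# Methods

This note documents the models and procedures `morphenv` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Skeleton handling

An SWC skeleton is a rooted tree of 3D nodes with radii, in µm in atlas
space.  On read, multi-node somas are collapsed to a single root at the
first soma node's position (children re-parented), and the tree is
re-indexed depth-first with the soma as root.  Three transforms matter
downstream:

- **Resampling** (default spacing 2 µm): branch endpoints — soma,
  bifurcations, tips — are preserved exactly; interior nodes are placed at
  arc-length steps along each branch polyline with radii linearly
  interpolated.  The final inter-node gap on a branch may be shorter than
  the spacing; endpoints are never moved.  Consequently total length is
  preserved to within one spacing per branch, and resampling is idempotent
  on node count.
- **Spherical cropping** (default radius 100 µm): only the soma-connected
  component inside the sphere is kept.  A subtree whose path to the soma
  exits the sphere is removed even where it re-enters.  Boundary-crossing
  segments are truncated with an interpolated node placed exactly on the
  sphere, which keeps length estimates unbiased near the boundary; the
  alternative reading (discarding whole neurons that lose any in-sphere
  material) is available behind `discard_if_disconnected`.
- **Bidirectional structure distance**: for each node of skeleton A the
  distance to the nearest node of B, and vice versa; pooled and summarised
  by mean or median.  Only meaningful between skeletons resampled to a
  comparable node density.

## The 24-feature vector

Feature definitions are fixed in `morphometry.extract_features` (topology
counts; bounding-box extents; total length; conical-frustum volume; maximum
Euclidean and path distance from the soma; maximum branch order; per-branch
contraction, fragmentation and parent-daughter radius ratios; local and
remote bifurcation angles; box-counting dimension; first principal axis and
the three explained-variance ratios of the node cloud).  Numerical choices:

- **Box-counting dimension**: occupied-box counts at grid scales
  {2, 4, 8, 16, 32, 64} µm; the reported value is the least-squares slope
  of log N(s) against log(1/s).  The scale grid matches the 2-µm node
  spacing at the bottom and typical arbor extents at the top.
- **PCA sign convention**: the first axis is flipped so its
  largest-magnitude component is positive, making PC11–13 deterministic.
- **Angles over zero bifurcations** are reported as 0 with a warning
  rather than NaN, so feature tables stay dense.
- **z-scoring** uses the population (n) denominator; standardization
  parameters are fitted once on the analysis set and reused downstream
  (microenvironments, parcellation) via the returned `(mean, std)`.
- **QC filtering** accepts a neuron when Total Length and #Bifurcations
  both lie within the reference min/max of its brain area widened by 5% of
  the range (range-relative margin; the alternative value-relative reading
  is not implemented).
- **mRMR** discretizes features into 10 equal-frequency bins and greedily
  maximizes label mutual information minus mean redundancy (difference
  form).  The supervision target defaults to the soma's region id and is a
  parameter.  Ties break by fixed column order, making selection
  deterministic.

## Microenvironments

A microenvironment blends a target neuron with at most five neighbors:
candidates are all neurons within radius R; when more than five exist, the
five closest in standardized feature space are kept (ties by table order).
Weights are a softmax of negative distance over the member set, target
included at distance 0, with decay D = R.  The default R = 166.36 µm is
the value of the density-derived rule — the 75th percentile over neurons
of the 6th-nearest-neighbor distance — on the mouse-brain dataset the
representation was developed for; `compute_radius` re-derives it for any
soma table, and pipeline-level code here uses the re-derived value because
synthetic populations have their own density.  Neighbor search is pooled
across brains and regions (no region gating).  Aggregated features are
convex combinations, hence bounded by the member min/max coordinate-wise.

## Spatial statistics

- **Moran's I** uses row-normalized, symmetrized binary kNN weights
  (k = 10); no weighting scheme is canonical for scattered somas, and kNN
  keeps the statistic density-independent.  Per-region scores average the
  per-feature I over non-constant features.  Expectation under random
  labeling is −1/(n−1).
- **Feature variance** of a point set is the mean standard deviation of
  the top three principal-component scores.
- **Confusion score** is mean intra-group pairwise distance divided by
  mean inter-group pairwise distance (≈1 for indistinguishable groups,
  → 0 for well-separated ones).  The wording "ratio of off-diagonal to
  diagonal" would invert this orientation for distance matrices; the
  implementation follows the semantics in which lower = better separated,
  matching how the score is read everywhere it is used.
- **Gini** of subregion volumes uses the standard sorted-cumulative-share
  form; **variance improvement** is the percent change from parent feature
  variance to the mean over children (negative = more homogeneous).

## Subparcellation

Eligible regions have ≥ 40 neurons and ≥ 225 µm extent on every axis.  The
chain per candidate configuration is:

1. **Graph**: nodes are microenvironments; edge (i, j) exists when i is
   among j's top-N spatial neighbors or vice versa (union rule); edge
   weight exp(−‖F_i − F_j‖) on standardized microenvironment features.
2. **Leiden** on the modularity objective.  The resolution default is 0.5:
   at resolution 1.0 the objective consistently shatters spatially coherent
   zones into 4–8 blocks on seeded synthetic regions, while 0.5 recovers
   the planted count; the parameter is exposed in `ParcellationConfig`.
3. **Majority vote**: one synchronous pass; each neuron takes the modal
   label of its five spatially nearest peers (self excluded), ties keeping
   the current label.  Voting runs in the same (possibly shape-scaled)
   coordinates as the graph.
4. **Shape scaling** (searched on/off): PCA of the region's edge voxels
   (mask voxels with a non-mask 6-neighbor); A = square roots of the
   eigenvalues; per-axis factor = ΣA / A_i, so Σ(1/factor) = 1 and the
   thinnest axis is stretched the most.  Degenerate (planar) axes are
   floored at one voxel length.  Scaling is applied to positions in the
   PCA frame before the kNN queries; silhouette is always computed in
   unscaled feature space.
5. **Adaptive parameterization**: every candidate N ∈ {50, 100, 250, 500}
   (truncated below the region's neuron count) × scaling on/off is run;
   the configuration with the best mean silhouette of the labels in
   standardized microenvironment feature space wins, ties preferring
   smaller N and no scaling.  A configuration is only valid if each of its
   communities holds ≥ 40 neurons (the regional support floor):
   modularity occasionally emits splinter communities of a few outlier
   neurons, and a [5, n−5] split can carry a spuriously high silhouette.
6. **Silhouette floor**: a region is left unparcellated when the best
   silhouette is below 0.10.  The floor was calibrated once against the
   generator's null model (zero planted effect): over 30 seeded null runs
   the best valid-configuration silhouette never exceeded 0.03 (a third of
   runs produced no valid configuration at all), while planted-zone runs
   at strong effect score ≈ 0.35–0.50.  0.10 sits well clear of both.
7. **Voxelization and cleanup**: mask voxels take the label of the
   spatially nearest soma; two rounds of median filtering with a
   5-voxel-radius (125 µm) ball kernel restricted to the mask (background
   never enters a median and is never modified; the lower median resolves
   even-count ties to the smallest label id); 26-connected components
   below 512 voxels are dissolved smallest-first into the adjacent
   component sharing the most voxel faces.  Components of one community
   label split across islands of a disconnected parent mask keep a single
   subregion id; a region under 512 voxels in total is returned whole.

Atlas assembly rewrites each subdivided region's voxels with fresh ids,
appends `<acronym>-R<k>` children under the parent in the ontology, and
never moves a voxel across a parent-region boundary (refinement property,
asserted in tests).

## Projections

Axons are the type-2 nodes of a 2-µm-resampled morphology, so each node
carries ≈ 2 µm of cable; per-(region, side) length is node count × spacing,
with ipsi/contra assigned by comparing each node's z against the atlas
mid-plane relative to the soma side, and out-of-atlas nodes kept in an
"unassigned" bucket so total length is conserved.  Intensity is
ln(length + 1) with length in mm; the clustering convention zeroes regions
receiving under 1 mm.  Specificity reports consider only groups of ≥ 5
neurons: pooled axonal spatial standard deviation per parent region versus
the mean over its subregions, Pearson correlations between subregion-mean
projection vectors, and per-subregion counts of targets above the 1-mm
threshold (reusing the clustering exclusion; no separate count threshold
is defined anywhere).

## Feature maps and slice stretching

RGB channels are built per feature by z-scoring then rank-based histogram
equalization onto [0, 255] (average ranks for ties keep the map monotone;
constant channels map to mid-gray 128).  Right-hemisphere points are
mirrored across the mid-z plane; mirroring is an involution and maps a
region to its contralateral homologue in a symmetric atlas.  Slice
rendering projects points within 0.5 mm of the slice plane by per-pixel
channel-wise maximum at 25 µm/pixel.

Slice stretching closes the 2D region mask with a 5-pixel square,
skeletonizes it, prunes terminal branches shortest-first (length in
along-skeleton pixels, ties by endpoint coordinates) until a simple path
remains, and extends both path ends along their terminal tangents to the
mask boundary.  The leftmost terminus (minimal image column) is the
origin; each point anchors to its nearest path vertex; x = along-path
distance from the origin, |y| = distance to the anchor, with the side of
the path nearer the mask bounding-box center ("dorsal") negative.
Tangent-direction extension at curved ends is a choice; any extension
confined to the mask changes x only by an additive constant.

## Synthetic data: what it emulates, and what it does not

The generators produce labeled ellipsoidal "regions" in a 25-µm grid
(optionally left-right symmetric with twin labels for mirroring tests),
planted zone partitions (axial slabs along the region's principal axis,
depth-band laminae, or nearest-seed blobs, each zone ≥ 512 voxels), and
neurons grown by seeded stochastic branching: tips advance in 2-µm steps
with direction noise scaled by (1 − tortuosity), bifurcate with a set
probability at exponentially distributed branch-length boundaries, and
stop when a per-neuron total-length budget (10% coefficient of variation)
is spent.  Zone parameter sets differ along fixed, roughly orthogonal
directions in (total length, branch length, tortuosity, stem count,
branching probability) space, scaled by a single `effect_size`; 0 is the
null model with identical parameters everywhere.  Axons are polylines from
the soma to each zone target region followed by a bounded meander inside
it until the sampled in-region cable length is reached.

Default demo scale is a 100³-voxel grid, 3 regions, 3 zones and 300
neurons per region, seed 1024.  Pipeline-level tests use single-region
volumes of ~40–90 voxels per axis with 400–1000 neurons and define
"strong effect" as `effect_size = 2.5`, at which zone feature clusters are
separated by several within-zone standard deviations — sized so that each
zone spans several microenvironment radii and a full simulate → features →
microenvironments → parcellate run takes seconds on one CPU.

What the generator does **not** emulate: imaging noise and tracing errors,
real soma-density gradients and cortical curvature, apical/basal dendrite
asymmetry, cell-type mixtures within a zone, and long-range axon
morphology beyond target membership.  Passing the planted-zone tests
therefore shows the pipeline recovers spatially organized morphological
structure at realistic densities; it does not certify performance under
real tracing artefacts or subtler effect sizes.

## Known limitations

- Median smoothing uses per-label FFT convolutions; volumes are processed
  whole, so very large regions cost memory proportional to mask bounding
  box × number of labels.
- The confusion score excludes singleton groups rather than erroring,
  which slightly biases it when many groups are tiny.
- mRMR mutual information is binned, not a continuous estimator; with
  < ~50 samples per class selection can be unstable.
- `majority_vote` is a single synchronous pass by design; iterating to
  convergence would change results on noisy boundaries.
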