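# morphenv

Dendritic **microenvironments** for whole-brain single-neuron morphometry:
spatially weighted feature aggregation, spatial-coherence statistics, and
data-driven subparcellation of brain-atlas regions, with seeded synthetic
generators that exercise the whole pipeline end to end.

## The problem

Large-scale reconstructions of local dendritic arbors (the soma-connected
subtree within 100 µm of the cell body, registered to a 25-µm reference
atlas such as CCFv3) are individually noisy, but their *spatial context*
carries robust anatomical signal: nearby neurons tend to share morphology.
`morphenv` implements the microenvironment representation that exploits
this: each neuron's 24-dimensional morphological feature vector
f<sub>0</sub> is blended with up to five spatial neighbors,

&nbsp;&nbsp;&nbsp;&nbsp;**F** = Σ<sub>i=0..k</sub> w<sub>i</sub> · f<sub>i</sub>,&nbsp;&nbsp; k ≤ 5,&nbsp;&nbsp;
w<sub>i</sub> = exp(−d<sub>i</sub>/D) / Σ<sub>j</sub> exp(−d<sub>j</sub>/D),

where d<sub>i</sub> is the spatial distance to the target soma
(d<sub>0</sub> = 0, so the target carries the largest weight) and
D = R = 166.36 µm, the 75th percentile over neurons of the distance to the
sixth-nearest neuron.  Candidates are all neurons within R; if more than
five fall inside, the five nearest in standardized feature space win.

On top of this representation the package provides:

- **morphometry** — the fixed 24-feature vector (topology counts, extents,
  length/volume, branch-shape averages, box-counting dimension, principal
  axis), quality-control range filtering, z-scoring, and mRMR feature
  selection;
- **spatial statistics** — Moran's I with kNN weights, per-region feature
  variance (mean s.d. of the top three PCs), the intra/inter confusion
  score, Gini coefficients of subregion volumes, variance improvement;
- **parcellation** — subdividing an atlas region from microenvironment
  features: a "connected-neuron" kNN graph (union rule, edge weight
  exp(−feature distance)), Leiden community detection, 5-NN majority
  voting, silhouette-based adaptive parameterization (graph-neighbor count
  N and optional region-shape scaling), nearest-neighbor voxelization,
  two rounds of ball-kernel median smoothing (radius 5 voxels = 125 µm),
  and dissolution of components under 512 voxels (0.008 mm³);
- **projections** — axonal length per (region, ipsi/contra) from 2-µm
  resampled skeletons, intensity ln(length+1) with length in mm (regions
  under 1 mm excluded for clustering), and projection-specificity
  summaries;
- **maps** — mRMR-top-3 RGB feature maps (z-score → rank histogram
  equalization to [0, 255]), hemisphere mirroring, maximum-intensity slice
  projection, and the slice-stretching transform that unbends a curved
  region into path-distance coordinates;
- **synthetic data** — seeded generators for labeled atlas volumes, planted
  subregion "zones" with zone-specific dendritic geometry, procedurally
  grown SWC skeletons and zone-specific axonal targets, so every claim the
  package makes is testable against known ground truth.

Coordinates are µm in atlas space (x anterior→posterior, y superior→
inferior, z left→right); voxel index = floor(coord / 25).

## Worked example

```python
import numpy as np
from morphenv import synthetic, morphometry, microenv, parcellation

atlas = synthetic.make_atlas(n_regions=1, shape=(96, 96, 96), seed=13)
somas, skels, truth = synthetic.sample_population(
    atlas, n_per_region=800, G=3, effect_size=2.5, seed=1024, region_ids=[1])

feats, _ = morphometry.standardize(morphometry.extract_feature_table(skels.values()))
R = microenv.compute_radius(somas)
me = microenv.build_all(somas, feats, microenv.MicroenvConfig(radius=R))
me_std, _ = morphometry.standardize(me[feats.columns])

parc = parcellation.parcellate_region(
    1, atlas.region_mask(1), somas, me_std,
    parcellation.ParcellationConfig(random_seed=1024))
print(f"radius R = {R:.1f} um")
print(f"N = {parc.chosen_N}, scaling = {parc.chosen_scaling}, "
      f"silhouette = {parc.silhouette:.2f}, subregions = {len(parc.subregions)}")

from sklearn.metrics import adjusted_rand_score
mask = atlas.region_mask(1)
ari = adjusted_rand_score(truth.zone_voxels[1][mask], parc.voxel_labels[mask])
print(f"voxel ARI vs planted zones = {ari:.2f}")
```

Output:

```
radius R = 117.2 um
N = 100, scaling = False, silhouette = 0.47, subregions = 3
voxel ARI vs planted zones = 0.80
```

The region's three planted zones are recovered as three subregions; the
adaptive search settled on a 100-neighbor graph without shape scaling, and
the voxelized, smoothed parcellation agrees with the planted ground truth
at ARI 0.80.  A region simulated with zero planted effect comes back
unparcellated (`None`): its best silhouette falls below the documented
floor (see `docs/methods.md`).

A command-line layer wraps the same steps:

```bash
morphenv simulate --out demo/ --n-regions 3 --n-per-region 300 --seed 1024
morphenv stats --somas-csv demo/somas.csv --features-csv features.csv --out stats.json
morphenv parcellate --atlas demo/atlas.nii.gz --ontology demo/ontology.json \
    --somas demo/somas.csv --features features.csv --seed 1024 --out out/
```

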