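# tracemap

Computational pipeline for mesoscale tract-tracing studies of brain
connectivity, built around the analysis stages used to map the
input/output connectivity of amygdalar nuclei: quantifying tracer
injection sites in section images, delineating anatomical domains from
labeled tracer pixels, partitioning injection-by-target annotation
matrices into connectivity communities, and comparing the morphology of
reconstructed projection neurons.  Everything runs end to end on seeded
synthetic data with known ground truth (`tracemap.synth`), so each stage
is testable without an imaging archive.

Intended users are neuroanatomists and pipeline developers who need the
computational half of a tracing study — segmentation-adjacent image
processing, boundary classification, graph community analysis and SWC
morphometry — as importable, tested functions.

## What it computes

**Injection-site extraction** (`tracemap.imaging`, `tracemap.mser`).
Injection sites are surrounded by irregular, very bright background that
confounds annotation.  A section image f(x, y) is decomposed with a
5-level 2D DWT; detail levels 1–3 are removed, large diagonal
coefficients at levels 4–5 amplified, small horizontal/vertical ones
dampened, and the low-pass block dampened and Gaussian-smoothed before
inverse transform.  Contrast is then enhanced with the locally adaptive
map built from T(f, p) = sin²((π/2)·fᵖ) and its first-order form
T(f, c) = (π²/4)·f^c with c = c₁(f_g + ε)/((1 − f_g) + ε) + c₂, where
f_g = f ∗ g is a Gaussian-smoothed copy:

    E = (f / f_g) · [ T(f, c) + (∂T/∂c)(f − f_g) ].

The injection blob is the maximally stable extremal region (MSER) through
the intensity maximum of E, annotated against a co-registered atlas
raster.

**Domain boundary demarcation** (`tracemap.boundary`).  Tracer-signal
pixel coordinates Dˡ with section-inherited labels y ∈ {medial, lateral,
caudal} train, per atlas level l, 64 soft-margin RBF SVMs on an 8×8
power-of-two grid of (C, γ).  Each member i is weighted by its mean
accuracy aᵢ over 10 repeats of stratified 3-fold cross-validation, and a
query x is labeled by the accuracy-weighted vote

    Eˡ(x) = argmax_y Σᵢ aᵢ · 1[yᵢ(x) = y].

Dense classification of the nucleus mask yields the domain boundary map.

**Connectivity communities** (`tracemap.connectivity`).  Annotation
matrices (pixel density for anterograde tracers, cell counts for
retrograde) are thresholded (0.0045 / 8), row-normalized to the maximum
injection total, cast as a weighted bipartite graph and partitioned by
Louvain modularity maximization at γ = 1.0; 100 stochastic runs are
summarized by consensus reclustering of the co-assignment matrix.
Downstream: community-sorted matrix orderings, injection-colored pixel
maps, stacked-bar level proportions, tertile strength classes, and
cosine-linkage hierarchical clustering of L1-normalized projection
vectors.

**Neuron morphometry** (`tracemap.morpho`, `tracemap.persistence`,
`tracemap.stats`).  SWC reconstructions are trimmed to a 300-unit
Euclidean radius around the soma, LOESS-smoothed (locally quadratic,
five neighbors each side, endpoints and bifurcations untouched), and
summarized by classic and surface-area Sholl profiles plus L-Measure-style
soma/dendrite features.  Cohorts are compared with PCA, two-sided
Wilcoxon rank-sum tests under Benjamini–Hochberg FDR (with
Hodges–Lehmann shift estimates), and by Wasserstein distances between
path-distance persistence diagrams of the dendritic trees.

## Worked example

Train the ensemble on one synthetic atlas level and score its dense
classification against the generator's ground truth:

```python
import numpy as np
from tracemap import boundary, synth

spec = synth.DomainCloudSpec.default("ARA1", seed=1, n_points_per_domain=500)
points, truth = synth.gen_domain_points(spec)          # 1500 labeled pixels
ensemble = boundary.train_ensemble(points, seed=101)   # 64 RBF SVMs
ground_truth = truth.label_raster((120, 160))
auto = boundary.demarcate(ensemble, ground_truth.mask)
report = boundary.agreement(auto, ground_truth)
print(len(ensemble.members), round(report.fraction, 4))
```

prints

```
64 0.9798
```

— 64 trained members whose weighted vote labels 97.98% of the 9435
nucleus-mask pixels identically to the generating mixture's
likelihood-ratio boundaries.  The numbered drivers under `analysis/` run
the other stages the same way: `01_injection_sites.py` recovers 20 seeded
injection blobs at mean Dice 0.932 (max centroid error 1.45 px),
`03_connectivity.py` recovers a planted 3-community matrix exactly
(adjusted Rand index 1.0 after consensus over 100 Louvain runs), and
`04_morphometry.py` surfaces planted bifurcation-rate and tortuosity
differences as FDR-significant contrasts.  Each driver writes its tables
under `results/`.

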