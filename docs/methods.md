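# Methods

## Model and assumptions

The tissue is modelled as a space-filling packing of convex cells whose
shapes are approximated by the Voronoi regions of their nuclei centroids.
Under that abstraction, two cells are in membrane contact iff their Voronoi
regions share a facet, which is exactly the dual condition for their
centroids to be joined by a Delaunay edge. The Delaunay triangulation is
therefore a *superset* of the true contact graph: it always contains the
nearest-neighbor graph and is stable under small displacements of the
centroids, but it also adds spurious links — long edges along the convex
hull and edges that "tunnel past" an intervening cell. The method's job is
to remove those.

Each candidate edge (i, j) is summarized by two features:

* `r_ij` — centroid distance, in the input's length units. Captures the
  pairwise plausibility of contact.
* `theta_ij` — the maximum over shared triangulation neighbors k of the
  angle i–k–j, in degrees. Captures non-pairwise interference: if k lies
  near the segment between i and j the angle approaches 180° no matter how
  close i and j are; if all shared neighbors are far away it is small. The
  shared-neighbor set is restricted to the opposite vertices of the
  triangles (3D: tetrahedron faces) containing the edge — that is what
  "shared neighbor" means in a triangulated graph, and it keeps the cost
  linear in the number of edges.

An edge is kept iff `r_ij <= r*` and `theta_ij <= theta*` (both closed
inequalities). The thresholds maximize the communicability efficiency

    E(r, theta) = F(r, theta) - L(r, theta)

where `F` is the joint empirical CDF of the observed features (fraction of
candidate edges retained) and `L` is the retention a featureless tissue
would have: the mean of the two min–max-normalized threshold coordinates
over their observed ranges. `E = 0` exactly at the observed joint maxima
(`F = 1`, `L = 1`), so the maximizer is always at non-negative efficiency;
real tissues concentrate their feature mass well below the extremes, giving
an interior maximum.

Because `F` only depends on the data through comparisons, and the whole
pipeline is built from distances and angles, the output graph is invariant
under translation, rotation, reflection and uniform scaling (`r*` scales
with the data; `theta*` and the kept edge set do not change), and the
procedure has no free parameters.

## Numerical and design choices

* **Argmax search.** `F` is piecewise constant with jumps only at observed
  feature values, while `L` strictly increases between them; hence the
  continuous-domain maximum of `E` lies on the Cartesian grid of observed
  unique `r` times observed unique `theta` values, which is searched
  exhaustively. Ties are broken toward smaller `r`, then smaller `theta`
  (the stricter graph), making the output deterministic.
* **Loss bounds.** The normalization bounds in `L` are the *observed*
  feature extrema, not fixed ranges such as [0°, 180°]. This makes
  `L = 1` and `F = 1` coincide exactly at the observed maxima, which is the
  limiting behaviour the statistic is built on. With fixed bounds the
  surface would shift slightly; the observed-extrema convention is the one
  the limiting argument requires and is applied uniformly.
* **Degenerate ranges.** If all `r` (or all `theta`) coincide, that axis
  cannot filter anything; its loss term is defined as 0, so `E = F = 1`
  at the single candidate and all edges are kept.
* **Distance-only baseline.** For ablation, `E(r) = F(r) - L(r)` with
  `L(r) = (r - r_min)/(r_max - r_min)` is maximized over observed unique
  distances; the angle is left at its observed maximum. Only these two loss
  functions are provided; `L` is in general only required to be increasing.
* **Degenerate geometry.** Exactly cocircular/cospherical configurations
  make the Delaunay triangulation non-unique; the triangulation produced by
  Qhull (via `scipy.spatial.Delaunay`, with its default handling of merged
  facets) is accepted as-is. Collinear/coplanar inputs and inputs with
  fewer than dim+1 points raise explicit errors. Centroids closer than
  1e-9 times the bounding-box diagonal are rejected rather than merged,
  because duplicate nuclei indicate an upstream segmentation fault.
* **Angles** are computed as `arccos` of the clipped normalized dot
  product and reported in degrees throughout.

## Synthetic tissues and what they do (not) show

`generate_tissue` places `n` sites on a hexagonal (2D), square/cubic
(2D/3D) or uniform-random layout inside a box, displaces lattice sites
uniformly within a disc/ball of radius `jitter * spacing` (jitter < 0.5
keeps displacements bounded and lattice adjacency meaningful), and derives
the exact ground truth as the adjacency of the Voronoi tessellation clipped
to the box: two cells are true neighbors iff their clipped regions share a
facet of positive measure. The clipped tessellation is computed by
reflecting all sites across every box face before tessellating, which makes
each original region exactly the box-clipped one; facets smaller than
1e-6 of the relevant power of the spacing are discarded, so zero-measure
point contacts (e.g. the diagonals of a perfect square lattice) are not
neighbors. Clipping, rather than periodic wrapping, deliberately keeps
boundary cells: hull edges are exactly where the filter has work to do.

Default study conditions used by the tests and the acceptance script, with
sizes chosen to keep full runs in seconds while leaving each tissue large
enough to have an interior: regular 2D = hexagonal, n = 100, jitter 0.1,
20 seeds; regular 3D = cubic, n = 125 (5x5x5), jitter 0.1, 20 seeds;
irregular = uniform-random, n = 30, 20 seeds for the ablation (small,
irregular tissues are where the angle term matters most).

The generator emulates centroid geometry only. It does not model irregular
(non-convex) cell shapes, anisotropic tissues, density gradients, nuclei
displaced from cell centers, or segmentation errors; passing the recovery
tests shows the inference machinery is correct under the Voronoi
abstraction, not that real tissues meet that abstraction. Real-data
performance depends additionally on centroid-extraction quality.

`render_nuclei_image` draws one unit-amplitude Gaussian blob
(sigma = radius/2) per centroid plus additive Gaussian noise, to exercise
the image front-end end-to-end; it warns when centroids come closer than
2x the nucleus radius (overlapping blobs).

## Image front-end

`extract_centroids` applies Otsu's global threshold, a morphological
opening with a 3^d structuring element, connected-component labelling
(8-connectivity in 2D, 26-connectivity in 3D), a minimum component size,
and intensity-weighted centers of mass scaled by per-axis voxel spacing.
The opening is required, not cosmetic: on a noise-only image roughly half
the voxels exceed the Otsu threshold and percolate into one giant
component, which no size filter can reject; opening suppresses speckle
while preserving blob-shaped nuclei that span at least ~3 voxels per axis.
The front-end is a convenience for well-separated nuclear markers, not a
general segmentation tool; for crowded or dim images, supply centroids from
a dedicated segmentation pipeline as a CSV.

## Evaluation

Confusion counts partition all C(n, 2) unordered cell pairs. The headline
metrics (TPR, PPV, JI) avoid true negatives, which dominate in sparse
spatial graphs and would inflate TN-dependent scores; F1 and MCC are
computed for completeness. Metrics with zero denominators are reported as
NaN with a warning rather than silently coerced to 0, so averages over many
runs are not biased. The identity `1/JI = 1/TPR + 1/PPV - 1` (TP > 0) is
used as an internal consistency check, including on the published
per-dataset benchmark triples bundled in
`nucgraph.evaluation.PUBLISHED_BENCHMARKS`; since those are printed to
three decimals, the identity is checked to one unit in the last digit.

## Known limitations

* The Voronoi/Delaunay abstraction assumes roughly convex, space-filling
  cells; dendritic or otherwise highly non-convex cells are outside its
  reach.
* The angle statistic is not invariant under anisotropic scaling, so
  anisotropic voxel sizes must be corrected before inference.
* One global threshold pair is selected per tissue; strong spatial
  gradients in cell size within a single image can defeat a global cutoff.
* The method outputs a single graph, not per-edge confidence scores.
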