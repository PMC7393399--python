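# Methods

## The lesion-correction model

Cortical volumetrics from surface reconstructions rest on two meshes — the
pial (outer) and white (inner) surface — with 1:1 vertex pairing; the
distance between paired vertices is the cortical thickness. A region's
volume is modelled as

    V [ml] = A [mm²] · t̄ [mm] / 1000,

where `A` is the region's surface area and `t̄` its mean thickness. At the
site of a chronic lesion the reconstruction is unreliable, so neither `A`
nor `t̄` is meaningful there. Rather than editing the surfaces, the method
has a rater outline the inaccurate patch on the surface, fills the outline,
and *excludes* the labelled vertices from the regional sums. The corrected
("post") statistics are therefore the same sums taken over the region minus
the lesion overlay; no assumption is made about the anatomy under the
lesion beyond treating it as non-contributing.

Surface area is accumulated from per-vertex areas using the uniform
one-third rule: each triangle contributes a third of its area to each of
its corners. This conserves total area exactly (Σ vertex areas = Σ triangle
areas), which is the property the regional sums rely on; Voronoi/mixed
vertex areas would change only the within-region split, not region totals,
and are not used. Mean thickness is area-weighted by default (each vertex
weighted by its vertex area), consistent with the area-based volume
formula; an unweighted mean is available via `area_weighted=False`.

### Lesion labeling semantics

`close_path` joins consecutive anchor vertices (and last back to first) by
shortest paths on the mesh edge graph — graph geodesics, not exact
polyhedral geodesics, matching how interactive outlining follows the mesh.
Dijkstra tie-breaks deterministically (lowest predecessor index), so
outlines are reproducible. `flood_fill` then takes everything reachable
from the seed without crossing the outline, plus the outline itself.

Two deliberate choices:

* **Boundary vertices belong to the lesion label.** The drawn outline
  passes through inaccurate surface, so it is excluded from statistics too.
  Subtract the path vertices if the open interior is wanted.
* **A fill that claims more than `max_fill_fraction` (default 0.5) of the
  hemisphere's vertices is rejected** as "fill escaped outline". An
  unclosed outline otherwise silently floods the hemisphere; interactive
  use catches this visually, a batch tool must catch it programmatically.
  The threshold is configurable; 0.5 is safely above any plausible lesion
  and below a whole-hemisphere flood.

Hemisphere identity is a property of the mesh file (`lh.`/`rh.` prefix),
never inferred geometrically; combining labels across hemispheres is an
error, mirroring the protocol's one-hemisphere-per-label rule.

### Overlap metrics and sign conventions

Per network: `% surface area affected = 100 · area(lesion ∩ network) /
area(network)`; a network is "lesioned" if at least one lesion vertex falls
in it (no minimum-area threshold); a lesion overlapping k networks counts
once in each of the k. Percent volume change is the *signed* quantity
`100 · (post − pre) / denominator`, with the denominator selectable as the
pre- or post-correction volume (default `post`). Both conventions are
exposed because field usage is inconsistent: with real reconstructions the
post-correction volume can exceed the pre-correction one (excluding a
thin, inaccurate patch raises the mean thickness more than it cuts area),
while with uniform thickness the change is exactly the negative of the
area fraction removed — a relation the tests assert. Unassigned vertices
(region id 0) are excluded from every denominator.

The group frequency map counts, per template vertex, the subjects whose
overlay contains it. It assumes all overlays are indexed on one template
mesh; cross-subject surface registration happens upstream.

## Quality-control statistics

* **SNR** = mean / sample SD (ddof = 1) of intensities within the WM
  segmentation mask.
* **CNR** = mean of the WM–GM and GM–CSF contrasts, with
  `contrast(a,b) = |μa − μb| / sqrt((σa² + σb²)/2)`. CNR is invariant to
  global intensity offset and positive scaling; SNR only to scaling.
* **ABC/2** = `A·B·C/2000` ml. From a binary mask: the axial slice with the
  largest cross-section is found (ties → lowest slice index); `A` is the
  maximum pairwise distance between voxel centers in that slice (convex
  hull first when the slice is large), `B` the extent perpendicular to
  `A`'s direction, `C` the number of lesion-bearing slices times the slice
  thickness. Center-to-center distances slightly under-measure a digitized
  ellipse; the error is below one voxel per axis.
* **ICC**: two-way single-measurement forms from the ANOVA mean squares.
  Default is absolute agreement ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE +
  k(MSC − MSE)/n); `form="consistency"` gives ICC(3,1) = (MSR − MSE)/(MSR +
  (k−1)MSE). CIs are the standard F-based intervals (exact for consistency,
  Satterthwaite approximation for agreement). Degenerate inputs (identical
  rater columns) return estimate and CI of exactly 1. The estimate is
  clipped to [−1, 1] and the CI to contain the estimate.

## Synthetic data: what it emulates, what it does not

The generator produces spheres, not folded cortices: all statistics here
are geometry-agnostic sums over vertices, and spheres give analytic area
limits (4πr², verified to <1%). A radial sinusoidal "wrinkle" (default
amplitude 0.03) de-trivializes vertex areas so tests do not pass by
symmetry. Defaults per hemisphere: icosphere subdivision 4 (2562 vertices —
thousands of vertices, as in real meshes, while keeping brute-force oracle
comparisons fast), radius 50 mm (≈314 cm², the order of one hemisphere's
area), base thickness 2.5 mm (typical cortical mean) plus three
low-frequency sinusoidal components of 0.15 mm amplitude, floored at
0.1 mm.

The 7-network parcellation is a seeded nearest-centroid partition of the
sphere — seven contiguous patches with the canonical network names, id 0
reserved for "unknown". Lesions grow breadth-first from a random in-network
seed, ring by ring (within a ring by ascending vertex index), accumulating
vertex area until the target fraction of the network's area is first
reached; the achieved fraction therefore overshoots the target by at most
one vertex area, and this quantization bound is recorded in the ground
truth. Default lesion load is one 10% limbic lesion plus one 5%
default-mode lesion on the left hemisphere, with lesion thickness
multiplied by 0.2 (encephalomalacic thinning). Ground-truth pre/post
statistics are computed by an independent plain-loop implementation, not by
the vectorized engine under test.

Voxel phantoms are concentric WM/GM/CSF shells (radii at 25/35/45% of the
smallest grid extent, default 64³ voxels of 1 mm) with Gaussian class
intensities, default μ = (150, 100, 50), σ = 10 — i.e. closed-form SNR 15
and CNR 5, the scale of good-quality T1 scans. Rater matrices default to 20
subjects × 3 raters (the size of a typical reliability sub-study), true
volumes N(15, 3²) ml and unit rater SD, giving a closed-form agreement ICC
of 9/(9+1) = 0.9.

What passing tests on these fixtures shows: the bookkeeping — areas,
exclusions, unions, counts, format round-trips — is exact, and the
statistical estimators recover known parameters at their theoretical rates.
What they cannot show: behaviour on real folded, topologically imperfect
reconstructions, rater variability in *placing* outlines, or partial-volume
effects in real segmentations.

## Numerical choices

* All on-disk formats are big-endian regardless of host, with float32
  coordinate/scalar storage (round-trip tolerances in tests are set by
  float32, indices round-trip exactly). Writers emit a fixed creation
  stamp, so rewriting a file is byte-identical — the end-to-end pipeline is
  bitwise reproducible given a seed.
* Degenerate faces get area 0 and a logged warning, not an error: real
  meshes contain them and the sums remain well defined.
* Regions emptied by exclusion are reported with 0 vertices, 0 area/volume
  and NaN thickness plus an explicit `thickness_defined=False` flag, rather
  than dropped, so pre/post tables stay row-aligned.
* Shortest-path and fill frontiers are ordered deterministically; every
  random draw flows from one integer seed through named per-component
  generators (`numpy.random.default_rng`), stable across platforms.
* `pct_volume_change` refuses a non-positive denominator volume rather
  than returning infinities.

## Known limitations

* Graph geodesics overestimate true geodesic distance by the mesh metric
  factor; outlines hug mesh edges exactly as interactive tracing does, but
  they are not geometry-optimal curves.
* The ABC/2 mask measurement assumes the axial axis is the third array
  axis and measures diameters between voxel centers.
* Self-intersecting outlines (two path segments sharing a vertex) are
  rejected rather than resolved; re-place the anchors.
* The group frequency map requires a shared template; no registration is
  performed.
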