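# Methods

This note records the model, the parameter choices, the numerical details
and the known limitations of `organmorph`, in the order the pipeline runs.

## Input model

A case is a binary 3D segmentation mask on a regular, possibly anisotropic
grid: voxel $(i,j,k)$ has its centre at `origin + (i·dx, j·dy, k·dz)` in mm,
with the third axis the slice (acquisition) axis. NIfTI-1 is the interchange
format; only orthogonal (axis-aligned, possibly flipped or permuted)
voxel-to-world transforms are accepted, and flips are normalised to a
right-handed positively-spaced grid on load. Oblique acquisitions would need
resampling that this package deliberately does not do — rejecting them
loudly is safer than silently shearing a mask. Values are binarised at 0.5
on load so probabilistic segmentations degrade gracefully.

## Reconstruction chain

1. **Isotropic resampling** (trilinear) to the finest input spacing by
   default. Abdominal MRI is typically much coarser between slices
   (e.g. 2.0 mm) than in-plane (e.g. 1.3128 mm); marching cubes on the raw
   grid would alias the slice direction.
2. **Gaussian smoothing** of the float-cast mask, $\sigma$ = 1.0 mm by
   default, kernel truncated at $4\sigma$ and renormalised to unit sum. The
   separable sampled kernel is exactly the normalised sampled 3D Gaussian,
   so total mass is conserved for interior-supported masks (tested to 1e-6
   relative). Smoothing the binary mask (rather than a distance field) keeps
   the 0.5 level set close to the half-occupancy surface.
3. **Marching cubes** at isovalue 0.5 — the midpoint of a binary field —
   using the 256-configuration table with topological disambiguation
   (scikit-image's Lewiner implementation), which guarantees a closed,
   manifold surface when the level set does not touch the array boundary.
   The mask is padded by one voxel plus the kernel radius beforehand, so the
   surface is always closed. Winding is normalised so the enclosed signed
   volume is positive (outward normals); faces with repeated indices
   (possible at exactly-at-level corners) are dropped.
4. **Laplacian fairing**, 10 iterations by default. The update is
   simultaneous (Jacobi-style): all vertices move at once to the mean of
   their edge-adjacent neighbours, so the result does not depend on vertex
   order. Uniform weights shrink the mesh slightly (a regular tetrahedron
   contracts by exactly 1/3 per iteration — a unit test); at 10 iterations
   on organ-scale meshes the volume bias is well under the digitisation
   error, and staircase artefacts from the binary input are removed.

σ, the isovalue and the iteration count are exposed in the CLI config; the
defaults above were fixed a priori from the geometry of the problem (σ of
one voxel, binary midpoint, visually converged fairing) and are used by all
tests.

## Volume

Computed on the original mask, not the mesh: per slice along the
acquisition axis, foreground pixel count × (dx·dy), times the slice
thickness dz, summed and converted to cm³. The mesh-enclosed signed volume
is available separately (`TriMesh.signed_volume`) as a diagnostic; the two
agree within a few percent on phantoms and converge as spacing shrinks.

## Curvature

Vertex normals are inverse-distance-weighted averages of one-ring face
normals, the weight being 1/distance from the vertex to the face centroid
(guarded at 1e-12 mm). For each vertex $q$, the $k$ nearest vertices by
Euclidean distance are selected (k-d tree; ties broken by vertex index;
default $k=50$). For each neighbour the point-pair estimate

$$c_n = -\langle q_i - q, N_i - N\rangle / \|q_i - q\|^2$$

is taken; pairs whose tangent-plane projection is below 1e-12 mm (neighbour
along the normal) are skipped. The local curvature is the **mean magnitude**
of the $k$ estimates and the global curvature $C_g$ is the mean of local
values.

Two conventions deserve justification:

- **Magnitude, not signed mean.** The raw estimate is negative on convex
  regions with outward normals ($-1/R$ on a sphere) and positive in
  concavities; averaging signed values lets dents cancel bulges, whereas a
  roughness summary should accumulate both. Taking $|c_n|$ makes $C_g$ a
  non-negative roughness measure: $1/R$ for spheres, strictly larger for
  ragged surfaces of equal size. The signed kernel is still exposed
  (`directional_curvature`) and is exact on spheres to machine precision.
- **Mean over k directions, not principal-curvature fitting.** Fitting a
  second fundamental form would estimate principal curvatures but requires a
  least-squares solve per vertex with its own conditioning issues; the mean
  of directional magnitudes is deterministic, cheap, and inherits the
  $1/s$ scale covariance that the cohort analyses rely on (doubling the mesh
  halves every local value — a unit test).

Larger $k$ averages over a wider patch, trading locality for noise
robustness; on bumpy phantoms the variance of local curvature is
non-increasing in $k$ through {10, 25, 50, 100} (tested). The default
$k=50$ is kept from common practice for organ-scale meshes at mm
resolution.

For visualisation, local values are normalised by the per-mesh maximum and
binned into half-open bands of width 0.05 (the maximum falls in the top
band); the banded field is exported as a per-vertex `curvature` property in
ASCII PLY.

## Segmentation metrics

Dice and Jaccard on same-grid masks, with the both-empty convention
DSC = JI = 1 so degenerate regression cases are stable. The modified
Hausdorff distance is the Dubuisson–Jain form — the max of the two mean
directed nearest-neighbour distances — computed between boundary-voxel
centres (6-connectivity surface) in physical mm, as contour comparison
should be. Feature errors are MAE, RMSE and mean absolute percentage error,
MAPE reported as mean ± sample SD across cases; zero-truth cases are
excluded from MAPE.

## Cohort statistics

`summarise` returns box-plot numbers: mean, sample SD, median, quartiles
with linear interpolation, and Tukey 1.5·IQR whiskers clipped to the data
range. The Wilcoxon signed-rank test drops zero differences, mid-ranks
ties, and computes the two-sided p exactly for n ≤ 25 via subset-sum
convolution of the null distribution of the positive-rank sum (identical to
enumerating all $2^n$ sign assignments, but feasible at the cutoff); beyond
that it uses the normal approximation with continuity and tie corrections.
The two branches agree within 0.02 at the switch point (tested). Pearson
p-values use the t-transform with n−2 degrees of freedom; Spearman uses an
exact full-permutation p for n ≤ 10 and the t-transform on the rank
correlation above.

The volume-versus-curvature signed-rank pairing mixes cm³ with mm⁻¹, so
both features are z-standardised across the cohort before differencing —
without a common scale the test statistic would be dominated by whichever
feature has larger numbers. Truth-versus-predicted comparisons per feature
need no standardisation and are run as-is; an all-zero difference vector is
reported as degenerate rather than raised, since identical cohorts are a
legitimate regression case.

## Phantoms

Phantom membership is decided purely by voxel centres (no partial-volume
weighting), which makes voxel counting an exact combinatorial oracle for
the analytic volume. Spheres and ellipsoids carry closed-form truth
(ellipsoid surface-averaged mean curvature is integrated from the exact
parametric fundamental forms on a dense midpoint grid). Lobed blobs
modulate the radius by a seeded band-limited real spherical-harmonic field
(degree ≤ 6 by default, coefficients i.i.d. standard normal, normalised to
max |f| = 1 on a fixed Fibonacci sphere so the normalisation is
grid-invariant); the amplitude is therefore the maximum relative radial
excursion, capped at 0.3 to keep the surface star-shaped and well resolved.
Harmonics are evaluated with a vectorised associated-Legendre recurrence
(validated against scipy term by term). Blob truth volume comes from exact
solid-angle quadrature of $r^3/3$; blob truth curvature from central
differences of the parametric surface on a dense grid — a numerical oracle
recorded for qualitative comparisons, not a closed form.

Cohorts draw radius and amplitude uniformly from given ranges under one
master seed that spawns per-case seeds, so any case is reproducible alone.
The default study condition used by the acceptance checks is 85 cases with
radii 15–45 mm and amplitudes 0–0.2 at 1 mm isotropic spacing: the cohort
size mirrors a realistic single-organ MRI study, the radii span
pancreas-scale organs, and the amplitude range covers smooth through
visibly ragged surfaces.

What the phantoms do **not** emulate: MRI intensities, bias fields,
partial-volume fractions, segmentation errors, multi-lobed topology, or
non-star-shaped anatomy. Passing phantom tests therefore validates the
geometry-processing and statistics machinery, not robustness to real
segmentation noise.

## Voxelization (round-trip check)

`voxelize` rasterises a watertight mesh by ray parity: for every (x, y)
column of voxel centres, crossings of the surface along +z are accumulated
and a centre is inside iff an odd number of crossings lies above it. The
mesh is nudged by an irrational sub-voxel offset (~1e-6 of a voxel) so no
ray passes exactly through a vertex or edge, which would make parity
ambiguous. The reconstruction round trip voxelize(reconstruct(mask))
overlaps the original sphere masks with Dice ≥ 0.95 at 1 mm spacing.

## Problem sizes and determinism

Tests and the acceptance script run on spheres of 15–40 mm radius at 1 mm
spacing (masks up to ~10⁶ voxels, meshes of 10⁴–10⁵ faces), an 85-case blob
cohort, 2000-replicate null calibrations, and 100-pair randomised metric
checks. Every stochastic step takes an explicit seed; the pipeline itself
is fully deterministic, and identical inputs produce byte-identical CSV and
JSON outputs.

## Known limitations

- Uniform Laplacian fairing shrinks; volume should always be read from the
  mask (as the pipeline does), not the faired mesh.
- Curvature at mesh scale is resolution-dependent: below ~10 voxels per
  radius the $1/R$ recovery degrades; phantom generators enforce a 5×
  coarsest-spacing minimum.
- The k-nearest-neighbour patch is Euclidean, not geodesic; on thin
  structures neighbours may jump across the organ, inflating local
  curvature there.
- Only single-component, orthogonal-grid masks are supported; oblique
  affines and DICOM series are out of scope.
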