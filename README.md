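# organmorph

3D reconstruction and morphological feature extraction for abdominal organs
segmented in volumetric MRI. Given a binary segmentation mask with its voxel
spacing, `organmorph` builds a smoothed watertight triangular surface mesh
and measures the two features that drive organ-shape studies — **volume**
and **3D surface curvature** — together with the segmentation-evaluation
metrics (DSC, Jaccard, modified Hausdorff, MAE/RMSE/MAPE) and cohort-level
statistics (box-plot summaries, Wilcoxon signed-rank, volume–curvature
correlation) needed to compare automatic segmentations against ground truth
across a study population.

It is aimed at medical-image-analysis researchers who already have organ
masks (manual or automatic) and want reproducible morphometry on top of
them. Because clinical MRI cohorts are rarely shareable, the package ships a
phantom generator — spheres, ellipsoids, and seeded "lobed blob" organs with
ragged surfaces — whose volume and curvature are known in closed form, so
the whole pipeline is testable end to end without patient data.

## Method

**Reconstruction.** The binary mask is trilinearly resampled to an isotropic
grid, convolved with a sampled Gaussian kernel

$$G(x,y,z) \propto \exp\!\left(-\tfrac{x^2+y^2+z^2}{2\sigma^2}\right)$$

(truncated at $4\sigma$, renormalised to unit sum), and the isosurface at a
mid-range isovalue is extracted by marching cubes: each $2\times2\times2$
cell is polygonised from its 8-bit corner-occupancy index into the
256-configuration triangle table, with vertices placed by linear edge
interpolation. The mesh is then faired by iterative uniform Laplacian
smoothing: each vertex is simultaneously replaced by the mean of its
edge-adjacent neighbours,

$$\bar v_i = \frac{1}{N}\sum_{j=1}^{N} \bar v_j .$$

**Volume.** Computed on the original mask, per slice: foreground pixel area
times slice thickness, summed along the acquisition axis, reported in cm³.

**Curvature.** On the mesh, the vertex normal $N$ is the
inverse-centroid-distance weighted average of one-ring face normals. For a
vertex $q$ and each of its $k$ nearest neighbours $q_i$ (default $k = 50$),
the normal curvature along the tangent direction towards $q_i$ is

$$c_n(t_i) = -\frac{\langle q_i - q,\; N_i - N\rangle}{\langle q_i - q,\; q_i - q\rangle},$$

which is exact ($-1/R$) on a sphere. The local curvature $c_j$ at a vertex
is the mean magnitude of these $k$ estimates, and the global curvature

$$C_g = \frac{1}{N_g}\sum_{j=1}^{N_g} c_j$$

is the mesh-wide mean — a non-negative roughness summary in mm⁻¹ that
decreases as $1/R$ for smooth round organs and rises with surface
raggedness.

## Worked example

```python
import organmorph as om

mask, truth = om.make_sphere(20.0, spacing=(1, 1, 1))   # R = 20 mm phantom
report = om.measure_case(mask, case_id="sphere20")
print(f"volume    {report.volume_cm3:.3f} cm^3  (analytic {truth.analytic_volume:.3f})")
print(f"curvature {report.global_curvature:.4f} /mm  (analytic {truth.expected_global_curvature:.4f})")
```

prints

```
volume    33.371 cm^3  (analytic 33.510)
curvature 0.0517 /mm  (analytic 0.0500)
```

The volume is the voxel-counting estimate of $\tfrac43\pi R^3$ (0.4% low at
1 mm spacing); the global curvature recovers $1/R = 0.05$ mm⁻¹ within a few
percent, the residual coming from digitisation and smoothing. On a cohort of
lobed-blob phantoms with radii 15–45 mm, measured volume and curvature show
the strong negative Spearman correlation expected from the $C_g \sim 1/R$
scale law.

The same pipeline is scriptable from the shell:

```bash
organmorph phantom --n 10 --seed 7 --out masks/
organmorph measure masks/*.nii.gz --out measured/
organmorph evaluate --truth masks/ --pred masks/ --out eval/
organmorph cohort measured/morphology.csv --out cohort/
```

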