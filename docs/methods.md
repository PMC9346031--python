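# Methods

## Problem and overall model

The main pancreatic duct is a thin, hypodense (fluid-filled) tube inside
contrast-enhanced parenchyma. On abdominal CT with ~1–2.5 mm slices it
spans only 3–5 voxels across its diameter, so at the original grid
resolution a voxel-wise segmentation cannot recover a geometrically
consistent tube even where a human observer can trace it. The package
implements a two-stage scheme built around that observation:

1. **Centerline first.** With the duct head and tail marked by user
   fiducials `P_0 … P_{N−1}`, the centerline is the curve `C`
   minimizing the vesselness-weighted path integral

   ```
   C = argmin ∫ (1 − V(C(t))) |C′(t)| dt ,   C(0)=P_0, C(1)=P_{N−1}, P_i ∈ C
   ```

   where `V ∈ [0,1]` is a Hessian-based tubularity map. By Bellman's
   principle the constrained problem decomposes into independent
   optimal sections between consecutive fiducials; each section is an
   exact shortest path on the voxel graph with edge weight
   `max(ε, 1 − (V(p)+V(q))/2) · ‖x_p − x_q‖` (physical mm, 26-connected
   by default). Tangents are finite differences and are not defined
   across section joints, because the sections are optimized
   independently.

2. **Super-resolved lumen segmentation.** The image is cropped to the
   vicinity of the centerline and refined by an odd per-axis factor
   `c = 5` (125× more voxels) with trilinear interpolation — the
   minimal convex kernel on a 3D grid, so no overshoot and exact
   reproduction at original voxel centers. On that grid a seed map `K`
   is built: label 1 (lumen) on the rasterized centerline, label 2
   (exterior) wherever the distance to the centerline exceeds
   `r = 10 mm`, label 0 undetermined. Each undetermined voxel is then
   assigned the label of the seed reachable at minimal accumulated
   intensity-difference cost

   ```
   l* = argmin_{l ∈ S} min_{paths H(l,p)} Σ |I(q_{i+1}) − I(q_i)|
   ```

   over Moore-adjacent steps, with intensities min–max normalized over
   the ROI so each step lies in [0, 1]. The cost deliberately carries
   no spatial length factor (unlike the centerline stage): homogeneous
   regions are free to traverse at any size, while crossing the duct
   wall costs the full local contrast. This is solved exactly with
   multi-source Dijkstra.

The value-1 region after propagation is the lumen; from it the package
reconstructs a surface mesh, a per-vertex Gaussian-curvature map, and a
fly-through camera path for virtual endoscopy.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| vesselness scales | 1, 1.5, 2, 3 | mm | Gaussian Hessian scales ≈ expected duct radii; spacing-aware, so anisotropic voxels are handled |
| vesselness α, β | 0.5, 0.5 | – | canonical plate/blob discrimination sensitivities |
| vesselness γ | auto | – | per scale, half the max Hessian Frobenius norm |
| polarity | dark_tube | – | duct is hypodense; the filter's sign convention flips, the image is untouched |
| edge-weight floor ε | 1e−6 | – | keeps edge weights positive so paths are finite and ties break toward shorter geometry where V = 1 |
| graph connectivity | 26 | – | Moore neighborhood, matching the propagation stage |
| super-resolution c | 5 | – | odd, so original voxel centers coincide with subvoxel centers |
| ROI margin | r + 5 | mm | guarantees exterior (label-2) seeds exist inside the ROI |
| seed radius r | 10 | mm | exterior-seed distance threshold, interpreted as physical mm via exact distances to the centerline polyline |
| surface smoothing | 1 | subvoxel | Gaussian pre-smoothing before marching cubes; suppresses staircase curvature artifacts |
| camera step | 1 | mm | fly-through keyframe spacing along the centerline spline |

## Numerical and design choices

- **Internal frame.** All physical coordinates are LPS millimetres,
  voxel-center convention, 0-based indices. Slicer `.fcsv` fiducials
  (RAS) are sign-flipped on load; the conversion is an involution.
- **Exactness of both graph solvers.** The centerline solver is a
  hand-written Dijkstra with lexicographic tie-breaking (heap keyed on
  (cost, voxel index)), so output is fully deterministic. The
  propagation stage runs two multi-source Dijkstra sweeps (one per
  seed class) and labels a voxel 1 iff its lumen-seed distance is ≤
  its exterior-seed distance — mathematically identical to one
  multi-source run with all seeds at distance 0 plus a lumen-wins tie
  rule. Ties favor the lumen because the centerline is the stronger
  prior at an exact tie. Both stages are verified against brute-force
  per-node-scan Dijkstra oracles to 1e−12.
- **ROI restriction.** The centerline graph is restricted to the
  fiducial bounding box dilated by 20 mm (disable-able); this is a
  pure optimization since the optimal duct path stays near the organ.
- **Upsampling geometry.** Output size is `n·c` per axis (each voxel
  subdivided into `c³` subvoxels), origin shifted by `−s(1 − 1/c)/2`;
  subvoxels beyond the outermost original centers use clamped nearest
  extension. Trilinear interpolation was chosen as "the" convex kernel:
  cubic kernels overshoot and would violate the convexity contract.
- **Seed rasterization.** The centerline is densified at half the
  subvoxel spacing; voxels within half a subvoxel diagonal get label 1.
  Exterior distances come from exact point-to-polyline distances via a
  k-d tree rather than a distance transform of the rasterized line,
  avoiding rasterization error at no extra cost.
- **Mask topology cleanup.** Image noise can thread single-subvoxel
  background tunnels through the lumen wall; these are below the
  geometric precision of the super-resolved grid but add spurious
  handles to the mesh. `lumen_mask` therefore applies an extensive
  one-subvoxel binary closing (never removes lumen voxels) before the
  largest-component filter. With it, phantom lumen meshes are
  watertight and genus 0 across noise seeds.
- **Curvature.** Per-vertex Gaussian curvature is the angle deficit
  divided by the Meyer mixed Voronoi area. Angle deficit satisfies the
  discrete Gauss–Bonnet identity exactly (Σ deficits = 2πχ), which the
  tests exploit as a sharp, geometry-independent check. Signed values
  are exported; color mapping is left to the viewer.
- **Camera frame.** View = spline tangent (central differences inside,
  second-order one-sided at the ends); up vector by parallel transport
  from an initial up orthogonal to the first tangent, avoiding roll
  flips at vertical tangents.
- **Degenerate inputs.** Constant images give an all-zero vesselness
  map (not an error); fiducials snapping to one voxel give a
  single-vertex, zero-cost curve; an all-seed ROI returns unchanged;
  empty masks and non-manifold meshes raise with diagnostic detail.

## The phantom: what it emulates, and what it does not

Every stage is testable without clinical data through a synthetic
phantom: a tube of configurable radius swept along a spline inside a
brighter parenchyma slab, rasterized with ×3 supersampling (fractional
partial-volume boundary intensities), Gaussian-blurred, and corrupted
with seeded additive Gaussian noise. Ground truth (exact voxel-center
mask, dense centerline, head/tail fiducials) is kept noise-free by
construction. Intensities are HU-like configuration values (background
−50, parenchyma +90, duct +15…+20) mimicking contrast-enhanced
pancreas; they are config, not physics.

Two stock configurations define the benchmark conditions:

- `easy`: straight tube, radius 2 mm, 1 mm isotropic 28×28×32 grid,
  full contrast, no blur or noise — every stage should be nearly exact
  (pipeline Dice ≥ 0.95 observed ≈ 0.97).
- `realistic`: curved spline tube, radius 1.5 mm on a (0.8, 0.8, 1.5) mm
  40×40×26 grid — 3–5 voxels across the diameter in-plane — with 70 HU
  contrast, 0.7 mm blur and noise σ = 10. The full pipeline reaches
  Dice ≈ 0.85–0.89 against truth with mean centerline error ≈ 0.3 mm.

These sizes are the package's benchmark problem sizes; they keep a full
single-CPU run in the tens of seconds while leaving the duct as thin,
in voxels, as the clinical target. The phantom does **not** emulate
surrounding anatomy (vessels, bowel gas, the duodenum), scanner physics
(beam hardening, reconstruction kernels), intensity inhomogeneity, or
pathology-distorted duct shapes. Passing the phantom benchmark
therefore demonstrates the correctness and sub-voxel capability of the
algorithmic chain under the stated noise/contrast regime — not clinical
segmentation accuracy, which depends on expert-placed fiducials and on
real-tissue appearance.

## Known limitations

- Two seed classes only: side branches not crossed by the centerline
  compete with the exterior class and are usually excluded.
- The intensity-geodesic cost has no boundary-length regularization;
  very low contrast-to-noise ratios can leak through the wall (the
  closing step removes only sub-precision tunnels, not gross leaks).
- Vesselness is computed at original resolution; a duct thinner than
  the smallest scale responds weakly and the centerline may cut
  corners at tight bends.
- Memory for the propagation graph grows linearly with ROI subvoxels
  (~13 edges/subvoxel); very long ducts should use a tubular ROI or a
  smaller margin.
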