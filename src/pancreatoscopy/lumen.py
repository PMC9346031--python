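"""Seeded lumen segmentation by intensity-geodesic label propagation.

The extracted centerline seeds the segmentation: voxels on the
(rasterized) centerline are known lumen (label 1) and voxels farther
than a radius r (default 10 mm) from it are known exterior (label 2);
everything else is undetermined (label 0). Each undetermined voxel is
then assigned the label of the seed it can reach at minimal accumulated
intensity-difference cost: a path between Moore-adjacent voxels x, y
contributes |I(x) - I(y)|, with intensities min-max normalized over the
ROI so every step lies in [0, 1]. The "distance" carries no spatial
length factor — it is purely intensity-geodesic, unlike the
length-weighted cost of the centerline stage — so homogeneous regions
are cheap to traverse at any size while crossing the duct wall costs the
full local contrast. The minimization is solved exactly with
multi-source Dijkstra sweeps; ties go to label 1 (lumen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing
from scipy.ndimage import label as cc_label
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .centerline import CenterlineCurve, resample_curve
from .core import ScalarVolume
from .superres import RoiVolume

__all__ = [
    "SeedConfig",
    "SeedLabelMap",
    "build_seed_map",
    "moore_neighbors",
    "propagate_labels",
    "lumen_mask",
]


@dataclass
class SeedConfig:
    """radius_r_mm: exterior-seed distance threshold (10 mm default)."""

    radius_r_mm: float = 10.0
    normalize: str = "minmax_roi"

    def __post_init__(self) -> None:
        if self.radius_r_mm <= 0:
            raise ValueError("radius_r_mm must be positive")
        if self.normalize != "minmax_roi":
            raise ValueError("only minmax_roi normalization is supported")


@dataclass
class SeedLabelMap:
    """Label volume over {0, 1, 2}; optionally the per-voxel geodesic cost."""

    labels: np.ndarray  # uint8, ROI grid
    costs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1, 2)).all():
            raise ValueError("labels must take values in {0, 1, 2}")

    @property
    def counts(self) -> dict[int, int]:
        return {v: int(np.count_nonzero(self.labels == v)) for v in (0, 1, 2)}


def build_seed_map(
    roi: RoiVolume, centerline: CenterlineCurve, config: SeedConfig | None = None
) -> SeedLabelMap:
    """Seed map K on the ROI grid from the centerline.

    Label 1: voxels whose center lies within half a subvoxel diagonal of
    the densified centerline polyline. Label 2: voxels whose physical
    distance to the centerline exceeds ``radius_r_mm``. Label 0:
    undetermined, to be classified by :func:`propagate_labels`.
    """
    config = config or SeedConfig()
    vol = roi.volume
    step = float(min(vol.spacing)) / 2.0
    dense = resample_curve(centerline, step).vertices
    tree = cKDTree(dense)
    shape = vol.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    centers = vol.index_to_physical(np.stack([ii, jj, kk], axis=-1)).reshape(-1, 3)
    dist, _ = tree.query(centers, workers=-1)
    dist = dist.reshape(shape)
    half_diag = 0.5 * float(np.linalg.norm(vol.spacing))
    labels = np.zeros(shape, dtype=np.uint8)
    labels[dist > config.radius_r_mm] = 2
    labels[dist <= half_diag] = 1
    if not (labels == 1).any():
        raise RuntimeError("centerline does not intersect the ROI")
    if not (labels == 2).any():
        raise ValueError(
            "no exterior (label-2) seeds inside the ROI: increase the ROI margin "
            f"beyond the seed radius r = {config.radius_r_mm} mm"
        )
    return SeedLabelMap(labels)


def moore_neighbors(index: tuple[int, int, int], shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """In-bounds Moore neighborhood of a voxel: 26 neighbors for an
    interior 3D voxel, 8 for an interior pixel of a single-slice volume."""
    idx = np.asarray(index, dtype=int)
    shp = np.asarray(shape, dtype=int)
    if np.any(idx < 0) or np.any(idx >= shp):
        raise ValueError(f"index {index} outside shape {shape}")
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                q = idx + (dx, dy, dz)
                if np.all(q >= 0) and np.all(q < shp):
                    out.append((int(q[0]), int(q[1]), int(q[2])))
    return out


def _normalize_minmax(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _moore_edges(shape: tuple[int, int, int]):
    """Undirected Moore-adjacency edges as flat index pairs (13 offsets)."""
    idx = np.arange(int(np.prod(shape)), dtype=np.int64).reshape(shape)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)  # lexicographically positive half
    ]
    rows, cols = [], []
    for off in offsets:
        src = [slice(None, -1) if o == 1 else (slice(1, None) if o == -1 else slice(None)) for o in off]
        dst = [slice(1, None) if o == 1 else (slice(None, -1) if o == -1 else slice(None)) for o in off]
        rows.append(idx[tuple(src)].ravel())
        cols.append(idx[tuple(dst)].ravel())
    return np.concatenate(rows), np.concatenate(cols)


def propagate_labels(roi: RoiVolume, seeds: SeedLabelMap) -> SeedLabelMap:
    """Classify every undetermined voxel by its intensity-geodesic seed.

    Runs one multi-source Dijkstra from the label-1 seeds and one from
    the label-2 seeds on the Moore voxel graph with step cost
    |I_norm(q) - I_norm(p)|; a voxel takes label 1 iff its distance to
    the lumen seeds is <= its distance to the exterior seeds (ties ->
    lumen). Seed voxels keep their labels; the returned map carries the
    minimal cost per voxel and contains no zeros.
    """
    labels = seeds.labels
    shape = labels.shape
    if not (labels == 0).any():
        return SeedLabelMap(labels.copy(), np.zeros(shape))
    if not (labels == 1).any() or not (labels == 2).any():
        raise ValueError("propagation needs at least one seed of each label (1 and 2)")
    inten = _normalize_minmax(roi.volume.values).ravel()
    rows, cols = _moore_edges(shape)
    weights = np.abs(inten[rows] - inten[cols])
    n = inten.size
    graph = csr_matrix((weights, (rows, cols)), shape=(n, n))
    del rows, cols, weights
    flat_labels = labels.ravel()
    d1 = dijkstra(graph, directed=False, indices=np.flatnonzero(flat_labels == 1), min_only=True)
    d2 = dijkstra(graph, directed=False, indices=np.flatnonzero(flat_labels == 2), min_only=True)
    out = np.where(d1 <= d2, np.uint8(1), np.uint8(2))
    out[flat_labels == 1] = 1
    out[flat_labels == 2] = 2
    costs = np.minimum(d1, d2)
    costs[flat_labels != 0] = 0.0
    return SeedLabelMap(out.reshape(shape), costs.reshape(shape))


def lumen_mask(
    labels: SeedLabelMap,
    roi: RoiVolume | None = None,
    largest_component: bool = True,
    fill_tunnels: bool = True,
    downsample: bool = False,
) -> ScalarVolume | tuple[ScalarVolume, ScalarVolume]:
    """Binary lumen mask from a propagated label map.

    The mask is the label-1 set, optionally restricted to its largest
    26-connected component. ``fill_tunnels`` applies a one-subvoxel
    binary closing first: noise can thread single-subvoxel background
    tunnels through the lumen wall, which are below the geometric
    precision of the grid but would add spurious handles to the surface
    topology; the closing is extensive (never removes lumen voxels).
    With ``downsample=True`` (requires ``roi``) a majority-vote mask on
    the original grid is returned as well: an original voxel is lumen
    iff more than half of its c^3 subvoxels are.
    """
    lab = labels.labels
    if (lab == 0).any():
        raise ValueError("label map still contains undetermined voxels; propagate first")
    mask = lab == 1
    if not mask.any():
        raise ValueError("degenerate result: empty lumen (no label-1 voxels)")
    if fill_tunnels:
        padded = np.pad(mask, 1)
        closed = binary_closing(padded, structure=np.ones((3, 3, 3), dtype=bool))
        mask = mask | closed[1:-1, 1:-1, 1:-1]
    if largest_component:
        comp, ncomp = cc_label(mask, structure=np.ones((3, 3, 3), dtype=int))
        if ncomp > 1:
            sizes = np.bincount(comp.ravel())
            sizes[0] = 0
            mask = comp == int(np.argmax(sizes))
    if roi is None:
        if downsample:
            raise ValueError("downsampling requires the RoiVolume for geometry")
        return ScalarVolume(mask.astype(np.uint8), np.ones(3), np.zeros(3))
    vol = roi.volume
    hi_res = ScalarVolume(mask.astype(np.uint8), vol.spacing, vol.origin, vol.direction)
    if not downsample:
        return hi_res
    c = roi.factor
    if any(s % c for s in mask.shape):
        raise ValueError("ROI shape is not a multiple of the super-resolution factor")
    n0, n1, n2 = (s // c for s in mask.shape)
    frac = mask.reshape(n0, c, n1, c, n2, c).mean(axis=(1, 3, 5))
    low = (frac > 0.5).astype(np.uint8)
    orig_spacing = vol.spacing * c
    # original voxel (0,0,0) center = mean of its subvoxel centers
    shift = vol.spacing * (c - 1) / 2.0
    orig_origin = vol.origin + vol.direction @ shift
    low_vol = ScalarVolume(low, orig_spacing, orig_origin, vol.direction)
    return hi_res, low_vol
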