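"""Duct centerline extraction by vesselness-weighted minimal paths.

The centerline is the curve C minimizing the path integral of
``(1 - V(C)) |C'(t)| dt`` between the user's first and last fiducials,
constrained to pass through every intermediate fiducial. By Bellman's
principle of optimality the constrained problem decomposes into
independent optimal sections between consecutive fiducials; each section
is solved exactly as a shortest path on the voxel graph with edge weight

    w(p, q) = max(weight_floor, 1 - (V(p) + V(q)) / 2) * ||x_p - x_q||

(physical mm, anisotropic spacing honored). Sections are concatenated
without smoothing across the joints; tangents are finite differences and
are deliberately not defined at section joints.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .core import FiducialSet, ScalarVolume

__all__ = [
    "CenterlineCurve",
    "PathGraphParams",
    "extract_centerline",
    "tangent_at",
    "resample_curve",
]


def _polyline_arclength(vertices: np.ndarray) -> np.ndarray:
    if len(vertices) <= 1:
        return np.zeros(len(vertices))
    steps = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class CenterlineCurve:
    """Ordered polyline in physical mm with arc length and path cost."""

    vertices: np.ndarray
    cost: float = 0.0
    section_breaks: list[int] = field(default_factory=list)
    arclength: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.arclength is None:
            self.arclength = _polyline_arclength(self.vertices)
        else:
            self.arclength = np.asarray(self.arclength, dtype=float)
        if len(self.arclength) and (
            np.any(np.diff(self.arclength) < 0) or self.arclength[0] != 0
        ):
            raise ValueError("arclength must start at 0 and be nondecreasing")

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "vertices_mm": self.vertices.tolist(),
                "arclength_mm": self.arclength.tolist(),
                "cost": self.cost,
                "section_breaks": list(self.section_breaks),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CenterlineCurve":
        import json

        data = json.loads(text)
        return cls(
            np.asarray(data["vertices_mm"], dtype=float),
            cost=float(data.get("cost", 0.0)),
            section_breaks=list(data.get("section_breaks", [])),
            arclength=np.asarray(data["arclength_mm"], dtype=float)
            if "arclength_mm" in data
            else None,
        )


@dataclass
class PathGraphParams:
    """Voxel-graph parameters for the minimal-path solver.

    connectivity: 26 (Moore, default) or 6-neighborhood.
    weight_floor: small positive floor keeping edge weights > 0 so paths
        stay finite and ties break toward shorter geometry where V = 1.
    snap_radius_mm: 0 snaps each fiducial to its nearest voxel center;
        > 0 snaps to the max-vesselness voxel within that radius.
    bbox_margin_mm: restrict the graph to the fiducial bounding box
        dilated by this margin; None uses the whole volume.
    """

    connectivity: int = 26
    weight_floor: float = 1e-6
    snap_radius_mm: float = 0.0
    bbox_margin_mm: float | None = 20.0

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.weight_floor < 0:
            raise ValueError("weight_floor must be >= 0")


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    return np.array(offs)


def _dijkstra_section(
    vess: np.ndarray,
    spacing: np.ndarray,
    src: tuple[int, int, int],
    dst: tuple[int, int, int],
    params: PathGraphParams,
) -> tuple[list[tuple[int, int, int]], float]:
    """Exact shortest path src -> dst on the voxel grid.

    Ties in tentative cost break toward the lexicographically smallest
    voxel index (heap entries are (cost, linear index); equal-cost
    relaxations prefer the lower-index predecessor), so output is fully
    deterministic.
    """
    shape = vess.shape
    if src == dst:
        return [src], 0.0
    offsets = _neighbor_offsets(params.connectivity)
    step_len = np.linalg.norm(offsets * spacing, axis=1)
    n = int(np.prod(shape))
    flat = vess.ravel()
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    src_lin = int(np.ravel_multi_index(src, shape))
    dst_lin = int(np.ravel_multi_index(dst, shape))
    dist[src_lin] = 0.0
    heap: list[tuple[float, int]] = [(0.0, src_lin)]
    shape_arr = np.array(shape)
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        if u == dst_lin:
            break
        u3 = np.array(np.unravel_index(u, shape))
        cand = u3 + offsets
        ok = np.all((cand >= 0) & (cand < shape_arr), axis=1)
        q3 = cand[ok]
        qlin = np.ravel_multi_index((q3[:, 0], q3[:, 1], q3[:, 2]), shape)
        w = np.maximum(params.weight_floor, 1.0 - 0.5 * (flat[u] + flat[qlin]))
        nd = d + w * step_len[ok]
        better = nd < dist[qlin]
        tie = (nd == dist[qlin]) & (pred[qlin] > u)
        upd = better | tie
        if np.any(upd):
            targets = qlin[upd]
            dist[targets] = nd[upd]
            pred[targets] = u
            for c, t in zip(nd[upd], targets):
                heapq.heappush(heap, (float(c), int(t)))
    if not np.isfinite(dist[dst_lin]):  # pragma: no cover - grid graphs are connected
        raise RuntimeError("voxel graph unexpectedly disconnected")
    path = []
    cur = dst_lin
    while cur != -1:
        path.append(tuple(int(v) for v in np.unravel_index(cur, shape)))
        cur = int(pred[cur]) if cur != src_lin else -1
    path.reverse()
    return path, float(dist[dst_lin])


def _snap_fiducial(vesselness: ScalarVolume, point: np.ndarray, params: PathGraphParams):
    idx = vesselness.physical_to_index(point)
    shape = np.array(vesselness.shape)
    if np.any(idx < -0.5) or np.any(idx > shape - 0.5):
        raise ValueError(f"fiducial {point} lies outside the volume")
    nearest = tuple(int(v) for v in np.clip(np.round(idx), 0, shape - 1).astype(int))
    if params.snap_radius_mm <= 0:
        return nearest
    # search the max-vesselness voxel within the physical snap radius
    rad_vox = np.ceil(params.snap_radius_mm / vesselness.spacing).astype(int)
    lo = np.maximum(np.array(nearest) - rad_vox, 0)
    hi = np.minimum(np.array(nearest) + rad_vox + 1, shape)
    sub = vesselness.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    centers = vesselness.index_to_physical(np.stack([ii, jj, kk], axis=-1))
    d = np.linalg.norm(centers - point, axis=-1)
    masked = np.where(d <= params.snap_radius_mm, sub, -np.inf)
    best = np.unravel_index(np.argmax(masked), masked.shape)
    return tuple(int(lo[a] + best[a]) for a in range(3))


def extract_centerline(
    vesselness: ScalarVolume,
    fiducials: FiducialSet,
    params: PathGraphParams | None = None,
) -> CenterlineCurve:
    """Section-wise optimal centerline through the ordered fiducials.

    Each consecutive fiducial pair gets an independent exact shortest
    path on the voxel graph; sections are concatenated. Returned
    vertices are voxel centers in mm; ``cost`` is the exact sum of
    traversed edge weights and ``section_breaks`` marks the joints.
    """
    params = params or PathGraphParams()
    v = vesselness.values
    if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
        raise ValueError("vesselness values must lie in [0, 1]")
    snapped = [_snap_fiducial(vesselness, p, params) for p in fiducials.points]

    # restrict the graph to the dilated fiducial bounding box (pure optimization)
    shape = np.array(vesselness.shape)
    if params.bbox_margin_mm is None:
        lo = np.zeros(3, dtype=int)
        hi = shape
    else:
        snap_arr = np.array(snapped)
        dil = np.ceil(params.bbox_margin_mm / vesselness.spacing).astype(int)
        lo = np.maximum(snap_arr.min(axis=0) - dil, 0)
        hi = np.minimum(snap_arr.max(axis=0) + dil + 1, shape)
    sub = np.asarray(v[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]], dtype=float)

    vertices: list[tuple[int, int, int]] = []
    breaks: list[int] = []
    total_cost = 0.0
    for a, b in zip(snapped[:-1], snapped[1:]):
        a_l = tuple(int(x) for x in (np.array(a) - lo))
        b_l = tuple(int(x) for x in (np.array(b) - lo))
        path, cost = _dijkstra_section(sub, vesselness.spacing, a_l, b_l, params)
        total_cost += cost
        path_g = [tuple(int(x) for x in (np.array(p) + lo)) for p in path]
        if vertices:
            breaks.append(len(vertices) - 1)
            path_g = path_g[1:]  # joint vertex shared with previous section
        vertices.extend(path_g)
    pts = vesselness.index_to_physical(np.array(vertices, dtype=float))
    return CenterlineCurve(pts, cost=total_cost, section_breaks=breaks)


def tangent_at(curve: CenterlineCurve, vertex_index: int, allow_joint: bool = False) -> np.ndarray:
    """Unit tangent by finite differences; one-sided at the endpoints.

    Section joints have no two-sided tangent (sections are optimized
    independently); pass ``allow_joint=True`` to get the one-sided
    backward difference there.
    """
    verts = curve.vertices
    n = len(verts)
    if n < 2:
        raise ValueError("tangent undefined for a single-vertex curve")
    i = vertex_index
    if i < 0 or i >= n:
        raise IndexError(f"vertex index {i} out of range [0, {n})")
    if i in curve.section_breaks:
        if not allow_joint:
            raise ValueError(
                f"vertex {i} is a section joint; tangents are not defined across "
                "joints (pass allow_joint=True for the one-sided difference)"
            )
        diff = verts[i] - verts[i - 1]
    elif i == 0:
        diff = verts[1] - verts[0]
    elif i == n - 1:
        diff = verts[-1] - verts[-2]
    else:
        diff = verts[i + 1] - verts[i - 1]
    nrm = np.linalg.norm(diff)
    if nrm == 0:
        raise ValueError(f"zero-length tangent at vertex {i} (repeated vertices)")
    return diff / nrm


def resample_curve(curve: CenterlineCurve, step_mm: float) -> CenterlineCurve:
    """Cubic-spline resampling at uniform arc-length steps <= step_mm.

    Endpoints are preserved exactly. The spline interpolates the input
    vertices (chord-length parameterization); the uniform arc-length grid
    is found by densely evaluating the spline and inverting its length
    function numerically.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    verts = curve.vertices
    if len(verts) < 2:
        raise ValueError("resampling needs at least 2 vertices")
    # drop exactly repeated consecutive vertices (spline needs strict params)
    keep = np.concatenate([[True], np.linalg.norm(np.diff(verts, axis=0), axis=1) > 0])
    verts = verts[keep]
    if len(verts) < 2:
        raise ValueError("curve has zero length")
    t = _polyline_arclength(verts)
    k = min(3, len(verts) - 1)
    spline = make_interp_spline(t, verts, k=k)
    dense_t = np.linspace(0.0, t[-1], max(20 * len(verts), 200))
    dense = spline(dense_t)
    s = _polyline_arclength(dense)
    total = s[-1]
    n_out = int(np.ceil(total / step_mm - 1e-12)) + 1
    targets = np.linspace(0.0, total, n_out)
    t_of_s = np.interp(targets, s, dense_t)
    out = spline(t_of_s)
    out[0] = verts[0]
    out[-1] = verts[-1]
    return CenterlineCurve(out, cost=curve.cost, section_breaks=[])
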