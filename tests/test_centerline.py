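"""Minimal-path centerline: exact-oracle equivalence and curve operations."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pancreatoscopy import (
    CenterlineCurve,
    FiducialSet,
    PathGraphParams,
    ScalarVolume,
    centerline_distance,
    extract_centerline,
    resample_curve,
    tangent_at,
)

WEIGHT_FLOOR = 1e-6


def _oracle_cost(vess: np.ndarray, spacing, src, dst, connectivity=26) -> float:
    """Brute-force shortest-path cost on the voxel graph via networkx."""
    g = nx.Graph()
    shape = vess.shape
    offs = [
        o
        for o in itertools.product((-1, 0, 1), repeat=3)
        if o != (0, 0, 0) and (connectivity == 26 or sum(map(abs, o)) == 1)
    ]
    for idx in itertools.product(*[range(n) for n in shape]):
        for off in offs:
            q = tuple(np.add(idx, off))
            if all(0 <= q[a] < shape[a] for a in range(3)):
                w = max(WEIGHT_FLOOR, 1.0 - 0.5 * (vess[idx] + vess[q]))
                g.add_edge(idx, q, weight=w * float(np.linalg.norm(np.multiply(off, spacing))))
    return nx.dijkstra_path_length(g, src, dst)


def _vol(vess, spacing=(1.0, 1.0, 1.0)):
    return ScalarVolume(np.asarray(vess, dtype=float), spacing, (0.0, 0.0, 0.0))


def _fids_at(vol, *indices):
    return FiducialSet(vol.index_to_physical(np.array(indices, dtype=float)))


def test_coincident_fiducials_give_single_vertex_zero_cost():
    vol = _vol(np.zeros((4, 4, 4)))
    fids = FiducialSet([[1.0, 1.0, 1.0], [1.2, 0.9, 1.1]])  # same nearest voxel
    curve = extract_centerline(vol, fids)
    assert len(curve) == 1
    assert curve.cost == 0.0


def test_high_vesselness_row_is_followed_exactly():
    """5x5x1 grid, V=1 on the middle row: the path runs along it at ~0 cost.

    Exhaustive check: every simple path between the endpoints on the
    25-node graph is enumerated; the middle row is the unique minimizer.
    """
    vess = np.zeros((5, 5, 1))
    vess[:, 2, 0] = 1.0
    vol = _vol(vess)
    curve = extract_centerline(vol, _fids_at(vol, (0, 2, 0), (4, 2, 0)), PathGraphParams())
    expected = vol.index_to_physical(np.array([[i, 2, 0] for i in range(5)], float))
    np.testing.assert_allclose(curve.vertices, expected)
    assert curve.cost == pytest.approx(4 * WEIGHT_FLOOR, abs=1e-12)

    g = nx.Graph()
    for i, j in itertools.product(range(5), range(5)):
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            if (di, dj) == (0, 0):
                continue
            q = (i + di, j + dj)
            if 0 <= q[0] < 5 and 0 <= q[1] < 5:
                w = max(WEIGHT_FLOOR, 1 - 0.5 * (vess[i, j, 0] + vess[q[0], q[1], 0]))
                g.add_edge((i, j), q, weight=w * float(np.hypot(di, dj)))
    best = min(
        sum(g[a][b]["weight"] for a, b in zip(p, p[1:]))
        for p in nx.all_simple_paths(g, (0, 2), (4, 2), cutoff=8)
    )
    assert curve.cost == pytest.approx(best, abs=1e-12)


def test_uniform_vesselness_gives_straight_path():
    vess = np.full((9, 3, 3), 0.5)
    vol = _vol(vess)
    curve = extract_centerline(vol, _fids_at(vol, (2, 1, 1), (6, 1, 1)))
    assert curve.cost == pytest.approx((1 - 0.5) * 4.0, rel=1e-9)
    assert len(curve) == 5
    assert np.all(curve.vertices[:, 1] == 1.0) and np.all(curve.vertices[:, 2] == 1.0)


@pytest.mark.parametrize("connectivity", [6, 26])
def test_cost_matches_bruteforce_oracle_on_random_volumes(rng, connectivity):
    """Exact equality with an independent Dijkstra on random small grids."""
    for _ in range(20):
        shape = tuple(rng.integers(3, 7, size=3))
        vess = rng.random(shape)
        spacing = rng.uniform(0.5, 2.0, size=3)
        vol = ScalarVolume(vess, spacing, (0.0, 0.0, 0.0))
        src = tuple(rng.integers(0, shape[a]) for a in range(3))
        dst = tuple(rng.integers(0, shape[a]) for a in range(3))
        fids = FiducialSet(vol.index_to_physical(np.array([src, dst], float)))
        curve = extract_centerline(vol, fids, PathGraphParams(connectivity=connectivity))
        expected = _oracle_cost(vess, spacing, src, dst, connectivity)
        assert curve.cost == pytest.approx(expected, abs=1e-12)


def test_endpoint_swap_reverses_curve_and_preserves_cost(rng):
    vess = rng.random((6, 6, 6))
    vol = _vol(vess)
    fwd = extract_centerline(vol, _fids_at(vol, (0, 0, 0), (5, 5, 5)))
    rev = extract_centerline(vol, _fids_at(vol, (5, 5, 5), (0, 0, 0)))
    assert fwd.cost == pytest.approx(rev.cost, abs=1e-9)
    np.testing.assert_allclose(fwd.vertices, rev.vertices[::-1])


def test_intermediate_fiducial_on_optimal_path_keeps_cost(rng):
    vess = rng.random((6, 6, 6))
    vol = _vol(vess)
    two = extract_centerline(vol, _fids_at(vol, (0, 0, 0), (5, 5, 5)))
    mid_vertex = two.vertices[len(two) // 2]
    three = extract_centerline(
        vol, FiducialSet(np.stack([two.vertices[0], mid_vertex, two.vertices[-1]]))
    )
    assert three.cost == pytest.approx(two.cost, abs=1e-9)
    assert three.section_breaks  # the joint is recorded


def test_tube_capture_on_easy_phantom(easy_result, easy_truth):
    """Extracted centerline stays within one voxel diagonal of the truth."""
    mean_d, _ = centerline_distance(easy_result.centerline, easy_truth.centerline)
    diag = float(np.linalg.norm(easy_truth.image.spacing))
    assert mean_d <= diag


def test_fiducial_outside_volume_rejected():
    vol = _vol(np.zeros((5, 5, 5)))
    with pytest.raises(ValueError, match="outside"):
        extract_centerline(vol, FiducialSet([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]))


# --- tangents ---------------------------------------------------------------


def test_tangent_of_straight_curve_along_z():
    curve = CenterlineCurve(np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)]))
    for i in range(1, 5):
        np.testing.assert_allclose(tangent_at(curve, i), (0, 0, 1))
    np.testing.assert_allclose(tangent_at(curve, 0), (0, 0, 1))
    np.testing.assert_allclose(tangent_at(curve, 5), (0, 0, 1))


def test_tangent_orthogonal_to_radius_on_quarter_circle():
    theta = np.deg2rad(np.arange(0, 91))
    pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros_like(theta)])
    curve = CenterlineCurve(pts)
    for i in (1, 30, 60, 89):
        t = tangent_at(curve, i)
        assert abs(np.dot(t, pts[i] / np.linalg.norm(pts[i]))) < 1e-3


def test_reversing_vertices_negates_tangents(rng):
    pts = np.cumsum(rng.normal(size=(8, 3)), axis=0)
    fwd = CenterlineCurve(pts)
    rev = CenterlineCurve(pts[::-1])
    n = len(pts)
    for i in range(n):
        np.testing.assert_allclose(tangent_at(fwd, i), -tangent_at(rev, n - 1 - i), atol=1e-12)


def test_tangent_refused_at_section_joint():
    pts = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
    curve = CenterlineCurve(pts, section_breaks=[2])
    with pytest.raises(ValueError, match="joint"):
        tangent_at(curve, 2)
    np.testing.assert_allclose(tangent_at(curve, 2, allow_joint=True), (0, 0, 1))


def test_tangent_undefined_for_single_vertex():
    with pytest.raises(ValueError, match="single-vertex"):
        tangent_at(CenterlineCurve([[0.0, 0.0, 0.0]]), 0)


# --- resampling -------------------------------------------------------------


def test_resample_straight_segment_uniform():
    curve = CenterlineCurve([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
    out = resample_curve(curve, 1.0)
    assert len(out) == 11
    np.testing.assert_allclose(np.diff(out.vertices[:, 2]), 1.0, atol=1e-9)
    np.testing.assert_allclose(out.vertices[0], curve.vertices[0])
    np.testing.assert_allclose(out.vertices[-1], curve.vertices[-1])


def test_resample_preserves_length_of_curved_polyline():
    t = np.linspace(0, 2 * np.pi, 40)
    pts = np.column_stack([5 * np.cos(t), 5 * np.sin(t), 2 * t])  # helix
    curve = CenterlineCurve(pts)
    out = resample_curve(curve, 0.5)
    assert out.length == pytest.approx(curve.length, rel=0.01)
    steps = np.diff(out.arclength)
    assert np.all(steps <= 0.5 + 1e-9)


def test_resample_twice_is_idempotent_on_straight_curve():
    curve = CenterlineCurve([[1.0, 2.0, 0.0], [1.0, 2.0, 12.0]])
    once = resample_curve(curve, 1.5)
    twice = resample_curve(once, 1.5)
    assert np.max(np.abs(once.vertices - twice.vertices)) < 1e-6


def test_resample_rejects_nonpositive_step():
    curve = CenterlineCurve([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(ValueError, match="positive"):
        resample_curve(curve, 0.0)
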