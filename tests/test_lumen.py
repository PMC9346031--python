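"""Seed map construction and intensity-geodesic label propagation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pancreatoscopy import (
    CenterlineCurve,
    RoiVolume,
    ScalarVolume,
    SeedConfig,
    SeedLabelMap,
    build_seed_map,
    lumen_mask,
    moore_neighbors,
    propagate_labels,
)


def _roi(values, spacing=(1.0, 1.0, 1.0), factor=1):
    vol = ScalarVolume(np.asarray(values, dtype=float), spacing, (0.0, 0.0, 0.0))
    return RoiVolume(vol, (0, 0, 0), factor)


def _oracle_labels(image: np.ndarray, seeds: np.ndarray):
    """Per-voxel exhaustive multi-source Dijkstra oracle (networkx).

    Returns (labels, costs) under the documented tie rule: label 1 wins
    when the minimal costs to both seed groups are equal.
    """
    norm = image.astype(float)
    lo, hi = norm.min(), norm.max()
    norm = (norm - lo) / (hi - lo) if hi > lo else np.zeros_like(norm)
    shape = image.shape
    g = nx.Graph()
    g.add_nodes_from(itertools.product(*[range(n) for n in shape]))
    for idx in itertools.product(*[range(n) for n in shape]):
        for off in itertools.product((-1, 0, 1), repeat=3):
            if off == (0, 0, 0):
                continue
            q = tuple(np.add(idx, off))
            if all(0 <= q[a] < shape[a] for a in range(3)):
                g.add_edge(idx, q, weight=abs(norm[idx] - norm[q]))
    d1 = nx.multi_source_dijkstra_path_length(g, set(map(tuple, np.argwhere(seeds == 1))))
    d2 = nx.multi_source_dijkstra_path_length(g, set(map(tuple, np.argwhere(seeds == 2))))
    labels = np.empty(shape, dtype=np.uint8)
    costs = np.empty(shape, dtype=float)
    for idx in itertools.product(*[range(n) for n in shape]):
        a, b = d1[idx], d2[idx]
        labels[idx] = 1 if a <= b else 2
        costs[idx] = min(a, b)
    labels[seeds == 1] = 1
    labels[seeds == 2] = 2
    costs[seeds != 0] = 0.0
    return labels, costs


# --- seed map ---------------------------------------------------------------


def test_seed_map_labels_follow_distance_to_centerline():
    roi = _roi(np.zeros((140, 9, 9)), spacing=(0.2, 0.2, 0.2))
    # straight centerline along x at y=z=0.8mm, spanning x in [0, 2] mm;
    # axial distance beyond the endpoint separates the three labels
    cl = CenterlineCurve([[0.0, 0.8, 0.8], [2.0, 0.8, 0.8]])
    seeds = build_seed_map(roi, cl, SeedConfig(radius_r_mm=10.0))
    lab = seeds.labels
    # every voxel traversed by the centerline has label 1
    x_mm = np.arange(140) * 0.2
    on_line = x_mm <= 2.0
    assert np.all(lab[on_line, 4, 4] == 1)
    # 12 mm from the curve -> label 2; 5 mm away -> label 0 (r = 10 mm)
    far = x_mm - 2.0 > 10.0 + 1e-9
    mid = (x_mm - 2.0 > 3.0) & (x_mm - 2.0 < 9.0)
    assert np.all(lab[far, 4, 4] == 2)
    assert np.all(lab[mid, 4, 4] == 0)
    counts = seeds.counts
    assert counts[0] + counts[1] + counts[2] == lab.size


def test_seed_map_requires_exterior_seeds():
    roi = _roi(np.zeros((10, 10, 10)))  # 10mm cube, nothing >10mm from the line
    cl = CenterlineCurve([[0.0, 4.5, 4.5], [9.0, 4.5, 4.5]])
    with pytest.raises(ValueError, match="margin"):
        build_seed_map(roi, cl, SeedConfig(radius_r_mm=10.0))


# --- Moore neighborhood -----------------------------------------------------


def test_moore_neighborhood_interior_3d_has_26():
    assert len(moore_neighbors((2, 2, 2), (5, 5, 5))) == 26


def test_moore_neighborhood_corner_has_7():
    assert len(moore_neighbors((0, 0, 0), (5, 5, 5))) == 7


def test_moore_neighborhood_single_slice_has_8():
    assert len(moore_neighbors((2, 2, 0), (5, 5, 1))) == 8


def test_moore_neighborhood_rejects_outside_index():
    with pytest.raises(ValueError, match="outside"):
        moore_neighbors((5, 0, 0), (5, 5, 5))


# --- propagation ------------------------------------------------------------


def test_constant_roi_total_tie_goes_to_lumen():
    seeds = np.zeros((4, 4, 1), dtype=np.uint8)
    seeds[0, 0, 0] = 1
    seeds[3, 3, 0] = 2
    out = propagate_labels(_roi(np.ones((4, 4, 1))), SeedLabelMap(seeds))
    assert out.labels[3, 3, 0] == 2  # seed keeps its label
    mask = np.ones((4, 4, 1), dtype=bool)
    mask[3, 3, 0] = False
    assert np.all(out.labels[mask] == 1)


def test_step_edge_chain_splits_at_the_jump():
    inten = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]).reshape(6, 1, 1)
    seeds = np.zeros((6, 1, 1), dtype=np.uint8)
    seeds[0, 0, 0] = 1
    seeds[5, 0, 0] = 2
    out = propagate_labels(_roi(inten), SeedLabelMap(seeds))
    np.testing.assert_array_equal(out.labels[:, 0, 0], [1, 1, 1, 2, 2, 2])
    np.testing.assert_allclose(out.costs[:, 0, 0], [0, 0, 0, 0, 0, 0])


def test_dark_tube_recovered_exactly():
    """Noise-free two-intensity tube: label-1 set equals the tube exactly."""
    img = np.full((20, 20, 5), 0.9)
    ii, jj = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
    tube = (ii - 10) ** 2 + (jj - 10) ** 2 <= 3.0**2
    img[tube] = 0.1
    seeds = np.zeros_like(img, dtype=np.uint8)
    seeds[10, 10, :] = 1  # centerline seeds inside
    ring = (ii - 10) ** 2 + (jj - 10) ** 2 >= 8**2
    seeds[ring] = 2
    out = propagate_labels(_roi(img), SeedLabelMap(seeds))
    np.testing.assert_array_equal(out.labels == 1, np.repeat(tube[:, :, None], 5, axis=2))
    oracle_lab, oracle_cost = _oracle_labels(img, seeds)
    np.testing.assert_array_equal(out.labels, oracle_lab)
    np.testing.assert_allclose(out.costs, oracle_cost, atol=1e-12)


def test_matches_exhaustive_oracle_on_random_images(rng):
    """Labels AND minimal costs equal the per-voxel Dijkstra oracle exactly."""
    for _ in range(15):
        shape = tuple(rng.integers(2, 6, size=2)) + (rng.integers(1, 4),)
        img = rng.random(shape)
        seeds = np.zeros(shape, dtype=np.uint8)
        flat = np.arange(img.size)
        picks = rng.choice(flat, size=max(2, img.size // 6), replace=False)
        seeds.ravel()[picks[: len(picks) // 2]] = 1
        seeds.ravel()[picks[len(picks) // 2 :]] = 2
        if not (seeds == 1).any() or not (seeds == 2).any():
            continue
        out = propagate_labels(_roi(img), SeedLabelMap(seeds))
        oracle_lab, oracle_cost = _oracle_labels(img, seeds)
        np.testing.assert_array_equal(out.labels, oracle_lab)
        np.testing.assert_allclose(out.costs, oracle_cost, atol=1e-12)


def test_two_region_images_are_segmented_exactly(rng):
    """Piecewise-constant two-region image: propagation recovers the regions
    for any one-seed-per-region placement."""
    for _ in range(10):
        shape = (rng.integers(4, 9), rng.integers(4, 9), rng.integers(1, 4))
        split = rng.integers(1, shape[0])
        img = np.empty(shape)
        v1, v2 = sorted(rng.random(2))
        img[:split] = v1
        img[split:] = v2 + 0.2  # distinct values
        seeds = np.zeros(shape, dtype=np.uint8)
        s1 = (rng.integers(0, split), rng.integers(0, shape[1]), rng.integers(0, shape[2]))
        s2 = (rng.integers(split, shape[0]), rng.integers(0, shape[1]), rng.integers(0, shape[2]))
        seeds[s1] = 1
        seeds[s2] = 2
        out = propagate_labels(_roi(img), SeedLabelMap(seeds))
        assert np.all(out.labels[:split] == 1)
        assert np.all(out.labels[split:] == 2)


def test_affine_intensity_rescaling_leaves_labels_unchanged(rng):
    img = rng.random((6, 6, 3))
    seeds = np.zeros_like(img, dtype=np.uint8)
    seeds[0, 0, 0] = 1
    seeds[5, 5, 2] = 2
    base = propagate_labels(_roi(img), SeedLabelMap(seeds))
    shifted = propagate_labels(_roi(img + 123.0), SeedLabelMap(seeds))
    scaled = propagate_labels(_roi(img * 7.5 + 3.0), SeedLabelMap(seeds))
    np.testing.assert_array_equal(base.labels, shifted.labels)
    np.testing.assert_array_equal(base.labels, scaled.labels)


def test_propagation_is_deterministic(rng):
    img = rng.random((7, 7, 3))
    seeds = np.zeros_like(img, dtype=np.uint8)
    seeds[0, :, :] = 1
    seeds[6, :, :] = 2
    a = propagate_labels(_roi(img), SeedLabelMap(seeds))
    b = propagate_labels(_roi(img), SeedLabelMap(seeds))
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.costs, b.costs)


def test_all_seed_map_returned_unchanged():
    seeds = np.full((3, 3, 1), 2, dtype=np.uint8)
    seeds[1, 1, 0] = 1
    out = propagate_labels(_roi(np.zeros((3, 3, 1))), SeedLabelMap(seeds))
    np.testing.assert_array_equal(out.labels, seeds)


# --- mask extraction --------------------------------------------------------


def test_majority_downsample_of_full_block_is_one():
    c = 3
    lab = np.ones((c, c, c), dtype=np.uint8)
    roi = _roi(np.zeros((c, c, c)), spacing=(1 / c,) * 3, factor=c)
    hi, lo = lumen_mask(SeedLabelMap(lab), roi, downsample=True)
    assert lo.values.shape == (1, 1, 1)
    assert lo.values[0, 0, 0] == 1


def test_mask_keeps_centerline_seed_voxels(easy_result):
    lab = easy_result.labels.labels
    mask = easy_result.lumen_highres.values
    # every label-1 seed region voxel retained by the largest-component filter
    assert mask[lab == 1].all() or (mask[lab == 1].mean() > 0.999)


def test_mask_requires_complete_propagation():
    lab = np.zeros((3, 3, 3), dtype=np.uint8)
    lab[0, 0, 0] = 1
    with pytest.raises(ValueError, match="undetermined"):
        lumen_mask(SeedLabelMap(lab))


def test_empty_lumen_is_degenerate():
    lab = np.full((3, 3, 3), 2, dtype=np.uint8)
    with pytest.raises(ValueError, match="empty lumen"):
        lumen_mask(SeedLabelMap(lab))
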