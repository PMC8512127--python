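"""Distance transform, marker extraction and ordered-queue flooding."""

import heapq

import numpy as np
import pytest

from phenoleaf import (
    BBox,
    SceneSpec,
    count_leaves,
    euclidean_distance_transform,
    find_markers,
    generate_scene,
    watershed_flood,
)
from phenoleaf.counting import _quantize_complement


def brute_force_edt(mask):
    """Literal minimum distance to any background pixel, O(n^2)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    bg = np.argwhere(~mask)
    out = np.zeros((h, w), dtype=float)
    for y, x in np.argwhere(mask):
        out[y, x] = np.sqrt(((bg - (y, x)) ** 2).sum(axis=1)).min()
    return out


def heap_flood(topo, markers, mask, connectivity=4):
    """Independent flooding oracle: a single heap keyed by
    (gray level, FIFO sequence number), same N/E/S/W neighbour order."""
    topo = np.asarray(topo)
    g = np.asarray(markers, dtype=np.int32).copy()
    mask = np.asarray(mask, dtype=bool)
    g[~mask] = 0
    h, w = topo.shape
    steps = [(-1, 0), (0, 1), (1, 0), (0, -1)]
    if connectivity == 8:
        steps += [(-1, -1), (-1, 1), (1, 1), (1, -1)]
    heap, counter = [], 0
    for y, x in np.argwhere(g > 0):
        for dy, dx in steps:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and g[ny, nx] != g[y, x]:
                heapq.heappush(heap, (int(topo[y, x]), counter, int(y), int(x)))
                counter += 1
                break
    while heap:
        _, _, y, x = heapq.heappop(heap)
        lbl = g[y, x]
        for dy, dx in steps:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and g[ny, nx] == 0:
                g[ny, nx] = lbl
                heapq.heappush(heap, (int(topo[ny, nx]), counter, ny, nx))
                counter += 1
    return g


class TestEuclideanDistanceTransform:
    def test_all_background_is_zero(self):
        assert not euclidean_distance_transform(np.zeros((5, 5), bool)).any()

    def test_single_foreground_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        dm = euclidean_distance_transform(mask)
        assert dm[2, 2] == 1.0
        assert dm.sum() == 1.0

    def test_centered_square_known_values(self):
        # 5x5 solid square centred in 11x11: centre 3.0; every corner's
        # nearest background pixel is its axial 4-neighbour, distance 1
        # (the diagonal background pixel is sqrt(2) away, farther)
        mask = np.zeros((11, 11), dtype=bool)
        mask[3:8, 3:8] = True
        dm = euclidean_distance_transform(mask)
        assert dm == pytest.approx(brute_force_edt(mask))
        assert dm[5, 5] == pytest.approx(3.0)
        for corner in [(3, 3), (3, 7), (7, 3), (7, 7)]:
            assert dm[corner] == pytest.approx(1.0)

    def test_all_foreground_measures_to_virtual_border(self):
        dm = euclidean_distance_transform(np.ones((5, 9), dtype=bool))
        assert dm[0, 0] == pytest.approx(1.0)
        assert dm[2, 4] == pytest.approx(3.0)  # centre row of height 5

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            mask = rng.random((32, 32)) < 0.6
            mask[0, 0] = False  # keep at least one background pixel
            assert np.array_equal(
                euclidean_distance_transform(mask), brute_force_edt(mask)
            )


class TestFindMarkers:
    def test_single_disc_one_marker(self):
        yy, xx = np.mgrid[-20:21, -20:21]
        dm = euclidean_distance_transform(xx**2 + yy**2 <= 15**2)
        markers = find_markers(dm, 7, 0.5)
        assert np.unique(markers[markers > 0]).size == 1

    def test_two_bridged_discs_two_markers(self):
        mask = np.zeros((40, 80), dtype=bool)
        yy, xx = np.mgrid[:40, :80]
        mask |= (xx - 20) ** 2 + (yy - 20) ** 2 <= 12**2
        mask |= (xx - 60) ** 2 + (yy - 20) ** 2 <= 12**2
        mask[19:21, 20:60] = True  # 2-px bridge, EDT 1 << disc EDT 12
        markers = find_markers(euclidean_distance_transform(mask), 7, 0.5)
        assert np.unique(markers[markers > 0]).size == 2

    def test_zero_map_no_markers(self):
        assert not find_markers(np.zeros((10, 10)), 7, 0.5).any()

    def test_marker_spacing_enforced(self):
        dm = np.zeros((9, 30))
        dm[4, 5] = dm[4, 9] = 5.0  # two equal peaks 4 px apart
        markers = find_markers(dm, min_distance=7, rel_height=0.5)
        assert np.unique(markers[markers > 0]).size == 1

    @pytest.mark.parametrize("bad", [dict(min_distance=0), dict(rel_height=1.5)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ValueError):
            find_markers(np.ones((4, 4)), **{"min_distance": 7, "rel_height": 0.5, **bad})


class TestWatershedFlood:
    def test_single_marker_floods_whole_component(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:10, 2:10] = True
        markers = np.zeros((12, 12), dtype=np.int32)
        markers[5, 5] = 1
        topo = np.zeros((12, 12), dtype=np.uint8)
        out = watershed_flood(topo, markers, mask)
        assert np.array_equal(out > 0, mask)
        assert set(np.unique(out[mask])) == {1}

    def test_labels_never_cross_components(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask[2:8, 2:8] = True
        mask[2:8, 12:18] = True
        markers = np.zeros((10, 20), dtype=np.int32)
        markers[4, 4] = 1
        markers[4, 14] = 2
        out = watershed_flood(np.zeros((10, 20), np.uint8), markers, mask)
        assert set(np.unique(out[:, 2:8])) == {0, 1}
        assert set(np.unique(out[:, 12:18])) == {0, 2}

    def test_two_basin_ramp_boundary_on_ridge(self):
        # valley at each side, ridge of high gray in the middle column:
        # the label boundary must sit on the ridge
        w = 17
        topo = np.zeros((9, w), dtype=np.uint8)
        for x in range(w):
            topo[:, x] = 10 * abs(x - w // 2)  # high at centre? no: valley at centre
        topo = topo.max() - topo  # ridge at the centre column
        markers = np.zeros((9, w), dtype=np.int32)
        markers[4, 1] = 1
        markers[4, w - 2] = 2
        mask = np.ones((9, w), dtype=bool)
        out = watershed_flood(topo, markers, mask)
        assert np.all(out[:, : w // 2] == 1)
        assert np.all(out[:, w // 2 + 1 :] == 2)

    def test_agrees_with_heap_oracle_on_random_terrain(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            topo = rng.integers(0, 8, (16, 16)).astype(np.uint8)
            mask = rng.random((16, 16)) < 0.9
            markers = np.zeros((16, 16), dtype=np.int32)
            ys, xs = np.nonzero(mask)
            picks = rng.choice(ys.size, size=3, replace=False)
            for lbl, i in enumerate(picks, start=1):
                markers[ys[i], xs[i]] = lbl
            ours = watershed_flood(topo, markers, mask, connectivity=4)
            ref = heap_flood(topo, markers, mask, connectivity=4)
            assert np.array_equal(ours, ref)

    def test_conservation_and_label_bounds(self):
        rng = np.random.default_rng(5)
        mask = rng.random((24, 24)) < 0.7
        topo = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        markers = np.zeros((24, 24), dtype=np.int32)
        ys, xs = np.nonzero(mask)
        for lbl, i in enumerate(rng.choice(ys.size, 4, replace=False), start=1):
            markers[ys[i], xs[i]] = lbl
        out = watershed_flood(topo, markers, mask)
        assert not out[~mask].any()  # flood stays inside the mask
        labelled = out > 0
        assert set(np.unique(out[labelled])) <= {1, 2, 3, 4}

    def test_label_permutation_equivariance(self):
        mask = np.ones((12, 12), dtype=bool)
        topo = np.zeros((12, 12), dtype=np.uint8)
        markers = np.zeros((12, 12), dtype=np.int32)
        markers[2, 2], markers[9, 9] = 1, 2
        swapped = np.zeros_like(markers)
        swapped[2, 2], swapped[9, 9] = 2, 1
        out = watershed_flood(topo, markers, mask)
        out_swapped = watershed_flood(topo, swapped, mask)
        assert np.array_equal(out == 1, out_swapped == 2)
        assert np.array_equal(out == 2, out_swapped == 1)

    def test_empty_markers_all_zero(self):
        out = watershed_flood(
            np.zeros((6, 6), np.uint8), np.zeros((6, 6), np.int32)
        )
        assert not out.any()


class TestCountLeaves:
    def test_single_disc_counts_one(self, config):
        img = np.full((64, 64, 3), 60, dtype=np.uint8)
        yy, xx = np.mgrid[:64, :64]
        img[(xx - 32) ** 2 + (yy - 32) ** 2 <= 14**2] = 230
        box = BBox(10, 10, 54, 54)
        assert count_leaves(img, box, config).count == 1

    def test_empty_box_counts_zero(self, config):
        img = np.full((40, 40, 3), 60, dtype=np.uint8)
        img[0, 0] = 230  # some contrast so Otsu is defined
        assert count_leaves(img, BBox(10, 10, 30, 30), config).count == 0

    @pytest.mark.parametrize("k", [5, 6, 8])
    def test_separated_rosette_counts_exactly(self, config, k):
        scene = generate_scene(
            SceneSpec(
                height=192, width=192, n_plants=1, leaves_per_plant=k,
                plant_spacing=1, seed=31 + k,
            )
        )
        box = scene.truth.boxes[0]
        result = count_leaves(scene.image, box, config)
        assert result.count == k

    def test_region_areas_cover_mask(self, config):
        scene = generate_scene(
            SceneSpec(height=192, width=192, n_plants=1, leaves_per_plant=6,
                      plant_spacing=1, seed=2)
        )
        box = scene.truth.boxes[0]
        result = count_leaves(scene.image, box, config)
        sl = (slice(box.y_min, box.y_max + 1), slice(box.x_min, box.x_max + 1))
        truth_crop = scene.truth.mask[sl]
        covered = (result.labels > 0) & truth_crop
        assert covered.sum() / truth_crop.sum() > 0.95
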