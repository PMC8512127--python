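"""Marker-controlled watershed leaf counting.

Within each detected plant box the foreground mask is distance-
transformed: every leaf pixel gets its Euclidean distance to the
nearest background pixel, so leaf centres become local maxima of the
distance map.  Those maxima seed a watershed flood over the
complemented (inverted) distance map, whose catchment basins are the
individual leaves; ridges between basins fall on the thin necks where
leaves touch.

The flood is scheduled by an ordered queue: one FIFO queue per gray
level of the flooding topography, always serviced from the lowest
occupied level.  Marker boundary pixels enter at their own gray level;
popping a pixel labels its unlabeled neighbours and enqueues them at
their gray level, until all queues drain.  Restricting the flood to the
foreground mask keeps basins inside the plant.

The leaf count LF of a plant is the number of basins whose area reaches
``leaf_area_min``; smaller fragments (over-segmentation noise) are
absorbed into their largest neighbouring basin.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import imaging, thresholding
from .config import PipelineConfig
from .detection import BBox

__all__ = [
    "LeafCount",
    "euclidean_distance_transform",
    "find_markers",
    "watershed_flood",
    "count_leaves",
]


@dataclass
class LeafCount:
    """Watershed result for one plant box."""

    plant_box: BBox
    count: int  # LF, the number of counted leaves
    labels: np.ndarray  # flooded label image, box-sized


def euclidean_distance_transform(mask: np.ndarray) -> np.ndarray:
    """Distance from each foreground pixel to the nearest background pixel.

    Background pixels map to 0.  A mask with no background at all is
    measured against a virtual background border one pixel outside the
    frame, so the transform stays finite.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.float64)
    if mask.all():
        padded = np.pad(mask, 1, mode="constant", constant_values=False)
        return ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    return ndi.distance_transform_edt(mask)


def find_markers(
    dm: np.ndarray, min_distance: int = 7, rel_height: float = 0.5
) -> np.ndarray:
    """Label the prominent local maxima of a distance map as seeds.

    A pixel is a candidate when it attains the maximum of its
    (2*min_distance+1)-square neighbourhood and reaches at least
    ``rel_height`` of the global maximum.  Connected candidate plateaus
    collapse to a single marker, and of any two surviving markers whose
    centroids lie closer than ``min_distance`` only the higher one is
    kept (ties: the more top-left one).  On a lattice, equal-valued
    plateau fragments of one ridge are common, so the spacing rule is
    what keeps one marker per leaf.  Returns an int32 label image
    (0 = no marker).
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    if not 0 < rel_height <= 1:
        raise ValueError("rel_height must be in (0, 1]")
    dm = np.asarray(dm, dtype=np.float64)
    peak = dm.max()
    if peak <= 0:
        return np.zeros(dm.shape, dtype=np.int32)
    size = 2 * min_distance + 1
    is_max = (dm == ndi.maximum_filter(dm, size=size)) & (dm >= rel_height * peak)
    plateaus, n = ndi.label(is_max, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros(dm.shape, dtype=np.int32)
    idx = np.arange(1, n + 1)
    heights = ndi.maximum(dm, plateaus, idx)
    centroids = ndi.center_of_mass(is_max, plateaus, idx)
    order = sorted(range(n), key=lambda i: (-heights[i], centroids[i]))
    kept: list[int] = []
    for i in order:
        cy, cx = centroids[i]
        if all(
            math.hypot(cy - centroids[j][0], cx - centroids[j][1]) >= min_distance
            for j in kept
        ):
            kept.append(i)
    markers = np.zeros(dm.shape, dtype=np.int32)
    for new_label, i in enumerate(sorted(kept), start=1):
        markers[plateaus == i + 1] = new_label
    return markers


_NEIGHBORS_4 = ((-1, 0), (0, 1), (1, 0), (0, -1))  # N, E, S, W
_NEIGHBORS_8 = ((-1, 0), (0, 1), (1, 0), (0, -1), (-1, -1), (-1, 1), (1, 1), (1, -1))


def watershed_flood(
    topo: np.ndarray,
    markers: np.ndarray,
    mask: np.ndarray | None = None,
    connectivity: int = 4,
) -> np.ndarray:
    """Flood a gray-level topography from labelled markers.

    Parameters
    ----------
    topo : (H, W) uint8-range gray image; level 0 floods first.
    markers : int label image, 0 = unlabeled; labels are the sources.
    mask : optional boolean; flooding never leaves the True region.
    connectivity : 4 (default, keeps ridge lines thin) or 8.

    Returns
    -------
    int32 label image: every reachable mask pixel carries the label of
    the marker that flooded it first; 0 remains on unreached pixels.

    The scheduler is a bank of FIFO queues, one per gray level, always
    serviced from the lowest occupied level.  Marker boundary pixels are
    enqueued at their own gray level during initialisation; each popped
    pixel labels and enqueues its unlabeled neighbours at their gray
    level.  FIFO order within a level and fixed N, E, S, W(, diagonals)
    neighbour order make the flood deterministic.
    """
    topo = np.asarray(topo)
    if topo.ndim != 2:
        raise ValueError("topography must be 2-D")
    levels = int(topo.max()) + 1 if topo.size else 1
    g = np.asarray(markers, dtype=np.int32).copy()
    if g.shape != topo.shape:
        raise ValueError("markers shape must match topography")
    if mask is None:
        mask = np.ones(topo.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        g[~mask] = 0
    if not g.any():
        return np.zeros(topo.shape, dtype=np.int32)
    neighbors = _NEIGHBORS_4 if connectivity == 4 else _NEIGHBORS_8
    h, w = topo.shape

    queues: list[deque[tuple[int, int]]] = [deque() for _ in range(levels)]
    # initialisation: boundary points of the markers enter at their level
    ys, xs = np.nonzero(g)
    for y, x in zip(ys.tolist(), xs.tolist()):
        lbl = g[y, x]
        for dy, dx in neighbors:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and g[ny, nx] != lbl:
                queues[topo[y, x]].append((y, x))
                break

    level = 0
    while level < levels:
        q = queues[level]
        if not q:
            level += 1
            continue
        y, x = q.popleft()
        lbl = g[y, x]
        for dy, dx in neighbors:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and g[ny, nx] == 0:
                g[ny, nx] = lbl
                lv = int(topo[ny, nx])
                queues[lv].append((ny, nx))
                if lv < level:  # water cannot flow uphill backwards;
                    level = lv  # lower levels may refill while flooding
    return g


def _quantize_complement(dm: np.ndarray) -> np.ndarray:
    """Flooding topography: max(dm) - dm scaled to the 0..255 range."""
    peak = dm.max()
    if peak <= 0:
        return np.zeros(dm.shape, dtype=np.uint8)
    inv = (peak - dm) * (255.0 / peak)
    return np.floor(inv + 0.5).astype(np.uint8)


def _absorb_small_regions(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Merge regions smaller than min_area into their largest neighbour."""
    labels = labels.copy()
    while True:
        ids, areas = np.unique(labels[labels > 0], return_counts=True)
        small = ids[areas < min_area]
        if small.size == 0 or ids.size <= 1:
            break
        area_of = dict(zip(ids.tolist(), areas.tolist()))
        merged_any = False
        for lbl in small.tolist():
            region = labels == lbl
            ring = ndi.binary_dilation(region, np.ones((3, 3), dtype=bool)) & ~region
            neighbor_ids = np.unique(labels[ring])
            neighbor_ids = neighbor_ids[neighbor_ids > 0]
            if neighbor_ids.size == 0:
                labels[region] = 0  # isolated fragment: not a leaf
                merged_any = True
                continue
            target = max(neighbor_ids.tolist(), key=lambda i: area_of.get(i, 0))
            labels[region] = target
            merged_any = True
        if not merged_any:
            break
    return labels


def count_leaves(
    img: np.ndarray,
    plant: BBox,
    config: PipelineConfig | None = None,
    mask: np.ndarray | None = None,
) -> LeafCount:
    """Count the leaves inside one plant bounding box.

    ``mask`` may carry the frame-level foreground mask from the
    detection stage (same resolution as ``img`` after preprocessing);
    without it the crop is re-thresholded with ``count_n_classes``-level
    Otsu, brightest class foreground.  The crop's mask is distance-
    transformed, seeded at its maxima and flooded; LF is the number of
    surviving basins.
    """
    config = config or PipelineConfig()
    h = img.shape[0] if mask is None else mask.shape[0]
    w = img.shape[1] if mask is None else mask.shape[1]
    if not (0 <= plant.x_min <= plant.x_max < w and 0 <= plant.y_min <= plant.y_max < h):
        raise ValueError(f"plant box {plant} outside {h}x{w} frame")
    sl = (slice(plant.y_min, plant.y_max + 1), slice(plant.x_min, plant.x_max + 1))
    if mask is not None:
        crop_mask = np.asarray(mask, dtype=bool)[sl]
    else:
        # threshold the whole frame, not the crop: the crop histogram is
        # leaf-dominated and multilevel Otsu would split the leaf mode
        gray = imaging.to_gray(img, config.channel_mode)
        hist = imaging.histogram(gray)
        ts = None
        for n_classes in range(config.count_n_classes, 1, -1):
            try:
                ts = thresholding.otsu_thresholds(hist, n_classes)
                break
            except thresholding.DegenerateHistogramError:
                continue  # frame too flat for this many classes
        if ts is None:
            return LeafCount(plant, 0, np.zeros((plant.height, plant.width), np.int32))
        crop_mask = thresholding.foreground_mask(gray, ts, "top_class")[sl]
    if not crop_mask.any():
        return LeafCount(plant, 0, np.zeros(crop_mask.shape, dtype=np.int32))

    dm = euclidean_distance_transform(crop_mask)
    markers = find_markers(dm, config.marker_min_distance, config.marker_rel_height)
    if not markers.any():
        return LeafCount(plant, 0, np.zeros(crop_mask.shape, dtype=np.int32))
    topo = _quantize_complement(dm)
    flooded = watershed_flood(topo, markers, crop_mask, config.flood_connectivity)
    flooded = _absorb_small_regions(flooded, config.leaf_area_min)
    count = int(np.unique(flooded[flooded > 0]).size)
    return LeafCount(plant, count, flooded)
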