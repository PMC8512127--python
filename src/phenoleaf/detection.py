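"""Plant bounding-box detection.

A thresholded foreground mask is turned into per-plant boxes in four
steps: connected-component labelling, area/shape filtering (shape
similarity = log-Hu-moment distance to a reference template), pairwise
box merging under the corner-proximity rules, and — for the combined
methods — fusion of the boxes found by two different Otsu class counts.

Two boxes a and b are merged when any of these four conjunctions holds
(tol = 30 px at the 640x512 working resolution):

    |ya_min - yb_min| < tol  AND  |xa_min - xb_min| < tol
    |ya_min - yb_min| < tol  AND  |xa_max - xb_max| < tol
    |ya_max - yb_max| < tol  AND  |xa_min - xb_min| < tol
    |ya_max - yb_max| < tol  AND  |xa_max - xb_max| < tol

i.e. the boxes share (within tolerance) a horizontal edge position and a
vertical edge position.  Of a merged pair, the box whose shape is more
similar to the reference (smaller Hu distance) survives with its own
extent.  Merging repeats to a fixed point, so chains collapse.

Method variants:

    M1 / M2 / M3 — bi- / three- / four-level Otsu alone
    M4 = M1 + M2,  M5 = M1 + M3,  M6 = M2 + M3 (box fusion)
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from . import imaging, thresholding
from .config import PipelineConfig

__all__ = [
    "BBox",
    "Component",
    "Detection",
    "connected_components",
    "filter_objects",
    "hu_distance",
    "disc_template_hu",
    "rosette_template_hu",
    "should_merge",
    "merge_detections",
    "detect_leaves",
    "METHOD_CLASSES",
]

logger = logging.getLogger(__name__)

# class counts run per method; pairs are fused with merge_detections
METHOD_CLASSES: dict[str, tuple[int, ...]] = {
    "M1": (2,),
    "M2": (3,),
    "M3": (4,),
    "M4": (2, 3),
    "M5": (2, 4),
    "M6": (3, 4),
}


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box with inclusive integer pixel coordinates."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    source_method: str = ""
    shape_similarity: float = math.inf  # lower = more similar to reference

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(f"empty box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1

    @property
    def area(self) -> int:
        return self.width * self.height

    def iou(self, other: "BBox") -> float:
        ix = min(self.x_max, other.x_max) - max(self.x_min, other.x_min) + 1
        iy = min(self.y_max, other.y_max) - max(self.y_min, other.y_min) + 1
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        return inter / (self.area + other.area - inter)


@dataclass
class Component:
    """A labelled foreground blob with its box and shape features.

    Hu moments are computed on first access: a noisy frame can carry
    tens of thousands of speckle components, and only the few that pass
    the area filter ever need shape features.
    """

    bbox: BBox
    area: int
    mask: np.ndarray  # boolean crop, bbox-aligned
    _hu: tuple[float, ...] | None = None

    @property
    def hu_moments(self) -> tuple[float, ...]:
        if self._hu is None:
            self._hu = _hu_of_mask(self.mask)
        return self._hu


@dataclass
class Detection:
    """Final box list for one frame."""

    boxes: list[BBox]
    method: str
    mask: np.ndarray | None = None


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=int)
    if connectivity == 4:
        return ndi.generate_binary_structure(2, 1)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _hu_of_mask(mask: np.ndarray) -> tuple[float, ...]:
    m = measure.moments(mask.astype(np.float64))
    cr, cc = m[1, 0] / m[0, 0], m[0, 1] / m[0, 0]
    mu = measure.moments_central(mask.astype(np.float64), center=(cr, cc))
    nu = measure.moments_normalized(mu)
    return tuple(float(h) for h in measure.moments_hu(nu))


def hu_distance(hu_a: tuple[float, ...], hu_b: tuple[float, ...]) -> float:
    """Log-magnitude Hu comparison: sum |1/slog(h_a) - 1/slog(h_b)|.

    slog(h) = sign(h) * log10(|h|).  Working on reciprocals of the
    signed log magnitudes keeps near-vanishing high-order moments from
    dominating the distance (they contribute terms near zero), which is
    the standard stabilised form of Hu-moment shape matching.
    """

    def inv_slog(h: float) -> float:
        if h == 0:
            return 0.0
        m = math.copysign(math.log10(max(abs(h), 1e-30)), h)
        return 1.0 / m if m != 0 else 0.0

    return float(sum(abs(inv_slog(a) - inv_slog(b)) for a, b in zip(hu_a, hu_b)))


@functools.lru_cache(maxsize=8)
def disc_template_hu(radius: int = 32) -> tuple[float, ...]:
    """Hu moments of a filled disc reference shape."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return _hu_of_mask(xx**2 + yy**2 <= radius**2)


@functools.lru_cache(maxsize=8)
def rosette_template_hu(n_blades: int = 6, radius: int = 40) -> tuple[float, ...]:
    """Hu moments of an idealised rosette: ``n_blades`` elliptical
    blades radiating from a core — the default shape reference.

    A top-view rosette is a star, not a disc: against real plant blobs
    the star template separates plants (distance well under 1) from bag
    rims and detached single blades (distance well above 1), which a
    disc reference does not.
    """
    side = 2 * radius + 11
    c = (side - 1) / 2
    d, a = 0.6 * radius, 0.3 * radius
    b = max(min(0.8 * d * math.sin(math.pi / n_blades), 0.75 * a), 3.0)
    yy, xx = np.mgrid[:side, :side]
    mask = np.zeros((side, side), dtype=bool)
    for i in range(n_blades):
        theta = 2 * math.pi * i / n_blades
        lx, ly = c + d * math.cos(theta), c + d * math.sin(theta)
        dx, dy = xx - lx, yy - ly
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        mask |= (np.abs(v) <= 0.75) & (u >= -d) & (u <= 0)  # petiole to the core
    return _hu_of_mask(mask)


def connected_components(mask: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Label foreground blobs; each gets a tight box and shape features."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_structure(connectivity))
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    out: list[Component] = []
    for i, sl in enumerate(ndi.find_objects(labels), start=1):
        bbox = BBox(
            x_min=sl[1].start,
            y_min=sl[0].start,
            x_max=sl[1].stop - 1,
            y_max=sl[0].stop - 1,
        )
        out.append(Component(bbox=bbox, area=int(areas[i]), mask=labels[sl] == i))
    return out


def filter_objects(
    components: list[Component],
    area_min: float,
    area_max: float,
    hu_ref: tuple[float, ...] | list[tuple[float, ...]],
    hu_tol: float,
) -> list[Component]:
    """Keep blobs with area in [area_min, area_max] and shape distance
    to the reference <= hu_tol; record the distance on the box.

    ``hu_ref`` may be a single Hu vector or a list of them (e.g. one
    rosette template per plausible leaf count); a blob is scored by its
    closest reference.
    """
    if area_min >= area_max:
        raise ValueError("area_min must be < area_max")
    refs = hu_ref if isinstance(hu_ref, list) else [hu_ref]
    kept = []
    for comp in components:
        if not area_min <= comp.area <= area_max:
            continue
        d = min(hu_distance(comp.hu_moments, ref) for ref in refs)
        if d > hu_tol:
            continue
        kept.append(
            replace(comp, bbox=replace(comp.bbox, shape_similarity=d))
        )
    return kept


def default_shape_references() -> list[tuple[float, ...]]:
    """Rosette templates spanning the plausible leaf-count range."""
    return [rosette_template_hu(k) for k in (5, 6, 7, 8)]


def should_merge(a: BBox, b: BBox, tol: int = 30) -> bool:
    """True when the two boxes share a top-or-bottom edge position and a
    left-or-right edge position within ``tol`` pixels."""
    dy_min = abs(a.y_min - b.y_min) < tol
    dy_max = abs(a.y_max - b.y_max) < tol
    dx_min = abs(a.x_min - b.x_min) < tol
    dx_max = abs(a.x_max - b.x_max) < tol
    return (dy_min or dy_max) and (dx_min or dx_max)


def _merge_boxes(boxes: list[BBox], tol: int) -> list[BBox]:
    """Collapse merge chains to their best-shaped box, to a fixed point.

    Mergeability is treated transitively: boxes are clustered by the
    connected components of the pairwise merge relation and each
    cluster keeps its lowest-distance (best-shaped) box, with
    coordinates as the deterministic tie-break.  Winning boxes may form
    new mergeable pairs, so clustering repeats until none remain.
    """
    boxes = sorted(
        boxes, key=lambda b: (b.shape_similarity, b.x_min, b.y_min, b.x_max, b.y_max)
    )
    while True:
        n = len(boxes)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        merged_any = False
        for i in range(n):
            for j in range(i + 1, n):
                if should_merge(boxes[i], boxes[j], tol):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
                    merged_any = True
        if not merged_any:
            return boxes
        # similarity-sorted order: the first box of a cluster is its best
        boxes = [b for i, b in enumerate(boxes) if find(i) == i]


def merge_detections(primary: Detection, secondary: Detection, tol: int = 30) -> Detection:
    """Fuse two box lists from the same frame.

    Boxes without a merge partner in the other list are copied through;
    of each mergeable pair the box with the smaller Hu distance to the
    reference survives.  Fusion runs to a fixed point, so merge chains
    across both lists collapse to a single best box.
    """
    method = primary.method if primary.method == secondary.method else (
        f"{primary.method}+{secondary.method}"
    )
    # the secondary (finer, multilevel) mask isolates leaves best and is
    # what the counting stage floods; the bi-level mask swallows the bag
    mask = secondary.mask if secondary.mask is not None else primary.mask
    return Detection(
        boxes=_merge_boxes(list(primary.boxes) + list(secondary.boxes), tol),
        method=method,
        mask=mask,
    )


def _detect_single(
    gray: np.ndarray, n_classes: int, config: PipelineConfig, tag: str
) -> Detection:
    n_px = gray.size
    area_min = config.area_min_frac * n_px
    area_max = config.area_max_frac * n_px
    try:
        ts = thresholding.otsu_thresholds(imaging.histogram(gray), n_classes)
    except thresholding.DegenerateHistogramError:
        logger.warning("degenerate image (too few gray levels) for %s", tag)
        return Detection(boxes=[], method=tag, mask=np.zeros_like(gray, dtype=bool))
    mask = thresholding.foreground_mask(
        gray, ts, config.fg_rule, area_min=area_min, area_max=area_max
    )
    comps = connected_components(mask, config.connectivity)
    comps = filter_objects(
        comps, area_min, area_max, default_shape_references(), config.hu_tol
    )
    boxes = [replace(c.bbox, source_method=tag) for c in comps]
    boxes = _merge_boxes(boxes, config.merge_tol_px)
    return Detection(boxes=boxes, method=tag, mask=mask)


def preprocess(img: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Resize (optional) -> sharpen -> grayscale, per the config."""
    if config.resize:
        img = imaging.resize_half(img, config.interpolation)
    img = imaging.sharpen(img, config.border_policy)
    return imaging.to_gray(img, config.channel_mode)


def detect_leaves(
    img: np.ndarray, method: str, config: PipelineConfig | None = None
) -> Detection:
    """Run the full static detection chain for one frame.

    resize -> sharpen -> grayscale -> Otsu -> foreground mask ->
    components -> area/shape filter -> box merge; combined methods fuse
    the box lists of their two constituent class counts.
    """
    config = config or PipelineConfig()
    base = method[:2]  # M4_SQ detects like M4
    if base not in METHOD_CLASSES:
        raise ValueError(f"unknown method {method!r}")
    gray = preprocess(img, config)
    runs = [
        _detect_single(gray, m, config, f"M{m - 1}") for m in METHOD_CLASSES[base]
    ]
    if len(runs) == 1:
        det = runs[0]
    else:
        det = merge_detections(runs[0], runs[1], config.merge_tol_px)
    det.method = method
    return det
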