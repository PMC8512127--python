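"""Synthetic greenhouse scenes with exact ground truth.

The generator emulates top-view near-infrared frames of potted rosette
plants: bright leaves (~230) on a poly-bag disc (~120) over darker soil
(~60).  Night frames add only low-variance Gaussian noise, so their
gray histograms are bimodal and a single Otsu threshold separates
leaves cleanly.  Day frames add a linear illumination gradient and
rectangular cast shadows over the plants, producing the multi-modal
histograms and broken-up foreground that motivate multilevel
thresholding and the night-trusting sequence strategy.

Each plant is a rosette of ``k`` elliptical leaves radiating from a
centre.  The ``overlap`` knob interpolates between well-separated
leaves (petiole gaps, narrow blades — every leaf is its own blob) and
heavily overlapping leaves (blades touch at the centre and sideways —
the undercounting regime of the watershed counter).

Rendering is deterministic: the same spec (including its seed) yields
byte-identical images.  Ground truth (tight leaf-pixel bounding box,
leaf count and foreground mask per frame) is recorded from the rendered
geometry, not re-measured from pixels downstream.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace

import numpy as np

from .detection import BBox
from .evaluation import GroundTruthScene
from .sequence import classify_day_night

__all__ = [
    "SceneSpecError",
    "SceneSpec",
    "SyntheticScene",
    "generate_scene",
    "generate_sequence",
]

# near-infrared palette (gray rendered into all three RGB channels)
LEAF_INTENSITY = 230
BAG_INTENSITY = 120
SOIL_INTENSITY = 60


class SceneSpecError(ValueError):
    """Raised when a scene specification cannot be rendered."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered scene.

    ``leaves_per_plant`` is either one integer for all plants or a
    sequence with one entry per plant.  ``leaf_radius`` bounds the
    rosette radius (leaf tip distance from the core) in pixels.
    ``overlap`` in [0, 1] moves from fully separated leaves to heavily
    overlapping ones.  ``shadow_boxes`` overrides the automatic daytime
    shadow placement with explicit ``(x0, y0, x1, y1, offset)`` tuples.
    """

    height: int = 512
    width: int = 640
    n_plants: int = 4
    leaves_per_plant: int | tuple[int, ...] = 6
    leaf_radius: tuple[int, int] = (34, 48)
    plant_spacing: int = 150
    illumination: str = "night_uniform"
    shadow_boxes: tuple[tuple[int, int, int, int, int], ...] | None = None
    n_shadows: int = 2
    shadow_offset: int = -90
    gradient_amplitude: int = 60
    noise_sd: float = 3.0
    overlap: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.illumination not in {"night_uniform", "day_gradient"}:
            raise SceneSpecError(f"unknown illumination {self.illumination!r}")
        if not 0 <= self.overlap <= 1:
            raise SceneSpecError("overlap must be in [0, 1]")
        if self.n_plants < 1:
            raise SceneSpecError("need at least one plant")
        if any(k < 1 for k in self.leaf_counts()):
            raise SceneSpecError("leaves_per_plant entries must be >= 1")

    def leaf_counts(self) -> tuple[int, ...]:
        if isinstance(self.leaves_per_plant, int):
            return (self.leaves_per_plant,) * self.n_plants
        if len(self.leaves_per_plant) != self.n_plants:
            raise SceneSpecError("leaves_per_plant length must equal n_plants")
        return tuple(self.leaves_per_plant)


@dataclass
class SyntheticScene:
    """A rendered frame with its exact annotation."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: GroundTruthScene
    timestamp: dt.datetime | None = None


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Place plant centres greedily on a shuffled lattice.

    A lattice of candidate positions (16 px pitch, inside the border
    margin) is shuffled and consumed greedily under the mutual-spacing
    constraint, then jittered by a few pixels.  Unlike rejection
    sampling this succeeds deterministically whenever a greedy packing
    exists, so every seed yields a valid layout or a clear error.
    """
    margin = spec.leaf_radius[1] + 12
    xs = np.arange(margin, spec.width - margin, 16)
    ys = np.arange(margin, spec.height - margin, 16)
    if xs.size == 0 or ys.size == 0:
        raise SceneSpecError("frame too small for the requested leaf radius")
    lattice = [(int(x), int(y)) for x in xs for y in ys]
    order = rng.permutation(len(lattice))
    centers: list[tuple[int, int]] = []
    for idx in order:
        cx, cy = lattice[idx]
        if all(
            math.hypot(cx - ox, cy - oy) >= spec.plant_spacing for ox, oy in centers
        ):
            jx = int(rng.integers(-5, 6))
            jy = int(rng.integers(-5, 6))
            centers.append(
                (
                    int(np.clip(cx + jx, margin, spec.width - margin - 1)),
                    int(np.clip(cy + jy, margin, spec.height - margin - 1)),
                )
            )
            if len(centers) == spec.n_plants:
                return centers
    raise SceneSpecError(
        f"cannot place {spec.n_plants} plants with spacing "
        f"{spec.plant_spacing} in a {spec.width}x{spec.height} frame"
    )


def _disc_mask(h: int, w: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _ellipse_mask(
    h: int, w: int, cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Filled rotated ellipse: semi-axis ``a`` along direction ``theta``."""
    yy, xx = np.mgrid[:h, :w]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _petiole_mask(
    h: int, w: int, cx: float, cy: float, length: float, theta: float, half_width: float
) -> np.ndarray:
    """Thin rotated bar from (cx, cy) outward along ``theta``."""
    yy, xx = np.mgrid[:h, :w]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (np.abs(v) <= half_width) & (u >= 0) & (u <= length)


def _render_plant(
    spec: SceneSpec, rng: np.random.Generator, cx: int, cy: int, k: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render one rosette; returns (leaf mask, bag mask, rosette radius).

    Each leaf is a roundish elliptical blade on a thin petiole running
    to the rosette centre, so the plant is one connected blob whose
    central junction stays much thinner than any blade — each blade
    then carries a single clean distance-transform maximum.  With
    ``overlap`` -> 1 the blades slide inward and widen until adjacent
    blades fuse, which is the regime where touching leaves defeat
    marker-based counting.
    """
    h, w = spec.height, spec.width
    r = float(rng.uniform(*spec.leaf_radius))
    d = (0.60 - 0.15 * spec.overlap) * r  # blade-centre distance from core
    a = 0.30 * r  # blade half-length (radial)
    sep_limit = d * math.sin(math.pi / k)  # adjacent blades just touch at 1.0
    b = (0.8 + 0.6 * spec.overlap) * sep_limit
    b = max(min(b, 0.75 * a), 3.0)
    leaves = np.zeros((h, w), dtype=bool)
    base = float(rng.uniform(0, 2 * math.pi))
    for i in range(k):
        theta = base + 2 * math.pi * i / k + float(rng.normal(0, 0.04))
        lx = cx + d * math.cos(theta)
        ly = cy + d * math.sin(theta)
        leaves |= _ellipse_mask(h, w, lx, ly, a, b, theta)
        leaves |= _petiole_mask(h, w, cx, cy, d, theta, 0.75)
    # the poly-bag rim shows as a bright ring around the rosette
    bag = _disc_mask(h, w, cx, cy, 1.3 * r) & ~_disc_mask(h, w, cx, cy, 1.1 * r)
    return leaves, bag, r


def _auto_shadows(
    spec: SceneSpec,
    rng: np.random.Generator,
    centers: list[tuple[int, int]],
    radii: list[float],
) -> list[tuple[int, int, int, int, int]]:
    """Cast rectangular shadows preferentially across plant rosettes."""
    boxes = []
    order = rng.permutation(len(centers))
    for idx in order[: spec.n_shadows]:
        cx, cy = centers[idx]
        r = radii[idx]
        sw, sh = int(2.4 * r), int(1.0 * r)
        x0 = int(cx - sw // 2 + rng.integers(-10, 11))
        y0 = int(cy + rng.integers(-int(0.2 * r), int(0.2 * r) + 1))
        boxes.append(
            (
                max(0, x0),
                max(0, y0),
                min(spec.width - 1, x0 + sw),
                min(spec.height - 1, y0 + sh),
                spec.shadow_offset,
            )
        )
    return boxes


def _render(
    spec: SceneSpec,
    rng_layout: np.random.Generator,
    rng_effects: np.random.Generator,
) -> SyntheticScene:
    """Render a frame: layout draws from one stream, noise/shadows from
    another, so a sequence can lock geometry while varying conditions."""
    h, w = spec.height, spec.width
    centers = _place_centers(spec, rng_layout)
    counts = spec.leaf_counts()

    canvas = np.full((h, w), float(SOIL_INTENSITY))
    truth_mask = np.zeros((h, w), dtype=bool)
    radii: list[float] = []
    plant_masks: list[np.ndarray] = []
    for (cx, cy), k in zip(centers, counts):
        leaves, bag, r = _render_plant(spec, rng_layout, cx, cy, k)
        radii.append(r)
        plant_masks.append(leaves)
        canvas[bag] = BAG_INTENSITY
        truth_mask |= leaves

    truth_boxes: list[BBox] = []
    for leaves in plant_masks:  # leaves paint over every bag
        canvas[leaves] = LEAF_INTENSITY
        ys, xs = np.nonzero(leaves)
        truth_boxes.append(
            BBox(
                x_min=int(xs.min()),
                y_min=int(ys.min()),
                x_max=int(xs.max()),
                y_max=int(ys.max()),
            )
        )

    if spec.illumination == "day_gradient":
        canvas = canvas + np.linspace(0.0, spec.gradient_amplitude, w)[None, :]
        shadows = (
            list(spec.shadow_boxes)
            if spec.shadow_boxes is not None
            else _auto_shadows(spec, rng_effects, centers, radii)
        )
        for x0, y0, x1, y1, offset in shadows:
            canvas[y0 : y1 + 1, x0 : x1 + 1] += offset
    if spec.noise_sd > 0:
        canvas = canvas + rng_effects.normal(0.0, spec.noise_sd, size=(h, w))

    gray = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    image = np.repeat(gray[..., None], 3, axis=2)
    truth = GroundTruthScene(boxes=truth_boxes, leaf_counts=list(counts), mask=truth_mask)
    return SyntheticScene(image=image, truth=truth)


def generate_scene(
    spec: SceneSpec, timestamp: dt.datetime | None = None
) -> SyntheticScene:
    """Render one frame and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    scene = _render(spec, rng, rng)
    scene.timestamp = timestamp
    return scene


def generate_sequence(
    spec: SceneSpec,
    n_frames: int,
    interval_minutes: int = 10,
    start_time: dt.datetime = dt.datetime(2021, 6, 1, 0, 0),
    day_start: str = "05:00",
    day_end: str = "18:00",
) -> list[SyntheticScene]:
    """Render a time-lapse with a fixed plant layout.

    Plant placement and leaf geometry are locked by ``spec.seed``; each
    frame draws its own noise and shadow realisation, and its
    illumination mode follows the day/night class of its timestamp.
    """
    if n_frames < 1:
        raise SceneSpecError("n_frames must be >= 1")
    scenes = []
    for i in range(n_frames):
        t = start_time + dt.timedelta(minutes=interval_minutes * i)
        phase = classify_day_night(t, day_start, day_end)
        mode = "day_gradient" if phase == "day" else "night_uniform"
        frame_spec = replace(spec, illumination=mode)
        scene = _render(
            frame_spec,
            np.random.default_rng(spec.seed),
            np.random.default_rng((spec.seed, 7919 + i)),
        )
        scene.timestamp = t
        scenes.append(scene)
    return scenes
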