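"""Temporal (image-sequence) detection strategy.

Greenhouse cameras capture around the clock.  Night frames, lit only by
near-infrared, segment cleanly; day frames suffer illumination gradients
and cast shadows that break up or fabricate foreground blobs.  The
sequence strategy therefore trusts night frames and reuses their boxes
during the day:

* frame 1 — always run static detection and store the boxes (even if it
  is a day frame, there is nothing better to fall back on);
* later day frames — emit the stored boxes unchanged, skipping fresh
  detection entirely (which also saves computation);
* later night frames — run static detection, fuse it with the stored
  boxes, emit the fusion and make it the new store.

Day/night is decided purely from the capture timestamp: daytime is
[05:00, 18:00) by default (start inclusive, end exclusive), both ends
configurable for other sites/seasons.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .detection import BBox, Detection, detect_leaves, merge_detections

__all__ = [
    "TimestampError",
    "TimestampedFrame",
    "classify_day_night",
    "parse_filename_timestamp",
    "process_sequence",
]

# default filename pattern: YYYYMMDD-HHMMSS anywhere in the stem
_TS_RE = re.compile(r"(\d{8})-(\d{6})")


class TimestampError(ValueError):
    """Raised when a capture timestamp cannot be parsed."""


@dataclass
class TimestampedFrame:
    """One capture in a sequence: image, timestamp and position."""

    image: np.ndarray
    capture_time: dt.datetime
    frame_index: int

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")


def _parse_hhmm(value: str) -> dt.time:
    try:
        hours, minutes = value.split(":")
        return dt.time(int(hours), int(minutes))
    except (ValueError, TypeError) as exc:
        raise TimestampError(f"cannot parse time of day {value!r}") from exc


def classify_day_night(
    t: dt.time | dt.datetime,
    day_start: str | dt.time = "05:00",
    day_end: str | dt.time = "18:00",
) -> str:
    """Classify a time of day as ``"day"`` or ``"night"``.

    Day is the half-open window [day_start, day_end): 05:00 is day,
    18:00 is already night.
    """
    if isinstance(t, dt.datetime):
        t = t.time()
    if not isinstance(t, dt.time):
        raise TimestampError(f"cannot classify timestamp {t!r}")
    start = _parse_hhmm(day_start) if isinstance(day_start, str) else day_start
    end = _parse_hhmm(day_end) if isinstance(day_end, str) else day_end
    return "day" if start <= t < end else "night"


def parse_filename_timestamp(name: str | Path) -> dt.datetime:
    """Extract a YYYYMMDD-HHMMSS timestamp from a filename."""
    match = _TS_RE.search(Path(name).stem)
    if match is None:
        raise TimestampError(f"no YYYYMMDD-HHMMSS timestamp in {name!r}")
    try:
        return dt.datetime.strptime("-".join(match.groups()), "%Y%m%d-%H%M%S")
    except ValueError as exc:
        raise TimestampError(f"invalid timestamp in {name!r}: {exc}") from exc


def process_sequence(
    frames: list[TimestampedFrame],
    base_method: str = "M4",
    config: PipelineConfig | None = None,
) -> list[Detection]:
    """Run the image-sequence strategy over time-ordered frames.

    Returns one Detection per frame, tagged ``<base_method>_SQ``.  The
    box store holds the most recent night-derived (or first-frame)
    detection; day frames after the first emit it verbatim, night frames
    fuse with it and refresh it.
    """
    config = config or PipelineConfig()
    base_method = base_method.replace("_SQ", "")
    if base_method not in {"M4", "M5"}:
        raise ValueError(f"sequence strategy supports M4/M5, got {base_method!r}")
    times = [f.capture_time for f in frames]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("frames must be time-ordered")

    tag = f"{base_method}_SQ"
    outputs: list[Detection] = []
    store: list[BBox] | None = None
    for i, frame in enumerate(frames):
        phase = classify_day_night(frame.capture_time, config.day_start, config.day_end)
        if i == 0:
            det = detect_leaves(frame.image, base_method, config)
            store = list(det.boxes)
        elif phase == "day":
            det = Detection(boxes=list(store or []), method=tag)
        else:
            det = detect_leaves(frame.image, base_method, config)
            stored = Detection(boxes=list(store or []), method=tag)
            det = merge_detections(det, stored, config.merge_tol_px)
            store = list(det.boxes)
        det.method = tag
        outputs.append(det)
    return outputs
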