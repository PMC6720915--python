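"""Axis-aligned boxes, circles and the two overlap metrics.

Coordinates are continuous, 0-based, origin at the top-left corner of the
frame, x rightward and y downward.  A box covers the half-open region
``[x0, x1) × [y0, y1)``; two boxes that merely share an edge therefore have
zero intersection area.  Areas are geometric products, not pixel counts —
on integer-aligned boxes the two conventions coincide.

Two overlap metrics are provided:

* :func:`iou` — the standard intersection-over-union ratio used to decide
  whether a detection matches an annotated grain (a match requires
  IoU ≥ 0.5).
* :func:`containment_iou` — IoU modified to return 1.0 whenever one box is
  entirely contained in the other.  Plain IoU can stay below any practical
  suppression threshold when a small nested proposal sits inside a much
  larger one; the containment rule exists so non-maximum suppression removes
  such nested duplicates.  It is used only inside NMS, never for
  detection-to-ground-truth matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Box",
    "Circle",
    "area",
    "intersection_area",
    "iou",
    "containment_iou",
    "circle_to_box",
    "clip_box",
]

#: Relative tolerance for the containment test; absorbs floating-point drift
#: introduced by coordinate scaling without ever firing on genuinely
#: non-nested boxes.
CONTAINMENT_RTOL = 1e-9


@dataclass(frozen=True, slots=True)
class Box:
    """Axis-aligned rectangle ``[x0, x1) × [y0, y1)`` in pixel coordinates."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"degenerate box: ({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x1, self.y1)


@dataclass(frozen=True, slots=True)
class Circle:
    """Circle with center ``(cx, cy)`` and radius ``r`` in pixels."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"circle radius must be positive, got {self.r}")


def area(b: Box) -> float:
    """Geometric area of ``b`` in pixels²."""
    return (b.x1 - b.x0) * (b.y1 - b.y0)


def intersection_area(a: Box, b: Box) -> float:
    """Area of overlap between two boxes; 0.0 when disjoint or edge-touching."""
    w = min(a.x1, b.x1) - max(a.x0, b.x0)
    h = min(a.y1, b.y1) - max(a.y0, b.y0)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


def iou(p: Box, g: Box) -> float:
    """Intersection over union, ``|p∩g| / |p∪g|``, in [0, 1]."""
    inter = intersection_area(p, g)
    if inter == 0.0:
        return 0.0
    union = area(p) + area(g) - inter
    return inter / union


def containment_iou(p: Box, g: Box) -> float:
    """IoU forced to 1.0 when either box is contained in the other.

    The containment test compares the intersection area with each box's own
    area under a relative tolerance, which makes the predicate stable under
    coordinate rescaling.  When neither box contains the other this is
    exactly :func:`iou`.
    """
    inter = intersection_area(p, g)
    if inter == 0.0:
        return 0.0
    if math.isclose(inter, area(p), rel_tol=CONTAINMENT_RTOL) or math.isclose(
        inter, area(g), rel_tol=CONTAINMENT_RTOL
    ):
        return 1.0
    union = area(p) + area(g) - inter
    return inter / union


def circle_to_box(c: Circle) -> Box:
    """Tight axis-aligned bounding box of a circle.

    Coordinates may extend beyond the frame; callers clip separately
    (see :func:`clip_box`).
    """
    return Box(c.cx - c.r, c.cy - c.r, c.cx + c.r, c.cy + c.r)


def clip_box(b: Box, width: float, height: float) -> Optional[Box]:
    """Clip ``b`` to the frame ``[0, width) × [0, height)``.

    Returns ``None`` when the box lies entirely outside the frame (the
    clipped region would be degenerate).
    """
    x0 = max(b.x0, 0.0)
    y0 = max(b.y0, 0.0)
    x1 = min(b.x1, float(width))
    y1 = min(b.y1, float(height))
    if x1 <= x0 or y1 <= y0:
        return None
    return Box(x0, y0, x1, y1)
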