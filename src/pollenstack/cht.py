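"""Classical per-frame grain detector: a gradient-voting circular Hough
transform (CHT).

The detector follows the classical two-stage gradient method.  Sobel edge
pixels whose gradient magnitude exceeds a threshold vote along their
gradient line, in both directions, for every candidate radius; circle
centers are accumulator peaks, and each center's radius is then estimated
from the distance histogram of the edge pixels whose gradient line passes
through it.  Stained pollen grains appear as dark-rimmed spheroids on a
light background, which is exactly the high-contrast circular structure the
transform responds to; bubbles and round debris respond too, which is the
known failure mode of this classical baseline.

Default parameters: median blur 17 px, full-resolution accumulator, minimum
center distance 25 px, gradient threshold 50, accumulator threshold 30,
radius 20–200 px (native 1280×1024 scale; use :meth:`ChtParams.scaled` for
downscaled frames).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import rank

from .geometry import Box, Circle, circle_to_box, clip_box, containment_iou

__all__ = [
    "ChtParams",
    "ScoredProposal",
    "to_grayscale",
    "median_filter",
    "hough_circles",
    "detect_frame",
]

# Gradient-direction alignment required for an edge pixel to support a
# center's radius estimate (cosine of the angle between the gradient and the
# pixel→center direction).  Rim pixels of a circle are radially aligned;
# texture speckle inside a grain is not.
_RADIAL_ALIGNMENT = 0.9


@dataclass(frozen=True, slots=True)
class ChtParams:
    """Configuration of the circular Hough transform detector.

    ``accumulator_scale`` is the ratio of accumulator resolution to image
    resolution (1 = one accumulator cell per pixel).  ``gradient_threshold``
    gates edge pixels on raw aperture-3 Sobel magnitude (the convention of
    the Canny high threshold in the classical implementation).
    ``accumulator_threshold`` is the minimum center-vote evidence (3×3 box
    sum of accumulator cells, since gradient-direction quantization spreads
    one circle's votes over adjacent cells) for a candidate center.
    ``min_support`` is the second-stage validity criterion: the fraction of
    the circumference that must carry radially-aligned edge pixels for a
    candidate to be accepted as a circle — the normalized-accumulator
    acceptance conventional for circular Hough peaks.  Half a rim separates
    genuine grains and bubbles (support near 1) from the open arcs produced
    by defocused or occluded borders.
    """

    median_kernel: int = 17
    accumulator_scale: float = 1.0
    min_center_dist: float = 25.0
    gradient_threshold: float = 50.0
    accumulator_threshold: float = 30.0
    min_radius: float = 20.0
    max_radius: float = 200.0
    min_support: float = 0.5

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError(f"median_kernel must be odd and >= 1, got {self.median_kernel}")
        if not (0 < self.min_radius < self.max_radius):
            raise ValueError(
                f"need 0 < min_radius < max_radius, got {self.min_radius}, {self.max_radius}"
            )
        for name in ("accumulator_scale", "min_center_dist", "gradient_threshold",
                     "accumulator_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.min_support <= 1.0):
            raise ValueError(f"min_support must be in [0, 1], got {self.min_support}")

    def scaled(self, factor: float) -> "ChtParams":
        """Parameters for a frame rescaled by ``factor`` (e.g. 0.5 for
        1280×1024 → 640×512): geometric quantities scale, vote and gradient
        thresholds do not.  The median kernel scales to the nearest odd size."""
        k = max(1, int(round(self.median_kernel * factor)))
        if k % 2 == 0:
            k += 1
        return replace(
            self,
            median_kernel=k,
            min_center_dist=self.min_center_dist * factor,
            min_radius=self.min_radius * factor,
            max_radius=self.max_radius * factor,
        )


@dataclass(frozen=True, slots=True)
class ScoredProposal:
    """A detection proposal: box, confidence in [0, 1], and the focal-plane
    index it came from.  The currency between detector, fusion and
    evaluation."""

    box: Box
    score: float
    frame_index: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to single-channel uint8 via luma weights
    (0.299 R + 0.587 G + 0.114 B)."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB frame, got shape {frame.shape}")
    weights = np.array([0.299, 0.587, 0.114])
    gray = frame.astype(np.float64) @ weights
    return np.rint(gray).clip(0, 255).astype(np.uint8)


def median_filter(gray: np.ndarray, kernel: int) -> np.ndarray:
    """Median-blur a uint8 grayscale raster with a ``kernel×kernel`` window,
    replicating edges at the borders."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale raster, got shape {gray.shape}")
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel >= min(gray.shape):
        raise ValueError(f"kernel {kernel} too large for image {gray.shape}")
    if kernel == 1:
        return gray.copy()
    pad = kernel // 2
    padded = np.pad(gray.astype(np.uint8), pad, mode="edge")
    out = rank.median(padded, footprint=np.ones((kernel, kernel), dtype=bool))
    return out[pad:-pad, pad:-pad]


def _thin_edges(gx: np.ndarray, gy: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Non-maximum suppression of the gradient magnitude along the gradient
    direction (Canny-style edge thinning).

    Defocused rims are several pixels wide; without thinning each rim casts
    a bundle of parallel vote lines whose chance crossings create spurious
    accumulator peaks.  Thinning reduces every edge to a one-pixel arc.
    """
    h, w = mag.shape
    # Quantize the gradient direction to the 8-neighborhood.
    ang = np.arctan2(gy, gx)
    octant = np.round(ang / (math.pi / 4.0)).astype(int) % 8
    steps = np.array([(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)])
    dx = steps[octant, 0]
    dy = steps[octant, 1]
    yy, xx = np.mgrid[0:h, 0:w]
    yp = np.clip(yy + dy, 0, h - 1)
    xp = np.clip(xx + dx, 0, w - 1)
    ym = np.clip(yy - dy, 0, h - 1)
    xm = np.clip(xx - dx, 0, w - 1)
    return (mag >= mag[yp, xp]) & (mag >= mag[ym, xm])


def _candidate_centers(
    acc: np.ndarray, params: ChtParams
) -> list[tuple[float, float, float]]:
    """Accumulator peaks: cell votes over threshold, 3×3 local maxima,
    greedily thinned to respect ``min_center_dist``.  Returns
    ``(cx, cy, votes)`` in image coordinates, votes descending."""
    evidence = ndi.uniform_filter(acc.astype(np.float64), size=3) * 9.0
    peak = (evidence >= params.accumulator_threshold) & (
        evidence == ndi.maximum_filter(evidence, size=3)
    )
    ys, xs = np.nonzero(peak)
    if len(xs) == 0:
        return []
    votes = evidence[ys, xs]
    # Descending votes; deterministic tie-break on position.
    order = np.lexsort((xs, ys, -votes))
    inv_scale = 1.0 / params.accumulator_scale
    kept: list[tuple[float, float, float]] = []
    for i in order:
        cx = xs[i] * inv_scale
        cy = ys[i] * inv_scale
        if all(
            math.hypot(cx - kx, cy - ky) >= params.min_center_dist
            for kx, ky, _ in kept
        ):
            kept.append((cx, cy, float(votes[i])))
    return kept


def hough_circles(
    gray: np.ndarray, params: ChtParams
) -> list[tuple[Circle, float]]:
    """Detect circles in a grayscale raster by gradient voting.

    Returns ``(circle, support)`` pairs sorted by descending support, where
    support is the fraction of the circle's circumference covered by
    radially-aligned edge pixels (capped at 1).
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale raster, got shape {gray.shape}")
    h, w = gray.shape

    gx = ndi.sobel(gray, axis=1)
    gy = ndi.sobel(gray, axis=0)
    mag = np.hypot(gx, gy)
    edge = (mag >= params.gradient_threshold) & _thin_edges(gx, gy, mag)
    ys, xs = np.nonzero(edge)
    if len(xs) == 0:
        return []
    ux = gx[edge] / mag[edge]
    uy = gy[edge] / mag[edge]

    r_lo = int(math.ceil(params.min_radius))
    r_hi = int(math.floor(params.max_radius))
    radii = np.arange(r_lo, r_hi + 1, dtype=np.float64)

    scale = params.accumulator_scale
    acc_h = max(1, int(round(h * scale)))
    acc_w = max(1, int(round(w * scale)))
    acc = np.zeros(acc_h * acc_w, dtype=np.int64)
    # Vote along the gradient line in both directions (the rim may be darker
    # or brighter than the interior).
    for sign in (1.0, -1.0):
        cx = np.rint((xs[:, None] + sign * ux[:, None] * radii[None, :]) * scale)
        cy = np.rint((ys[:, None] + sign * uy[:, None] * radii[None, :]) * scale)
        ok = (cx >= 0) & (cx < acc_w) & (cy >= 0) & (cy < acc_h)
        flat = (cy[ok] * acc_w + cx[ok]).astype(np.int64)
        acc += np.bincount(flat, minlength=acc_h * acc_w)
    acc = acc.reshape(acc_h, acc_w)

    candidates: list[tuple[Circle, float]] = []
    for cx0, cy0, _votes in _candidate_centers(acc, params):
        fit = _refine_circle(cx0, cy0, xs, ys, ux, uy, params)
        if fit is not None:
            candidates.append(fit)
    candidates.sort(key=lambda cs: (-cs[1], cs[0].cy, cs[0].cx))

    # Sequential evidence consumption: accept circles best-first and remove
    # each accepted circle's rim pixels from the edge set before validating
    # the rest.  A candidate whose support is mostly borrowed from an already
    # accepted rim (e.g. an off-center fit through a tangent arc of a real
    # grain) then falls below min_support and is rejected, while genuinely
    # distinct circles keep their own evidence.
    used = np.zeros(len(xs), dtype=bool)
    kept: list[tuple[Circle, float]] = []
    for circle, _support in candidates:
        avail = ~used
        if not avail.any():
            break
        fit = _refine_circle(
            circle.cx, circle.cy, xs[avail], ys[avail], ux[avail], uy[avail], params
        )
        if fit is None:
            continue
        final, support = fit
        if support < params.min_support:
            continue
        if not (params.min_radius <= final.r <= params.max_radius):
            continue
        if any(
            math.hypot(final.cx - k.cx, final.cy - k.cy) < params.min_center_dist
            for k, _s in kept
        ):
            continue
        kept.append((final, support))
        # Consume the whole annular neighborhood of the accepted rim: a dark
        # rim band has an outer and an inner edge, and both belong to the
        # same grain border.
        dx = xs - final.cx
        dy = ys - final.cy
        dist = np.hypot(dx, dy)
        with np.errstate(invalid="ignore", divide="ignore"):
            align = np.abs(dx * ux + dy * uy) / np.where(dist > 0, dist, 1.0)
        tol = max(3.0, 0.2 * final.r)
        used |= (np.abs(dist - final.r) <= tol) & (align >= _RADIAL_ALIGNMENT)

    kept.sort(key=lambda cs: (-cs[1], cs[0].cy, cs[0].cx))
    return kept


def _ring_support(
    cx: float,
    cy: float,
    xs: np.ndarray,
    ys: np.ndarray,
    ux: np.ndarray,
    uy: np.ndarray,
    params: ChtParams,
) -> tuple[np.ndarray, int] | None:
    """Edge pixels radially aligned with center ``(cx, cy)`` lying on the
    dominant radius ring; returns their index mask and the mode radius."""
    dx = xs - cx
    dy = ys - cy
    dist = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        align = np.abs(dx * ux + dy * uy) / np.where(dist > 0, dist, 1.0)
    candidate = (
        (dist >= params.min_radius)
        & (dist <= params.max_radius)
        & (align >= _RADIAL_ALIGNMENT)
    )
    if not candidate.any():
        return None
    r_hi = int(math.floor(params.max_radius))
    bins = np.rint(dist[candidate]).astype(np.int64)
    counts = np.bincount(bins, minlength=r_hi + 2)[: r_hi + 1].astype(np.float64)
    counts[: int(math.ceil(params.min_radius))] = 0.0
    smoothed = ndi.uniform_filter1d(counts, size=3)
    best_r = int(np.argmax(smoothed))
    if smoothed[best_r] <= 0:
        return None
    tol = max(2.0, 0.05 * best_r)
    ring = candidate & (np.abs(dist - best_r) <= tol)
    return ring, best_r


def _kasa_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float] | None:
    """Algebraic least-squares circle fit (Kåsa)."""
    a = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    try:
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if not np.isfinite(r2) or r2 <= 0:
        return None
    return float(cx), float(cy), float(math.sqrt(r2))


def _refine_circle(
    cx: float,
    cy: float,
    xs: np.ndarray,
    ys: np.ndarray,
    ux: np.ndarray,
    uy: np.ndarray,
    params: ChtParams,
) -> tuple[Circle, float] | None:
    """Second CHT stage for one candidate center.

    Alternates (a) picking the dominant rim ring among radially-aligned
    edge pixels and (b) least-squares re-fitting the circle to that ring.
    The score is the fraction of the circumference the final ring covers,
    a geometric confidence in [0, 1].
    """
    best_r: float | None = None
    for _ in range(3):
        found = _ring_support(cx, cy, xs, ys, ux, uy, params)
        if found is None:
            return None
        ring, mode_r = found
        fit = _kasa_fit(xs[ring].astype(np.float64), ys[ring].astype(np.float64))
        if fit is None:
            best_r = float(mode_r)
            break
        fx, fy, fr = fit
        if not (params.min_radius <= fr <= params.max_radius):
            best_r = float(mode_r)
            break
        cx, cy, best_r = fx, fy, fr

    if best_r is None:
        return None
    found = _ring_support(cx, cy, xs, ys, ux, uy, params)
    if found is None:
        return None
    ring, mode_r = found
    radius = float(best_r)
    # Angular coverage of the final ring: 72 sectors of 5 degrees.
    ang = np.arctan2(ys[ring] - cy, xs[ring] - cx)
    sectors = np.unique(np.floor((ang + math.pi) / (2 * math.pi) * 72).astype(int) % 72)
    score = len(sectors) / 72.0
    return Circle(float(cx), float(cy), radius), score


def detect_frame(
    frame: np.ndarray,
    frame_index: int,
    params: ChtParams | None = None,
    nms_threshold: float = 0.5,
) -> list[ScoredProposal]:
    """Run the full classical pipeline on one RGB frame.

    Grayscale conversion → median blur → circular Hough transform → box
    conversion (clipped to the frame) → per-frame greedy NMS under the
    containment-modified IoU.  Proposals are returned in descending score
    order and carry ``frame_index`` for downstream z-stack fusion.
    """
    if params is None:
        params = ChtParams()
    gray = to_grayscale(frame)
    blurred = median_filter(gray, params.median_kernel)
    h, w = gray.shape
    proposals: list[ScoredProposal] = []
    for circle, support in hough_circles(blurred, params):
        box = clip_box(circle_to_box(circle), w, h)
        if box is None:
            continue
        proposals.append(ScoredProposal(box=box, score=support, frame_index=frame_index))

    from .fusion import greedy_nms  # deferred: fusion imports this module

    return greedy_nms(proposals, nms_threshold, metric=containment_iou)
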