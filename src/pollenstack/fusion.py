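"""Z-stack focal-plane selection and proposal fusion.

A multifocal sample is an ordered stack of frames recorded while focusing
through the slide; each grain is sharpest in its own focal plane.  The
recognition flow picks a reference plane by autofocus, processes a window
of planes around it (10 below and 10 above by default, i.e. at least 21
planes), concatenates the per-frame proposals and merges them with a
score-sorted greedy non-maximum suppression.

NMS uses the containment-modified IoU: a small proposal fully nested inside
a larger one has an arbitrarily low plain IoU, so without the containment
rule both would survive and the duplicate would count against precision.
Boxes are compared as-is across frames — the slight drift of grain position
with focus is a property of the data and is not corrected here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.ndimage as ndi

from .cht import ScoredProposal, to_grayscale
from .geometry import Box, containment_iou

__all__ = [
    "Sample",
    "FusionConfig",
    "autofocus_reference",
    "select_focus_frames",
    "greedy_nms",
    "fuse_nms",
]

logger = logging.getLogger("pollenstack.fusion")


@dataclass(slots=True)
class Sample:
    """One multifocal sample: z-ascending frames plus metadata."""

    sample_id: str
    slide_id: str
    pollen_type: str
    frames: list[np.ndarray]
    width: int
    height: int
    reference_frame: int | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError(f"sample {self.sample_id!r} has no frames")
        for i, f in enumerate(self.frames):
            if f.shape[:2] != (self.height, self.width):
                raise ValueError(
                    f"sample {self.sample_id!r}: frame {i} has shape {f.shape[:2]}, "
                    f"expected ({self.height}, {self.width})"
                )
        if self.reference_frame is not None and not (
            0 <= self.reference_frame < len(self.frames)
        ):
            raise ValueError(
                f"sample {self.sample_id!r}: reference_frame {self.reference_frame} "
                f"outside [0, {len(self.frames)})"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True, slots=True)
class FusionConfig:
    """Frame-window and NMS configuration.

    ``half_width`` frames are processed on each side of the reference plane
    (default 10, so 21 planes for an interior reference).  ``nms_threshold``
    is the suppression threshold Nt on the containment-modified IoU.
    ``score_min`` drops proposals below a confidence gate; 0.85 is the gate
    used with CNN detectors, while the classical CHT backend — whose scores
    are normalized accumulator support, not calibrated confidences — runs
    ungated (0.0).
    """

    half_width: int = 10
    nms_threshold: float = 0.5
    score_min: float = 0.85
    gate_after_nms: bool = False

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError(f"half_width must be >= 0, got {self.half_width}")
        if not (0.0 < self.nms_threshold <= 1.0):
            raise ValueError(f"nms_threshold must be in (0, 1], got {self.nms_threshold}")
        if not (0.0 <= self.score_min <= 1.0):
            raise ValueError(f"score_min must be in [0, 1], got {self.score_min}")


def _laplacian_variance(frame: np.ndarray) -> float:
    gray = to_grayscale(frame) if frame.ndim == 3 else np.asarray(frame)
    lap = ndi.laplace(gray.astype(np.float64))
    return float(lap.var())


def autofocus_reference(
    sample: Sample,
    sharpness: Callable[[np.ndarray], float] = _laplacian_variance,
) -> int:
    """Index of the sharpest frame, by variance of the Laplacian.

    The variance-of-Laplacian contrast measure peaks where the most image
    structure is in focus; with several grains sharp at different depths it
    lands near the best-populated plane.  Ties break to the lowest index.
    """
    scores = np.array([sharpness(f) for f in sample.frames])
    return int(np.argmax(scores))


def select_focus_frames(sample: Sample, cfg: FusionConfig) -> list[int]:
    """Frame indices ``ref − half_width … ref + half_width``, clipped to the
    stack, ascending.  The reference is ``sample.reference_frame`` when set,
    otherwise determined by autofocus."""
    ref = (
        sample.reference_frame
        if sample.reference_frame is not None
        else autofocus_reference(sample)
    )
    lo = max(0, ref - cfg.half_width)
    hi = min(sample.n_frames - 1, ref + cfg.half_width)
    return list(range(lo, hi + 1))


def _sort_key(p: ScoredProposal) -> tuple:
    # Descending score; deterministic tie-break by frame then coordinates.
    return (-p.score, p.frame_index, p.box.x0, p.box.y0, p.box.x1, p.box.y1)


def greedy_nms(
    proposals: Sequence[ScoredProposal],
    threshold: float,
    metric: Callable[[Box, Box], float] = containment_iou,
) -> list[ScoredProposal]:
    """Greedy non-maximum suppression.

    Repeatedly keep the highest-scoring remaining proposal and eliminate
    every proposal whose overlap with it (under ``metric``) exceeds
    ``threshold``.  Survivors are returned in score order.
    """
    ordered = sorted(proposals, key=_sort_key)
    kept: list[ScoredProposal] = []
    for p in ordered:
        if all(metric(p.box, k.box) <= threshold for k in kept):
            kept.append(p)
    return kept


def fuse_nms(
    proposals: Sequence[ScoredProposal], cfg: FusionConfig | None = None
) -> list[ScoredProposal]:
    """Merge per-frame proposals from a whole z-stack into final detections.

    Proposals below ``score_min`` are dropped, the remainder sorted by
    descending score, and greedy NMS applied across frames under the
    containment-modified IoU with threshold Nt.  With ``gate_after_nms``
    the score gate is applied to the NMS survivors instead; the two orders
    produce identical detections (a sub-gate proposal only ever suppresses
    lower-scored, hence also sub-gate, proposals), so the flag exists to
    make that equivalence checkable rather than to change behavior.
    """
    if cfg is None:
        cfg = FusionConfig()
    if cfg.gate_after_nms:
        survivors = greedy_nms(proposals, cfg.nms_threshold)
        return [p for p in survivors if p.score >= cfg.score_min]
    gated = [p for p in proposals if p.score >= cfg.score_min]
    return greedy_nms(gated, cfg.nms_threshold)
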