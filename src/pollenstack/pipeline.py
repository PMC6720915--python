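"""End-to-end orchestration: detect over a z-stack window, fuse, evaluate.

This is the library layer underneath the command-line interface; each
function logs per-stage record counts at INFO so a run's totals reconcile
across stages.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .cht import ChtParams, ScoredProposal, detect_frame
from .evaluation import (
    EvalCounts,
    GroundTruthGrain,
    aggregate,
    match_sample,
)
from .fusion import FusionConfig, Sample, fuse_nms, select_focus_frames

__all__ = ["detect_sample", "fuse_sample", "evaluate_samples"]

logger = logging.getLogger("pollenstack.pipeline")


def detect_sample(
    sample: Sample,
    params: ChtParams | None = None,
    cfg: FusionConfig | None = None,
    frame_indices: Sequence[int] | None = None,
) -> list[ScoredProposal]:
    """Run the per-frame detector over the sample's focus window.

    By default frames are selected around the autofocus reference (or the
    sample's stored reference frame); ``frame_indices`` overrides the
    selection, e.g. with a single annotated plane.  Each selected plane is
    processed independently; the un-fused proposals of all planes are
    returned.
    """
    if params is None:
        params = ChtParams()
    if cfg is None:
        cfg = FusionConfig()
    if frame_indices is None:
        indices = select_focus_frames(sample, cfg)
    else:
        indices = sorted(set(frame_indices))
        if any(not 0 <= z < sample.n_frames for z in indices):
            raise ValueError(
                f"sample {sample.sample_id!r}: frame indices {indices} outside "
                f"[0, {sample.n_frames})"
            )
    proposals: list[ScoredProposal] = []
    for z in indices:
        proposals.extend(
            detect_frame(sample.frames[z], z, params, nms_threshold=cfg.nms_threshold)
        )
    logger.info(
        "sample %s: processed %d focal planes, %d proposals",
        sample.sample_id,
        len(indices),
        len(proposals),
    )
    return proposals


def fuse_sample(
    proposals: Sequence[ScoredProposal], cfg: FusionConfig | None = None,
    sample_id: str = "?",
) -> list[ScoredProposal]:
    detections = fuse_nms(proposals, cfg)
    logger.info(
        "sample %s: fused %d proposals into %d detections",
        sample_id, len(proposals), len(detections),
    )
    return detections


def evaluate_samples(
    detections_by_sample: dict[str, Sequence[ScoredProposal]],
    grains_by_sample: dict[str, Sequence[GroundTruthGrain]],
    iou_min: float = 0.5,
    tpe_rule: str = "iou",
) -> EvalCounts:
    """Match fused detections against ground truth, sample by sample.

    Samples present in the annotations but absent from the detections
    contribute their fully-visible grains as false negatives.
    """
    per_sample: list[EvalCounts] = []
    for sample_id in sorted(set(detections_by_sample) | set(grains_by_sample)):
        counts = match_sample(
            detections_by_sample.get(sample_id, []),
            grains_by_sample.get(sample_id, []),
            iou_min=iou_min,
            tpe_rule=tpe_rule,  # type: ignore[arg-type]
        )
        per_sample.append(counts)
    total = aggregate(per_sample)
    logger.info(
        "evaluated %d samples: predictions=%d tp=%d fn=%d fp=%d tpe=%d",
        len(per_sample), total.predictions, total.tp, total.fn, total.fp, total.tpe,
    )
    return total
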