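"""Detection-protocol evaluation: TP/FN/FP/TPE tallies, recall/precision,
and per-species IoU statistics.

A fused detection is a true positive (TP) when its standard IoU with an
unmatched fully-visible ground-truth grain is at least 0.5; a grain no
detection reaches is a false negative (FN); a detection matching no grain
is a false positive (FP) — unless it covers a partially-visible grain at
the frame border, in which case it is a "true positive at the edge" (TPE).
Partial grains never count as FN, and TPE detections are excluded from both
recall and precision: when the microscope stage moves, a border grain
reappears complete in a neighbouring field and is counted there.

Recall and precision are percentages over fully-visible grains only:
recall = 100·TP/(TP+FN), precision = 100·TP/(TP+FP).

Matching is greedy by detection score with one-to-one grain consumption,
the standard detection-benchmark discipline: two detections cannot share a
grain, and a single merged detection over two overlapping grains registers
one TP plus one FN.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .cht import ScoredProposal
from .geometry import Box, iou

__all__ = [
    "GroundTruthGrain",
    "EvalCounts",
    "SpeciesIoUStats",
    "match_sample",
    "aggregate",
    "recall_precision",
    "per_species_iou_stats",
    "summary_dict",
    "write_summary_json",
    "write_species_csv",
]


@dataclass(frozen=True, slots=True)
class GroundTruthGrain:
    """An annotated grain: box in the focal plane where its border is
    sharpest, species label, and visibility flags.

    ``fully_visible`` marks grains entirely inside the frame (only these
    count toward recall); ``sharp`` marks grains with a sharp border in
    their annotated plane, as opposed to a blurred appearance.
    """

    grain_id: str
    sample_id: str
    box: Box
    species: str
    frame_index: int
    fully_visible: bool = True
    sharp: bool = True


@dataclass(slots=True)
class EvalCounts:
    """TP/FN/FP/TPE tallies plus the IoU of every TP match.

    ``matched_ious`` holds ``(grain_id, species, iou)`` for matched
    fully-visible grains; every reported rate derives from these fields.
    """

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tpe: int = 0
    matched_ious: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def predictions(self) -> int:
        """Total fused detections: TP + TPE + FP."""
        return self.tp + self.tpe + self.fp


@dataclass(frozen=True, slots=True)
class SpeciesIoUStats:
    species: str
    mean_iou: float
    sigma_iou: float
    n_pred: int


def _det_order(p: ScoredProposal) -> tuple:
    return (-p.score, p.frame_index, p.box.x0, p.box.y0, p.box.x1, p.box.y1)


def match_sample(
    detections: Sequence[ScoredProposal],
    gts: Sequence[GroundTruthGrain],
    iou_min: float = 0.5,
    tpe_rule: Literal["iou", "center"] = "iou",
) -> EvalCounts:
    """Match one sample's fused detections against its ground truth.

    Detections, in descending score order, each claim the unmatched
    fully-visible grain of highest IoU (ties on grain_id); a claim at
    IoU ≥ ``iou_min`` is a TP.  Unclaimed detections are then tested against
    partially-visible border grains — either at the same IoU threshold
    against the grain's visible (clipped) box, or, with
    ``tpe_rule="center"``, by the detection center falling inside it — and
    become TPE on success, FP otherwise.  Unmatched fully-visible grains
    are FN; partial grains are never FN.
    """
    if not (0.0 < iou_min <= 1.0):
        raise ValueError(f"iou_min must be in (0, 1], got {iou_min}")
    sample_ids = {g.sample_id for g in gts}
    if len(sample_ids) > 1:
        raise ValueError(f"ground truth mixes sample ids: {sorted(sample_ids)}")

    full = [g for g in gts if g.fully_visible]
    partial = [g for g in gts if not g.fully_visible]
    counts = EvalCounts()

    matched_full: set[str] = set()
    unclaimed: list[ScoredProposal] = []
    for det in sorted(detections, key=_det_order):
        best: GroundTruthGrain | None = None
        best_iou = 0.0
        for g in full:
            if g.grain_id in matched_full:
                continue
            v = iou(det.box, g.box)
            if v > best_iou or (v == best_iou and best is not None and v > 0.0
                                and g.grain_id < best.grain_id):
                best, best_iou = g, v
        if best is not None and best_iou >= iou_min:
            matched_full.add(best.grain_id)
            counts.tp += 1
            counts.matched_ious.append((best.grain_id, best.species, best_iou))
        else:
            unclaimed.append(det)

    matched_partial: set[str] = set()
    for det in unclaimed:
        hit = False
        for g in sorted(partial, key=lambda g: g.grain_id):
            if g.grain_id in matched_partial:
                continue
            if tpe_rule == "center":
                cx, cy = det.box.center
                covered = g.box.x0 <= cx < g.box.x1 and g.box.y0 <= cy < g.box.y1
            else:
                covered = iou(det.box, g.box) >= iou_min
            if covered:
                matched_partial.add(g.grain_id)
                hit = True
                break
        if hit:
            counts.tpe += 1
        else:
            counts.fp += 1

    counts.fn = len(full) - counts.tp
    return counts


def aggregate(counts: Iterable[EvalCounts]) -> EvalCounts:
    """Component-wise sum over samples; matched IoU records concatenated."""
    total = EvalCounts()
    for c in counts:
        total.tp += c.tp
        total.fn += c.fn
        total.fp += c.fp
        total.tpe += c.tpe
        total.matched_ious.extend(c.matched_ious)
    return total


def recall_precision(c: EvalCounts) -> tuple[float | None, float | None]:
    """(recall %, precision %) over fully-visible grains; TPE excluded.

    A rate with a zero denominator is undefined and reported as ``None``
    rather than 0.
    """
    recall = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    precision = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    return recall, precision


def per_species_iou_stats(
    c: EvalCounts, ddof: int = 0
) -> tuple[list[SpeciesIoUStats], SpeciesIoUStats | None]:
    """Mean and standard deviation of TP match IoUs, per species and pooled.

    The pooled row weights grains, not species (a "mean per grain").  σ is
    the population standard deviation by default (``ddof=0``); species with
    no matches are omitted.  Returns ``(per_species, overall)``; overall is
    ``None`` when there are no matches at all.
    """
    by_species: dict[str, list[float]] = {}
    for _gid, species, v in c.matched_ious:
        by_species.setdefault(species, []).append(v)
    rows = [
        SpeciesIoUStats(
            species=s,
            mean_iou=float(np.mean(vals)),
            sigma_iou=float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0,
            n_pred=len(vals),
        )
        for s, vals in sorted(by_species.items())
    ]
    pooled = [v for _g, _s, v in c.matched_ious]
    overall = (
        SpeciesIoUStats(
            species="all",
            mean_iou=float(np.mean(pooled)),
            sigma_iou=float(np.std(pooled, ddof=ddof)) if len(pooled) > ddof else 0.0,
            n_pred=len(pooled),
        )
        if pooled
        else None
    )
    return rows, overall


def summary_dict(c: EvalCounts) -> dict:
    """Summary of the localization performance of a run: counts, the
    Predictions = TP + TPE + FP total, and the recall/precision percentages."""
    recall, precision = recall_precision(c)
    return {
        "predictions": c.predictions,
        "tp": c.tp,
        "fn": c.fn,
        "fp": c.fp,
        "tpe": c.tpe,
        "recall_pct": None if recall is None else round(recall, 2),
        "precision_pct": None if precision is None else round(precision, 2),
    }


def write_summary_json(c: EvalCounts, path: str | Path) -> dict:
    summary = summary_dict(c)
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def write_species_csv(
    stats: Sequence[SpeciesIoUStats],
    path: str | Path,
    overall: SpeciesIoUStats | None = None,
) -> None:
    """Per-species IoU report: species, mean IoU, σ, number of predictions."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "mean_iou", "sigma_iou", "n_pred"])
        for row in stats:
            writer.writerow([row.species, f"{row.mean_iou:.4f}", f"{row.sigma_iou:.4f}", row.n_pred])
        if overall is not None:
            writer.writerow(
                ["mean_per_grain", f"{overall.mean_iou:.4f}", f"{overall.sigma_iou:.4f}", overall.n_pred]
            )
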