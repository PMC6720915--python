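"""Annotation schema, proposal files, rescaling, and the train/test split.

The annotation container is one JSON document per dataset (schema id
``pollenstack-annotations/1``): sample records — frame files, annotated
focal planes of interest, frame dimensions — plus one record per annotated
grain (box, species, sharpest plane, visibility flags).  Boxes are stored
at native resolution and scaled on load; scaling is the only raster
preprocessing in the pipeline.

Detector proposals travel as JSON lines, one record per proposal:
``{sample_id, frame_index, x0, y0, x1, y1, score}`` (fused detections add
``"fused": true``).

The train/test split mirrors the grain-ratio-balanced allocation used to
build monospecies pollen datasets: within each pollen type, samples are
sorted by grain count descending and assigned greedily to whichever set's
grain share is furthest below its target (60 % train / 40 % test).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cht import ScoredProposal
from .evaluation import GroundTruthGrain
from .fusion import Sample
from .geometry import Box

__all__ = [
    "SCHEMA_ID",
    "AnnotationError",
    "SampleRecord",
    "AnnotationSet",
    "SplitResult",
    "read_annotations",
    "write_annotations",
    "load_sample_frames",
    "read_proposals",
    "write_proposals",
    "scale_sample",
    "scale_grains",
    "split_train_test",
]

SCHEMA_ID = "pollenstack-annotations/1"


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation data; the message names the
    offending record."""


@dataclass(slots=True)
class SampleRecord:
    """Metadata of one multifocal sample as stored in the annotation file."""

    sample_id: str
    slide_id: str
    pollen_type: str
    width: int
    height: int
    n_frames: int
    frame_files: list[str] = field(default_factory=list)
    frames_of_interest: list[int] = field(default_factory=list)
    reference_frame: int | None = None


@dataclass(slots=True)
class AnnotationSet:
    """All sample records and grain annotations of one dataset."""

    samples: list[SampleRecord] = field(default_factory=list)
    grains: list[GroundTruthGrain] = field(default_factory=list)

    def validate(self) -> None:
        seen_samples: dict[str, SampleRecord] = {}
        for rec in self.samples:
            if rec.sample_id in seen_samples:
                raise AnnotationError(f"duplicate sample_id {rec.sample_id!r}")
            if rec.width <= 0 or rec.height <= 0 or rec.n_frames < 1:
                raise AnnotationError(f"sample {rec.sample_id!r}: bad dimensions")
            for z in rec.frames_of_interest:
                if not (0 <= z < rec.n_frames):
                    raise AnnotationError(
                        f"sample {rec.sample_id!r}: frame of interest {z} out of range"
                    )
            seen_samples[rec.sample_id] = rec
        seen_grains: set[str] = set()
        for g in self.grains:
            if g.grain_id in seen_grains:
                raise AnnotationError(f"duplicate grain_id {g.grain_id!r}")
            seen_grains.add(g.grain_id)
            rec = seen_samples.get(g.sample_id)
            if rec is None:
                raise AnnotationError(
                    f"grain {g.grain_id!r} references unknown sample {g.sample_id!r}"
                )
            if not (0 <= g.frame_index < rec.n_frames):
                raise AnnotationError(
                    f"grain {g.grain_id!r}: frame_index {g.frame_index} outside "
                    f"[0, {rec.n_frames})"
                )
            b = g.box
            if b.x0 < 0 or b.y0 < 0 or b.x1 > rec.width or b.y1 > rec.height:
                raise AnnotationError(
                    f"grain {g.grain_id!r}: box {b.as_tuple()} exceeds frame "
                    f"{rec.width}×{rec.height}"
                )

    def grains_of(self, sample_id: str) -> list[GroundTruthGrain]:
        return [g for g in self.grains if g.sample_id == sample_id]


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    ann.validate()
    doc = {
        "schema": SCHEMA_ID,
        "samples": [dataclasses.asdict(rec) for rec in ann.samples],
        "grains": [
            {
                "grain_id": g.grain_id,
                "sample_id": g.sample_id,
                "box": list(g.box.as_tuple()),
                "species": g.species,
                "frame_index": g.frame_index,
                "fully_visible": g.fully_visible,
                "sharp": g.sharp,
            }
            for g in ann.grains
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_annotations(path: str | Path) -> AnnotationSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("schema") != SCHEMA_ID:
        raise AnnotationError(
            f"{path}: unsupported schema {doc.get('schema')!r}, expected {SCHEMA_ID!r}"
        )
    try:
        samples = [SampleRecord(**rec) for rec in doc.get("samples", [])]
        grains = [
            GroundTruthGrain(
                grain_id=g["grain_id"],
                sample_id=g["sample_id"],
                box=Box(*g["box"]),
                species=g["species"],
                frame_index=g["frame_index"],
                fully_visible=g["fully_visible"],
                sharp=g["sharp"],
            )
            for g in doc.get("grains", [])
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationError(f"{path}: malformed record ({exc})") from exc
    ann = AnnotationSet(samples=samples, grains=grains)
    ann.validate()
    return ann


def load_sample_frames(rec: SampleRecord, root: str | Path) -> Sample:
    """Load a sample's frames from the PNG/TIFF files referenced by its
    annotation record (paths relative to the dataset root)."""
    import imageio.v3 as iio

    root = Path(root)
    frames = []
    for rel in rec.frame_files:
        f = root / rel
        if not f.exists():
            raise AnnotationError(f"sample {rec.sample_id!r}: missing frame file {rel}")
        frames.append(np.asarray(iio.imread(f)))
    return Sample(
        sample_id=rec.sample_id,
        slide_id=rec.slide_id,
        pollen_type=rec.pollen_type,
        frames=frames,
        width=rec.width,
        height=rec.height,
        reference_frame=rec.reference_frame,
    )


# ---------------------------------------------------------------------------
# Proposal JSON lines

def write_proposals(
    proposals: dict[str, Sequence[ScoredProposal]],
    path: str | Path,
    fused: bool = False,
) -> None:
    with open(path, "w") as fh:
        for sample_id in sorted(proposals):
            for p in proposals[sample_id]:
                rec = {
                    "sample_id": sample_id,
                    "frame_index": p.frame_index,
                    "x0": p.box.x0,
                    "y0": p.box.y0,
                    "x1": p.box.x1,
                    "y1": p.box.y1,
                    "score": p.score,
                }
                if fused:
                    rec["fused"] = True
                fh.write(json.dumps(rec) + "\n")


def read_proposals(path: str | Path) -> dict[str, list[ScoredProposal]]:
    out: dict[str, list[ScoredProposal]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                p = ScoredProposal(
                    box=Box(rec["x0"], rec["y0"], rec["x1"], rec["y1"]),
                    score=rec["score"],
                    frame_index=rec["frame_index"],
                )
                out.setdefault(rec["sample_id"], []).append(p)
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise AnnotationError(f"{path}:{lineno}: bad proposal record ({exc})") from exc
    return out


# ---------------------------------------------------------------------------
# Rescaling

def scale_grains(
    grains: Iterable[GroundTruthGrain], sx: float, sy: float
) -> list[GroundTruthGrain]:
    return [
        dataclasses.replace(
            g, box=Box(g.box.x0 * sx, g.box.y0 * sy, g.box.x1 * sx, g.box.y1 * sy)
        )
        for g in grains
    ]


def scale_sample(
    sample: Sample,
    grains: Sequence[GroundTruthGrain] = (),
    target: tuple[int, int] = (640, 512),
) -> tuple[Sample, list[GroundTruthGrain]]:
    """Resample frames to ``target = (width, height)`` (bilinear) and scale
    grain boxes by the per-axis factors.  The canonical use is halving
    native 1280×1024 captures to 640×512."""
    from skimage.transform import resize

    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError(f"target dimensions must be positive, got {target}")
    sx = tw / sample.width
    sy = th / sample.height
    if (tw, th) == (sample.width, sample.height):
        frames = [f.copy() for f in sample.frames]
    else:
        frames = [
            np.rint(
                resize(
                    f.astype(np.float64),
                    (th, tw) + f.shape[2:],
                    order=1,
                    preserve_range=True,
                    anti_aliasing=sx < 1.0,
                )
            ).clip(0, 255).astype(np.uint8)
            for f in sample.frames
        ]
    scaled = Sample(
        sample_id=sample.sample_id,
        slide_id=sample.slide_id,
        pollen_type=sample.pollen_type,
        frames=frames,
        width=tw,
        height=th,
        reference_frame=sample.reference_frame,
    )
    return scaled, scale_grains(grains, sx, sy)


# ---------------------------------------------------------------------------
# Train/test split

@dataclass(slots=True)
class SplitResult:
    train_sample_ids: list[str]
    test_sample_ids: list[str]
    train_grains: int
    test_grains: int

    @property
    def train_share(self) -> float:
        total = self.train_grains + self.test_grains
        return self.train_grains / total if total else 0.0


def split_train_test(
    samples: Iterable[tuple[str, str, int]],
    train_fraction: float = 0.60,
) -> SplitResult:
    """Grain-ratio-balanced allocation of samples to train/test sets.

    ``samples`` is an iterable of ``(sample_id, pollen_type, grain_count)``.
    Within each pollen type, samples are sorted by grain count descending
    (ties: sample_id ascending) and assigned one by one to the set whose
    grain share, over what that type has assigned so far, is furthest below
    its target share (``train_fraction`` vs the remainder); ties favor
    train.  Assigning the heaviest samples first keeps the achieved share
    within one sample's grains of the target.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    by_type: dict[str, list[tuple[str, int]]] = {}
    for sample_id, ptype, count in samples:
        if count < 0:
            raise ValueError(f"sample {sample_id!r}: negative grain count {count}")
        by_type.setdefault(ptype, []).append((sample_id, count))

    train_ids: list[str] = []
    test_ids: list[str] = []
    train_g = test_g = 0
    for ptype in sorted(by_type):
        ordered = sorted(by_type[ptype], key=lambda sc: (-sc[1], sc[0]))
        t_g = s_g = 0
        for sample_id, count in ordered:
            total = t_g + s_g
            train_share = t_g / total if total else 0.0
            test_share = s_g / total if total else 0.0
            deficit_train = train_fraction - train_share
            deficit_test = (1.0 - train_fraction) - test_share
            if deficit_train >= deficit_test:
                train_ids.append(sample_id)
                t_g += count
            else:
                test_ids.append(sample_id)
                s_g += count
        train_g += t_g
        test_g += s_g
    return SplitResult(
        train_sample_ids=sorted(train_ids),
        test_sample_ids=sorted(test_ids),
        train_grains=train_g,
        test_grains=test_g,
    )
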