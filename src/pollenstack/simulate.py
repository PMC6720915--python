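"""Synthetic multifocal slide generator.

Renders annotated z-stacks that emulate stained bright-field pollen slides:
fuchsia-tinted spheroidal grains whose border is sharpest at a grain-specific
focal plane, optional clumped grains, partially-visible grains at the frame
border, thin-rimmed bubbles, irregular debris, and a noisy tinted background.
Every pipeline stage is testable against these stacks without external data.

The defocus model is a z-linear Gaussian blur: a grain rendered at plane
``z`` is blurred with σ = ``blur_sigma_per_plane · |z − z_sharp|``.  Grain
ornamentation is band-pass speckle texture, strongest near the sharp plane
(it is destroyed by defocus blur), deliberately free of concentric circular
structure so the grain's rim remains the only circle at its location.

Randomness is split over independent streams (layout / artifacts / noise),
so adding bubbles or debris to a configuration leaves the grain layout and
the background noise bit-identical.  Output is byte-identical for identical
seeds.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import scipy.ndimage as ndi

from .datasets import AnnotationSet, SampleRecord, write_annotations
from .evaluation import GroundTruthGrain
from .fusion import Sample
from .geometry import Box, clip_box

__all__ = ["SlideConfig", "GrainSpec", "PlacementError", "generate_sample",
           "iter_dataset", "generate_dataset", "SHARP_ORNAMENTATION_CUTOFF"]

#: Ornamentation amplitude (8-bit intensity units) at and above which a
#: grain is annotated ``sharp``: its surface texture gives the border a
#: crisp, high-contrast appearance in the sharp plane.
SHARP_ORNAMENTATION_CUTOFF = 8.0

#: Default pool of 11 synthetic species labels, mirroring the breadth of a
#: monospecies-slide database with 11 pollen types.
DEFAULT_SPECIES = tuple(f"synthetic-sp{i:02d}" for i in range(1, 12))

_BACKGROUND = np.array([236.0, 226.0, 233.0])   # pale fuchsia-tinted substrate
_GRAIN_FILL = np.array([214.0, 118.0, 170.0])   # stained grain body
_GRAIN_RIM = np.array([122.0, 24.0, 84.0])      # dark exine rim
_BUBBLE_RIM = np.array([90.0, 80.0, 95.0])      # dark thin bubble outline
_DEBRIS = np.array([150.0, 138.0, 125.0])       # desaturated clutter


class PlacementError(RuntimeError):
    """Raised when grains cannot be placed without violating separation."""


@dataclass(frozen=True)
class SlideConfig:
    """Rendering and layout configuration for one synthetic sample.

    ``n_grains`` is a fixed count or an inclusive ``(lo, hi)`` range.
    ``blur_sigma_per_plane`` is the Gaussian σ (pixels) added per unit of
    z-distance from a grain's sharp plane.  ``z_sharp_band`` restricts the
    sharp planes to an inclusive index band; ``None`` uses a centered band
    of half-width 8 so the autofocus window covers most grains.
    """

    width: int = 640
    height: int = 512
    n_frames: int = 41
    n_grains: int | tuple[int, int] = (3, 8)
    radius_range: tuple[float, float] = (22.0, 90.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.12)
    ornamentation_range: tuple[float, float] = (4.0, 16.0)
    blur_sigma_per_plane: float = 0.8
    stain_rgb: tuple[int, int, int] = (214, 118, 170)
    p_partial: float = 0.10
    p_cluster: float = 0.15
    n_bubbles: int = 2
    n_debris: int = 3
    background_noise_sigma: float = 4.0
    min_separation: float = 10.0
    z_sharp_band: tuple[int, int] | None = None
    species_pool: tuple[str, ...] = DEFAULT_SPECIES
    pollen_type: str | None = None
    sample_id: str = "sample-000"
    slide_id: str = "slide-000"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        lo, hi = self.radius_range
        if not (0 < lo <= hi) or 2 * hi > min(self.width, self.height):
            raise ValueError(f"radius_range {self.radius_range} infeasible for frame")
        for name in ("n_bubbles", "n_debris"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.n_grains, tuple):
            if self.n_grains[0] < 0 or self.n_grains[0] > self.n_grains[1]:
                raise ValueError(f"bad n_grains range {self.n_grains}")
        elif self.n_grains < 0:
            raise ValueError("n_grains must be >= 0")
        if self.z_sharp_band is not None:
            zl, zh = self.z_sharp_band
            if not (0 <= zl <= zh < self.n_frames):
                raise ValueError(f"z_sharp_band {self.z_sharp_band} outside stack")

    @classmethod
    def easy(cls, **overrides) -> "SlideConfig":
        """An easy imaging condition: few well-separated, sharp,
        high-contrast circular grains, no artifacts, low noise, and sharp
        planes within ±5 frames of the stack center so the 21-plane
        recognition window always covers them."""
        base = dict(
            n_grains=(1, 5),
            radius_range=(25.0, 80.0),
            eccentricity_range=(0.0, 0.06),
            ornamentation_range=(9.0, 14.0),
            p_partial=0.0,
            p_cluster=0.0,
            n_bubbles=0,
            n_debris=0,
            background_noise_sigma=2.0,
            min_separation=40.0,
        )
        base.update(overrides)
        cfg = cls(**base)
        if cfg.z_sharp_band is None:
            mid = cfg.n_frames // 2
            half = min(5, mid)
            cfg = dataclasses.replace(cfg, z_sharp_band=(mid - half, mid + half))
        return cfg


@dataclass(frozen=True)
class GrainSpec:
    """Geometry and appearance of one rendered grain."""

    cx: float
    cy: float
    radius: float
    eccentricity: float
    z_sharp: int
    species: str
    ornamentation_amplitude: float

    @property
    def semi_axes(self) -> tuple[float, float]:
        a = self.radius
        b = self.radius * (1.0 - self.eccentricity)
        return a, b

    @property
    def true_box(self) -> Box:
        a, b = self.semi_axes
        return Box(self.cx - a, self.cy - b, self.cx + a, self.cy + b)


def _z_band(cfg: SlideConfig) -> tuple[int, int]:
    if cfg.z_sharp_band is not None:
        return cfg.z_sharp_band
    mid = (cfg.n_frames - 1) // 2
    half = min(8, mid)
    return (mid - half, min(cfg.n_frames - 1, mid + half))


def _place_grains(cfg: SlideConfig, rng: np.random.Generator) -> list[GrainSpec]:
    if isinstance(cfg.n_grains, tuple):
        n = int(rng.integers(cfg.n_grains[0], cfg.n_grains[1] + 1))
    else:
        n = cfg.n_grains
    zlo, zhi = _z_band(cfg)
    species = cfg.pollen_type or str(rng.choice(list(cfg.species_pool)))
    grains: list[GrainSpec] = []
    for _ in range(n):
        r = float(rng.uniform(*cfg.radius_range))
        ecc = float(rng.uniform(*cfg.eccentricity_range))
        orn = float(rng.uniform(*cfg.ornamentation_range))
        z = int(rng.integers(zlo, zhi + 1))
        partial = rng.random() < cfg.p_partial
        cluster = bool(grains) and rng.random() < cfg.p_cluster
        for _attempt in range(200):
            if partial:
                side = int(rng.integers(0, 4))
                t = float(rng.uniform(0.3, 0.7))  # keep 30–70 % of the grain visible
                off = r * (1.0 - t)
                if side == 0:
                    cx, cy = -off, rng.uniform(r, cfg.height - r)
                elif side == 1:
                    cx, cy = cfg.width + off, rng.uniform(r, cfg.height - r)
                elif side == 2:
                    cx, cy = rng.uniform(r, cfg.width - r), -off
                else:
                    cx, cy = rng.uniform(r, cfg.width - r), cfg.height + off
            elif cluster:
                anchor = grains[int(rng.integers(0, len(grains)))]
                ang = rng.uniform(0, 2 * math.pi)
                d = (anchor.radius + r) * float(rng.uniform(0.85, 1.0))
                cx = anchor.cx + d * math.cos(ang)
                cy = anchor.cy + d * math.sin(ang)
                if not (r <= cx <= cfg.width - r and r <= cy <= cfg.height - r):
                    continue
            else:
                cx = float(rng.uniform(r, cfg.width - r))
                cy = float(rng.uniform(r, cfg.height - r))
            ok = True
            for g in grains:
                d = math.hypot(cx - g.cx, cy - g.cy)
                limit = (0.0 if (cluster or partial)
                         else g.radius + r + cfg.min_separation)
                if d < limit:
                    ok = False
                    break
            if ok:
                grains.append(GrainSpec(cx, cy, r, ecc, z, species, orn))
                break
        else:
            raise PlacementError(
                f"could not place grain {len(grains)} of {n} after 200 attempts"
            )
    return grains


def _speckle(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Band-pass speckle in [-1, 1]: surface ornamentation without coherent
    circular structure."""
    noise = rng.standard_normal(shape)
    band = ndi.gaussian_filter(noise, 1.5) - ndi.gaussian_filter(noise, 3.0)
    peak = np.abs(band).max()
    return band / peak if peak > 0 else band


def _composite_layer(
    canvas: np.ndarray,
    rgb: np.ndarray,
    alpha: np.ndarray,
    y0: int,
    x0: int,
    sigma: float,
) -> None:
    """Alpha-composite a (blurred) premultiplied layer patch onto the canvas."""
    if sigma > 0.05:
        alpha = ndi.gaussian_filter(alpha, sigma)
        rgb = np.stack([ndi.gaussian_filter(rgb[..., c], sigma) for c in range(3)], axis=-1)
    h, w = alpha.shape
    region = canvas[y0 : y0 + h, x0 : x0 + w]
    region *= (1.0 - alpha)[..., None]
    region += rgb * alpha[..., None]


def _grain_patch(
    grain: GrainSpec,
    stain: np.ndarray,
    texture: np.ndarray,
    pad: int,
    pad_max: int,
    frame_w: int,
    frame_h: int,
) -> tuple[np.ndarray, np.ndarray, int, int] | None:
    """Premultiplied RGB and alpha for one grain, in patch coordinates.

    ``pad`` is the halo the caller's blur needs; the ornamentation texture
    is indexed by absolute pixel position (via ``pad_max``) so it stays
    registered across focal planes.
    """
    a, b = grain.semi_axes
    tx0 = int(math.floor(grain.cx - a)) - pad_max
    ty0 = int(math.floor(grain.cy - b)) - pad_max
    x0c = max(0, int(math.floor(grain.cx - a)) - pad)
    y0c = max(0, int(math.floor(grain.cy - b)) - pad)
    x1c = min(frame_w, int(math.ceil(grain.cx + a)) + pad)
    y1c = min(frame_h, int(math.ceil(grain.cy + b)) + pad)
    if x1c <= x0c or y1c <= y0c:
        return None
    ys, xs = np.mgrid[y0c:y1c, x0c:x1c]
    d = np.hypot((xs + 0.5 - grain.cx) / a, (ys + 0.5 - grain.cy) / b)
    alpha = np.clip(1.0 - (d - 1.0) / 0.03, 0.0, 1.0)  # ~1px soft edge
    rim = np.clip(1.0 - np.abs(d - 0.93) / 0.09, 0.0, 1.0)
    rgb = np.empty(d.shape + (3,))
    rgb[:] = stain
    rgb += texture[ys - ty0, xs - tx0, None] * grain.ornamentation_amplitude
    rgb = rgb * (1.0 - rim[..., None]) + _GRAIN_RIM * rim[..., None]
    return rgb * alpha[..., None], alpha, y0c, x0c


@dataclass(frozen=True)
class _Bubble:
    cx: float
    cy: float
    r: float


def _place_artifacts(
    cfg: SlideConfig, grains: list[GrainSpec], rng: np.random.Generator
) -> tuple[list[_Bubble], list[tuple[float, float, float]]]:
    """Bubbles and debris blobs, kept clear of grain boxes so clutter can
    only add false detections, never mask a grain."""

    def clear_of_grains(cx: float, cy: float, r: float) -> bool:
        return all(
            math.hypot(cx - g.cx, cy - g.cy) > r + g.radius + 5.0 for g in grains
        )

    bubbles: list[_Bubble] = []
    for _ in range(cfg.n_bubbles):
        for _attempt in range(100):
            r = float(rng.uniform(35.0, 70.0))
            cx = float(rng.uniform(r, cfg.width - r))
            cy = float(rng.uniform(r, cfg.height - r))
            if clear_of_grains(cx, cy, r):
                bubbles.append(_Bubble(cx, cy, r))
                break
    debris: list[tuple[float, float, float]] = []
    for _ in range(cfg.n_debris):
        for _attempt in range(100):
            r = float(rng.uniform(4.0, 12.0))
            cx = float(rng.uniform(r, cfg.width - r))
            cy = float(rng.uniform(r, cfg.height - r))
            if clear_of_grains(cx, cy, r):
                debris.append((cx, cy, r))
                break
    return bubbles, debris


def generate_sample(cfg: SlideConfig) -> tuple[Sample, list[GroundTruthGrain]]:
    """Render one annotated multifocal sample.

    Returns the z-stack (uint8 RGB frames) and its ground truth: one grain
    record per rendered grain, box at the sharp plane (clipped at the frame
    border for partial grains), ``fully_visible`` iff the grain's true
    extent lies inside the frame, ``sharp`` iff its ornamentation amplitude
    reaches :data:`SHARP_ORNAMENTATION_CUTOFF`.
    """
    ss = np.random.SeedSequence(cfg.seed)
    layout_rng, artifact_rng, noise_rng, texture_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    grains = _place_grains(cfg, layout_rng)
    bubbles, debris = _place_artifacts(cfg, grains, artifact_rng)
    stain = np.array(cfg.stain_rgb, dtype=np.float64)

    pad = 6
    # Largest blur halo any plane can need; also sizes the texture arrays.
    pad_max = pad + int(math.ceil(2.5 * cfg.blur_sigma_per_plane * max(1, cfg.n_frames - 1)))
    textures = [
        _speckle(
            (
                int(math.ceil(2 * g.semi_axes[1])) + 2 * pad_max + 2,
                int(math.ceil(2 * g.semi_axes[0])) + 2 * pad_max + 2,
            ),
            texture_rng,
        )
        for g in grains
    ]

    base = np.empty((cfg.height, cfg.width, 3))
    base[:] = _BACKGROUND

    # Static artifact layer (bubbles/debris do not change with focus much;
    # a constant mild blur keeps them plausible).
    artifact_canvas = base.copy()
    for bub in bubbles:
        x0 = max(0, int(bub.cx - bub.r) - pad)
        y0 = max(0, int(bub.cy - bub.r) - pad)
        x1 = min(cfg.width, int(bub.cx + bub.r) + pad)
        y1 = min(cfg.height, int(bub.cy + bub.r) + pad)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xs + 0.5 - bub.cx, ys + 0.5 - bub.cy)
        ring = np.clip(1.0 - np.abs(d - bub.r) / 2.0, 0.0, 1.0)
        inner = np.clip(1.0 - d / bub.r, 0.0, 1.0) * 0.08  # faint tinted fill
        alpha = np.clip(ring + inner, 0.0, 1.0)
        rgb = np.empty(d.shape + (3,))
        rgb[:] = _BUBBLE_RIM
        rgb = rgb * ring[..., None] + (_BACKGROUND * 0.97) * (1 - ring[..., None])
        _composite_layer(artifact_canvas, rgb * alpha[..., None], alpha, y0, x0, 1.0)
    for cx, cy, r in debris:
        x0 = max(0, int(cx - 2 * r) - pad)
        y0 = max(0, int(cy - 2 * r) - pad)
        x1 = min(cfg.width, int(cx + 2 * r) + pad)
        y1 = min(cfg.height, int(cy + 2 * r) + pad)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        blob = np.zeros(ys.shape)
        for _k in range(4):  # irregular union of lobes
            ox = float(artifact_rng.uniform(-r, r))
            oy = float(artifact_rng.uniform(-r, r))
            rr = float(artifact_rng.uniform(0.4 * r, r))
            d = np.hypot(xs + 0.5 - (cx + ox), ys + 0.5 - (cy + oy))
            blob = np.maximum(blob, np.clip(1.0 - d / rr, 0.0, 1.0))
        alpha = np.clip(blob * 1.5, 0.0, 0.9)
        rgb = np.empty(ys.shape + (3,))
        rgb[:] = _DEBRIS
        _composite_layer(artifact_canvas, rgb * alpha[..., None], alpha, y0, x0, 0.8)

    frames: list[np.ndarray] = []
    for z in range(cfg.n_frames):
        canvas = artifact_canvas.copy()
        for g, tex in zip(grains, textures):
            sigma = cfg.blur_sigma_per_plane * abs(z - g.z_sharp)
            pad_z = min(pad_max, pad + int(math.ceil(2.5 * sigma)))
            patch = _grain_patch(g, stain, tex, pad_z, pad_max, cfg.width, cfg.height)
            if patch is None:
                continue
            rgb_a, alpha, y0, x0 = patch
            _composite_layer(canvas, rgb_a, alpha, y0, x0, sigma)
        canvas = canvas + noise_rng.normal(
            0.0, cfg.background_noise_sigma, canvas.shape
        )
        frames.append(np.rint(np.clip(canvas, 0, 255)).astype(np.uint8))

    gts: list[GroundTruthGrain] = []
    for i, g in enumerate(grains):
        tb = g.true_box
        fully = (
            tb.x0 >= 0 and tb.y0 >= 0 and tb.x1 <= cfg.width and tb.y1 <= cfg.height
        )
        clipped = clip_box(tb, cfg.width, cfg.height)
        if clipped is None:
            continue  # entirely off-frame (cannot occur with the placement rules)
        gts.append(
            GroundTruthGrain(
                grain_id=f"{cfg.sample_id}-g{i:03d}",
                sample_id=cfg.sample_id,
                box=clipped,
                species=g.species,
                frame_index=g.z_sharp,
                fully_visible=fully,
                sharp=g.ornamentation_amplitude >= SHARP_ORNAMENTATION_CUTOFF,
            )
        )

    sample = Sample(
        sample_id=cfg.sample_id,
        slide_id=cfg.slide_id,
        pollen_type=grains[0].species if grains else (cfg.pollen_type or "none"),
        frames=frames,
        width=cfg.width,
        height=cfg.height,
    )
    return sample, gts


def iter_dataset(
    n_samples: int, cfg: SlideConfig, seed: int | None = None
) -> Iterator[tuple[SlideConfig, Sample, list[GroundTruthGrain]]]:
    """Lazily generate ``n_samples`` independent samples.

    Per-sample seeds are ``seed + ordinal`` (``seed`` defaults to
    ``cfg.seed``); sample ids are derived from the ordinal.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    base_seed = cfg.seed if seed is None else seed
    for i in range(n_samples):
        sub = dataclasses.replace(
            cfg,
            seed=base_seed + i,
            sample_id=f"s{i:03d}",
            slide_id=f"slide-{i // 20:02d}",
        )
        sample, gts = generate_sample(sub)
        yield sub, sample, gts


def generate_dataset(
    n_samples: int,
    cfg: SlideConfig,
    out_dir: str | Path,
    seed: int | None = None,
) -> AnnotationSet:
    """Generate a dataset on disk: PNG frame files per sample, one
    annotation document, and a manifest recording the configuration."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[SampleRecord] = []
    all_grains: list[GroundTruthGrain] = []
    for sub, sample, gts in iter_dataset(n_samples, cfg, seed):
        frame_dir = out / "frames" / sample.sample_id
        frame_dir.mkdir(parents=True, exist_ok=True)
        files = []
        for z, frame in enumerate(sample.frames):
            rel = f"frames/{sample.sample_id}/frame_{z:03d}.png"
            iio.imwrite(out / rel, frame)
            files.append(rel)
        records.append(
            SampleRecord(
                sample_id=sample.sample_id,
                slide_id=sample.slide_id,
                pollen_type=sample.pollen_type,
                width=sample.width,
                height=sample.height,
                n_frames=sample.n_frames,
                frame_files=files,
                frames_of_interest=sorted({g.frame_index for g in gts}),
            )
        )
        all_grains.extend(gts)
    ann = AnnotationSet(samples=records, grains=all_grains)
    write_annotations(ann, out / "annotations.json")
    manifest = {
        "generator": "pollenstack.simulate",
        "n_samples": n_samples,
        "seed": cfg.seed if seed is None else seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return ann
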