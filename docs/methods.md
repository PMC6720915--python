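# Methods

## Problem setting

Airborne pollen monitoring counts stained pollen grains on adhesive tape
under bright-field microscopy.  A single focal plane of such a slide shows
only part of the scene sharply: grains are volumetric (8–100 μm), sit at
different depths in the adhesive, and a grain that is crisp in one plane can
be invisible two planes away.  `pollenstack` implements the multifocal
detection pipeline for this setting: per-frame detection of grain-like
objects, fusion of the proposals from a window of focal planes into one
detection list per sample, and a matching protocol that turns detections and
annotations into recall, precision, and localization-accuracy (IoU)
statistics.  The detector backend provided here is the classical circular
Hough transform; the fusion and evaluation stages are detector-agnostic and
accept any per-frame proposal stream (the `external-proposals` backend),
which is how a CNN detector would be attached.

## Geometry and the two overlap metrics

Boxes are continuous, half-open rectangles `[x0,x1)×[y0,y1)`; areas are
geometric products.  On integer-aligned boxes this coincides with
pixel-count conventions (the test suite checks equivalence against an
explicit rasterized pixel-set oracle on a 64×64 grid), and it makes IoU
exactly invariant under coordinate scaling.  Two boxes sharing only an edge
have IoU 0.

Standard IoU, `|P∩G| / |P∪G|`, is used for detection-to-ground-truth
matching with the conventional 0.5 threshold.  Inside non-maximum
suppression a modified metric is used instead: the overlap is defined as 1.0
whenever `|P∩G|` equals the area of either box (one box nested in the
other), and plain IoU otherwise.  The rationale is a failure mode specific
to multifocal proposals: a small spurious box fully inside a much larger
detection has plain IoU far below any usable suppression threshold, so both
would survive NMS and the duplicate would count as a false positive.  The
containment test compares areas with a relative tolerance of 1e-9, which
keeps the predicate stable after box rescaling while never firing on
genuinely non-nested boxes.

## Per-frame detector: gradient-voting circular Hough transform

The classical backend mirrors the standard two-stage gradient method:

1. grayscale conversion (luma weights 0.299/0.587/0.114) and median blur
   (default kernel 17 px at native 1280×1024 scale; borders handled by edge
   replication);
2. Sobel gradients; pixels whose raw aperture-3 gradient magnitude reaches
   `gradient_threshold` (default 50, the Canny-high-threshold convention)
   are edge pixels, thinned by non-maximum suppression along the gradient
   direction.  Thinning matters: defocused rims are several pixels wide and,
   unthinned, cast bundles of parallel vote lines whose chance crossings
   create spurious accumulator peaks far from any circular object;
3. each edge pixel votes along its gradient line, both directions, for every
   radius in `[min_radius, max_radius]` (defaults 20–200 px at native
   scale); candidate centers are accumulator local maxima whose 3×3
   vote sum reaches `accumulator_threshold` (default 30) — the 3×3 sum
   compensates the transverse vote spread caused by Sobel direction
   quantization — and are greedily thinned to `min_center_dist` (25 px);
4. for each candidate, the radius is the mode of the distance histogram of
   *radially aligned* edge pixels (gradient within ~26° of the pixel→center
   direction), and the circle is re-fit to that ring by algebraic
   least squares (Kåsa), alternating ring selection and fitting up to three
   times.  Alignment filtering keeps speckle texture and neighbouring grains
   out of the radius estimate;
5. candidates are accepted best-first with sequential evidence consumption:
   an accepted circle removes the radially-aligned pixels of its annular
   neighborhood (±max(3 px, 0.2 r), spanning both edges of a dark rim band)
   from the edge set, and every later candidate is re-fit and re-scored on
   what remains.  Without this, an off-center candidate can assemble a
   plausible ring out of a real grain's tangent arc — evidence already
   explained by the accepted circle.  A candidate is accepted only if its
   final ring covers at least `min_support` of the circumference (default
   0.5, measured over 72 angular sectors) and its fitted center keeps
   `min_center_dist` from every accepted center.  The coverage criterion is
   the normalized-accumulator acceptance conventional for circular Hough
   peaks: full rims — grains and bubbles — score near 1, while the open
   arcs left by defocused or occluded borders score well below one half.
   The coverage fraction doubles as the proposal's confidence score in
   [0, 1].

Detected circles become clipped boxes, per-frame NMS (containment metric,
threshold Nt) removes same-frame duplicates, and proposals carry their focal
plane index.  `ChtParams.scaled(f)` maps the parameter set to rescaled
frames: geometric quantities (radii, center distance, median kernel) scale
by `f`, vote and gradient thresholds do not.  The half-resolution mapping
used throughout the synthetic experiments is radius 10–100 px, center
distance 12.5 px, median kernel 9 at 640×512.

Circles are what this backend can represent; grains without a circular
appearance, low contrast against the tinted background, and round non-grain
objects (bubbles) are its known failure modes, and the cluttered synthetic
runs reproduce the bubble-as-grain false positive.

## Focal-plane selection and z-stack fusion

The reference plane of a stack is chosen by autofocus: the frame maximizing
the variance of the Laplacian of the grayscale image (ties to the lowest
index; the functional is swappable).  The window `ref ± half_width` (default
half-width 10, hence 21 planes for an interior reference, fewer only when
clipped at the stack ends) is processed frame by frame.

All proposals of the window are pooled, optionally gated by a minimum score,
sorted by descending score (ties broken by frame index, then box
coordinates, for determinism), and reduced by greedy NMS under the
containment metric with threshold Nt.  Nt defaults to 0.5, matching the
evaluation threshold; the gate defaults to 0.85 for calibrated CNN scores
and to 0 for the CHT backend, whose rim-coverage scores are geometric
support rather than calibrated confidence.  Gating before or after NMS is
provably equivalent for greedy NMS (a sub-gate proposal only ever suppresses
proposals scored below itself), and a flag exposes both orders so the
equivalence is testable.  Boxes are compared as-is across planes — focus
drift of grain position is a property of the data and is deliberately not
corrected.

## Evaluation protocol

Per sample, fused detections are matched greedily in descending score order;
each detection claims the unmatched fully-visible grain of highest IoU, a
claim counting as a true positive when IoU ≥ 0.5.  The greedy one-to-one
discipline is the standard detection-benchmark choice: it prevents one
merged detection from consuming two overlapping grains (that situation
yields one TP and one FN).  Unclaimed detections are then tested against
partially-visible border grains: a detection covering one (same IoU
threshold against the grain's visible clipped box by default; a
center-in-box rule is available) is a "true positive at the edge" (TPE),
otherwise a false positive.  Fully-visible grains left unmatched are false
negatives; partial grains are never false negatives.  TPE detections are
excluded from both rates, because a border grain reappears complete in the
adjacent field of view when the stage moves: recall = 100·TP/(TP+FN) and
precision = 100·TP/(TP+FP) over fully-visible grains only.  Rates with a
zero denominator are reported as absent, not as 0.

Localization accuracy is summarized as the mean and standard deviation of
TP match IoUs, per species and pooled over grains ("mean per grain" — the
pooled row weights grains, not species).  σ is the population standard
deviation (`ddof=0`); the choice is a convention, exposed as a parameter.
The JSON summary reports the identity Predictions = TP + TPE + FP.

## Annotation schema and train/test split

Annotations live in one JSON document per dataset (schema id
`pollenstack-annotations/1`): sample records (frame files, dimensions,
annotated frames of interest) and grain records (box at the plane where the
border is sharpest, species, fully-visible and sharp flags).  Boxes are
stored at native resolution; rescaling (bilinear frames, per-axis box
factors) is the only raster preprocessing.

The train/test split balances the grain ratio rather than the sample count:
within each pollen type, samples are sorted by grain count descending and
assigned one at a time to the set whose current grain share is furthest
below its target (60 % train / 40 % test; ties favor train).  Because the
heaviest samples are placed first, the achieved share per type deviates from
the target by at most (max per-sample grain count)/(total grains) — a bound
the property tests exercise on randomized profiles.

## Synthetic slide generator

The generator renders annotated z-stacks emulating the structure of stained
slide recordings: fuchsia-tinted spheroidal grains (ellipses, small
eccentricity) with a dark exine rim and speckle ornamentation on a pale
tinted background with Gaussian sensor noise; optional clumped grains,
partial grains straddling the frame border, thin-rimmed bubbles, and
irregular desaturated debris blobs.  Defocus is modeled as a z-linear
Gaussian blur, σ = 0.8 px per plane of distance from the grain's sharp
plane — no attempt at optical realism, but linear decay makes autofocus
behavior and rim-gradient decay analyzable, and the generator's core purpose
is to reproduce the two difficulties the pipeline exists for: each grain is
sharp only near its own plane, and multifocal proposals nest.
Ornamentation is band-pass speckle rather than any concentric pattern, so
the rim remains the only circular structure at a grain's location; a grain
is annotated `sharp` when its ornamentation amplitude is at least 8
intensity units.

Randomness is split into independent streams for grain layout, artifacts,
texture, and noise, all derived from one seed.  Consequently adding bubbles
or debris to a configuration changes nothing about grain placement or
noise — the basis for the clutter-invariance property — and identical seeds
give byte-identical stacks.  Infeasible layouts (too many grains for the
separation constraint) raise a generation error after 200 placement
attempts per grain.

Defaults model a moderately busy sample: 640×512 frames, 41 planes, 3–8
grains of radius 22–90 px, sharp planes within ±8 planes of the stack
center, 10 % partial grains, 15 % clumped, 2 bubbles, 3 debris blobs,
noise σ 4.  The `easy` profile used for the end-to-end checks is the
well-separated sharp condition: 1–5 grains of radius 25–80 px, ≥40 px
separation, no artifacts, noise σ 2, and sharp planes within ±5 planes of
the stack center so the 21-plane recognition window always covers every
grain's sharp plane regardless of where autofocus lands inside that band.

## Verification scale and what it shows

The end-to-end acceptance runs 20 easy samples (≈60 grains) at 640×512 with
21 planes processed per stack, clean and cluttered; at this scale the
classical pipeline reaches 100 % recall and precision with mean TP IoU
≈ 0.84, and clutter adds false positives without costing recall.  Passing
these checks shows the stages compose correctly and that the containment
NMS and evaluation protocol behave as specified — it does not certify
performance on real slides, whose backgrounds, staining variability,
non-circular grains, and focus drift the generator deliberately does not
reproduce.

## Known limitations

- The CHT backend detects circles only; elongated or clumped grains merge
  or are missed, and bubbles fire it — both expected of the classical
  baseline.
- Autofocus assumes image contrast peaks where grains are sharp; a stack
  whose grains all lie outside the processed window yields no detections.
- The simulator's blur model is z-linear and per-grain isotropic; there is
  no chromatic aberration, no substrate occlusion, no grain drift across z.
- No sub-pixel z interpolation, soft-NMS/weighted fusion, or per-frame
  registration; these are out of scope by design.
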