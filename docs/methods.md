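# Methods

This note records the models, conventions and design choices behind
`asterpol`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Coordinate and unit conventions

All analysis happens in continuous 2D physical coordinates (µm), with the
origin at the centre of the top-left pixel, x increasing along columns and
y increasing down rows. Pixel data are converted through a mandatory
microns-per-pixel calibration carried in the TIFF sidecar metadata
(synthetic default 0.22 µm/px, a typical sCMOS/spinning-disk scale at
high-NA magnification). Frames are indexed from 0; frame times are
`frame × frame_interval_s`.

## The angle metric θ

For one comet, the comet vector runs from rear tip to front tip and the
radial vector from the reference centre to the front tip. θ is the unsigned
angle between them, so θ ∈ [0°, 180°]; θ > 90° is classed centripetal
(plus end growing toward the centre), θ ≤ 90° centrifugal. Decisions fixed
here:

- **Tie at 90°** is scored centrifugal. The boundary must belong to one
  class for determinism; assigning it to the "away" class matches the
  ≤/> split of the classification rule and is documented on `classify`.
- **Closed 22 µm disk.** A front tip at exactly 22 µm is inside the
  analysis region. Measure-zero choice, fixed for determinism. Only the
  front tip governs membership; the rear tip may lie outside.
- **Numerics.** θ is evaluated from the law-of-cosines triangle of the two
  normalized vectors via the half-angle identity
  θ = 2·atan2(|û − v̂|, |û + v̂|), which avoids the ill-conditioned
  arccosine near 0°/180°. Exactly antiparallel input returns exactly
  180.0°; the tests hold this against an independent signed-angle oracle to
  below 1e-9°.
- **One θ per comet per still frame** (frame 0 by default). A radially
  symmetric aster makes a single plane through the centre representative,
  so the orientation analysis scores a single time point; multi-frame
  aggregation exists but is explicit (`frame=None`).
- A front tip coinciding with the centre leaves θ undefined; the comet is
  excluded with a logged warning.
- **Summaries.** Histogram bins default to 10° over [0°, 180°]
  (configurable; the last bin is closed so θ = 180° is counted).
  Percentages keep full precision internally; display values round to the
  nearest integer (43/49 → 87.8 → 88). Replicate s.e.m. uses the sample SD
  (n−1) over √n and is undefined (None) for a single replicate. When
  replicate structure is ambiguous (per-aster vs per-experiment), compute
  both groupings by calling `replicate_stats` on either list — the function
  is agnostic about the grouping and outputs are labelled by the caller.

## Centre detection

The reference centre of an aster is the area-weighted (shoelace) centroid
of a polygon outlining the EB1-enriched focus, invariant to vertex winding
and starting vertex. Manual outlines can be supplied as ROI JSON; the
automated stand-in (`segment_center`) thresholds the frame at the 99th
intensity quantile — the focus is assumed to be the brightest structure —
and returns the boundary of the largest connected component. In fields
without an aster the centre is an arbitrary mid-image point, with the
constraint (enforced) that the full 22 µm disk fits inside the image.

## Tracking

Detection finds local maxima of a lightly smoothed frame (σ = 0.15 µm)
above a threshold `max(intensity quantile, median + 6·robust SD)`; the
second term keeps near-empty noisy frames from producing false peaks while
the quantile adapts to busy scenes. Each detection carries an orientation
axis from local intensity second moments; head/tail polarity is only
resolved by motion, since a single frame cannot distinguish them.

Linking is greedy nearest-neighbour between consecutive frames: candidate
pairs sorted by distance, matched one-to-one under a hard displacement cap,
no gap closing, unmatched detections opening new tracks. Detections are
canonically ordered by position first, so permuting input order cannot
change the result. Greedy matching can drop a link that a globally optimal
assignment would keep; the tests bound this against an exhaustive
minimal-total-distance oracle on small cases (≤4 detections per frame) and
the benchmark scenes are sparse enough that the bound is tight. This
deliberately simple linker stands in the role of a full multi-hypothesis
tracker, which is out of scope.

Track direction is the circular mean of segment angles — the angle of the
resultant of segment unit vectors — because an arithmetic mean of angle
values is ill-defined across the 0°/360° wrap (segments at 350° and 10°
must average to 0°, not 180°). Zero-length segments are skipped; a
vanishing resultant leaves the direction undefined (None). Directions map
to colours through the periodic HSV wheel: injective on [0°, 360°),
0° ≡ 360°.

Centre-interaction classes operationalize "terminates at / emanates from
the centre" with a deterministic rule: a track is `incoming_terminating`
when its last point lies within the capture radius (default 10 µm) and its
final distance to the centre is smaller than its initial distance;
`outgoing` is the mirror case; everything else is `other`. The net-inward
requirement is a repo decision — a comet vanishing inside the radius while
moving tangentially does not count as terminating. Terminate/emanate
fractions are taken over classifiable tracks only, so they sum to 1
exactly. The default observation window is 180 s (~3 min of a movie at 5 s
frame intervals).

## Intensity quantification

- **Total-intensity series**: per time point, the sum of all pixel
  intensities over all confocal planes (the sum-of-slices projection).
  Normalization divides every co-plotted series by their single common
  maximum, so exactly one point reaches 1 (up to ties).
- **Line profiles**: a 15-pixel-wide scan line sampled every 1 pixel along
  its length; each profile value is the mean of `width_px` bilinearly
  interpolated samples spaced 1 pixel apart across the line. Scan lines of
  equal declared length always share a distance axis, so profiles from
  different time points are comparable point-by-point. Any sample leaving
  the image is an error rather than a silent clamp.
- **Temporal-drift correction**: the model is a per-frame scalar baseline
  b(t) added to every pixel (photobleaching-like decay). The estimator is a
  robust low-percentile frame statistic (default 5th percentile, optional
  temporal moving average) — a deliberately simple baseline estimator whose
  contract is exact on pure-background frames and within ~2% when bright
  structures cover ≪ 5% of pixels. Correction subtracts b(t) from raw
  profile values; corrected profiles are then normalized by the maximum
  over the time points selected for plotting. Normalized units are
  dimensionless a.u.; values are never compared across fluorophores.
- **Compartment fractions**: inside = (sum of intensities within the union
  of labelled compartments) / (sum over the image); outside = 1 − inside by
  definition, so the pair is conserved to machine precision.

## Synthetic scenes

The generator emulates the three study conditions: a centripetal aster
(fraction *p* of comets oriented plus-end-toward the focus along jittered
radial lines, the inverted-polarity case), a centrifugal aster (the mirror,
centrosome-like case), and a uniformly random field (the no-aster null,
whose centripetal count is Binomial(n, ½) by symmetry — the calibration the
null tests rely on).

Parameters and defaults (chosen once; the paper-facing radii and windows
are fixed by the protocol, the kinematics are field-plausible values):

| parameter | default | rationale |
|---|---|---|
| field | 60 × 60 µm | holds the 22 µm analysis disk with margin |
| pixel size | 0.22 µm | typical spinning-disk sCMOS scale |
| comet length | 2 µm | typical EB1 comet extent in extract |
| speed | 0.25 µm/s | microtubule growth ~15 µm/min in egg extract |
| frame interval | 5 s | movie cadence for a ~3 min window (30 frames) |
| angular jitter | 10° wrapped normal | real asters are not perfectly radial; keeps mixtures nondegenerate |
| aster comet radii | uniform 2–20 µm | front tips populate the analysis disk |

Comets advance front-tip-first by `speed × frame_interval` per frame.
Ground truth records, per comet, the orientation class implied by its true
growth direction at frame 0 and its centre-interaction class from its true
trajectory endpoints. All randomness flows from the scene seed through
named `numpy.random.Generator` streams; identical specs are bit-identical,
and there is no global random state.

Rendering draws each comet as a streak of Gaussian-blurred mass (σ =
0.35 µm) whose density ramps toward the front tip, with the head weighted
so the intensity maximum lands on the head (detection localizes heads to
about half a pixel); aster scenes add a bright Gaussian focus at the centre
(the EB1-enriched centre, also what `segment_center` finds) and frames get
additive Gaussian noise. Drift corruption adds b(t) per frame, with
`none`, `constant_offset`, and `exponential_decay` (A·e^(−kt), t in
frames) models.

What the generator does **not** emulate: point-spread-function realism, 3D
confocal geometry (stacks carry a single plane), comet nucleation/
catastrophe dynamics, motion along curved bundles, and tubulin-channel
textures. Passing tests therefore demonstrate correctness of the
*quantification* given comet-like images and annotations, not detection
performance on real micrographs.

## Problem sizes in tests and benchmarks

The test-suite and benchmark scenes are desk-scale by design: replicate
counts of 3–6, 100–300 comets per field (the per-region comet counts in
real data are a few dozen to ~100), 8–30 frames, and 500-seed coverage
sweeps for mixture recovery. These sizes make every statistical check
well-powered while keeping a full run in tens of seconds.

## Known limitations

- The greedy linker underperforms global assignment in dense fields; it is
  adequate for sparse benchmark scenes and its error is bounded by the
  exhaustive oracle in tests.
- The percentile baseline estimator is a functional substitute for a full
  illumination/drift decomposition; equivalence with such tools is not
  claimed beyond the scalar-baseline model it implements.
- Detection merges comets closer than ~1.5 µm; crowded aster centres are
  reported as single detections (the central focus itself yields one
  stationary track, classed `other`).
- Orientation ground truth in mixtures is defined at frame 0; comets that
  cross the centre during a movie can change their instantaneous
  relationship to it, which is why the θ analysis scores a still frame.
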