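# Methods

## Head frame and angular coordinates

Three landmarks are tracked on the head in top-view video: the points
nearest the left eye (`leftHead`), the right eye (`rightHead`) and the top
of the head (`topHead`).  The per-frame head frame is

- **origin**: the midpoint of the two eye landmarks.  The eye midpoint is
  preferred over `topHead` as projection origin because it is symmetric
  with respect to both eyes and stable under head roll;
- **heading**: the unit vector from the origin toward `topHead` — the only
  orientation the three named landmarks define;
- **left sign**: +1 or −1, chosen per frame so that the `leftHead` landmark
  itself has a positive signed angle.

The signed angle of a point is the angle between the heading and the
origin→point ray, positive on the animal's left, in (−180°, 180°].
Because the left sign is re-derived each frame from the landmark
configuration, the coordinate is invariant under rigid motions of the
scene and independent of the image's y-down convention.  A corollary worth
stating: reflecting the scene *with its labels* leaves signed angles
unchanged (the convention is anatomical, not retinal); the mirror image of
a session is the reflection with the left/right eye labels swapped, and
that operation negates every angle and swaps left/right sectors.  The
tests exercise the latter form.

Degenerate frames (coincident landmarks, `topHead` on the eye midpoint or
collinear with the eye axis) raise a geometry error naming the frame; they
cannot be scored and should be excluded upstream by the likelihood filter,
which in practice catches them first.

## Visual-field partition

Three per-side widths — frontal half-width f, lateral width l, blind
half-width b, with f + l + b = 180° — tile the circle into six half-open
sectors (FL, FR, LL, LR, BL, BR; see README for the intervals).  Defaults
are the domestic-chick values f = 15°, l = 135°, b = 30°.  The "blind"
width is interpreted per side; the alternative (30° total) would leave 30°
of the circle in no sector.  Boundary ties are measure-zero and resolved by
the half-open convention: a point exactly on the midline ahead falls in FL,
a point exactly behind in BL.

## Stimulus attribution

A stimulus subtends an angular interval as seen from the origin: a point
subtends a single angle, a circle its centre angle ± arcsin(r/d), a segment
the (<180°) arc between its border angles.  Heads inside a stimulus, and
segments seen edge-on through the origin, are geometry errors.  The score
of sector s is arc-length(interval ∩ s) / arc-length(interval), so scores
are in [0, 1] and sum to 1.  The straddle fraction is measured along the
subtended *arc*, not linearly along the stimulus's physical extent; the
two differ at second order for small stimuli, and the angular form matches
the visual-field semantics of radial projection lines.  The analytic
overlap is verified in the tests against a dense-sampling oracle (classify
10⁵ equally spaced angles inside the interval) to 1e-3.

Frames excluded by QC carry *missing* scores, never zeros: zeros would
deflate eye-use proportions for sessions with many dropped frames.

## Quality control

Two stages, in a fixed order:

1. **Likelihood filter.** A frame is flagged when any landmark's tracking
   confidence is below the cut-off (default 0.95).  The flag condition is
   `likelihood < cutoff`, so a value exactly at the cut-off is retained.
2. **Distance filter.** Over likelihood-passing frames only, each of the
   three inter-landmark distances is summarised by mean and sample SD
   (n−1).  A frame is flagged when any distance deviates from its mean by
   more than k·SD (default k = 3), two-sided: mistracking both stretches
   the head triangle (a label teleports away) and collapses it (all labels
   pile onto the beak).  There is no iterative re-estimation after
   removing outliers.

Computing the statistics on likelihood survivors keeps gross mistracks
from inflating the SD and masking themselves; the two failure modes are
correlated in practice, so most bad frames trip both filters.  The
deviation threshold has a numerical floor of 1e-9 px so that a perfectly
rigid synthetic head, whose distances differ only by floating-point
round-off (SD ~1e-14 px), is never flagged; the floor is far below any
physical motion.

Flags are advisory: a review workflow accepts per-frame `keep`/`drop`
overrides (a frame is invalid iff it is flagged and not kept, or dropped),
plus a seeded uniform sampler of frames for visual inspection — on the
order of 100 frames per subject is a sensible audit.

## Aggregation and agreement

Totals are sums of per-frame scores over valid frames; durations are
totals/fps (a single nominal fps per video is assumed); proportions are
totals/n_valid.  The laterality index (R−L)/(R+L) over the four seeing
fields is a convenience extension of the per-field outputs (+1 fully
right, −1 fully left).  Head activity sums eye-midpoint displacement and
absolute heading change (minimal wrapped difference) over *adjacent* valid
frame pairs; gaps across invalid frames contribute nothing and are never
interpolated.  Zone occupancy counts valid frames whose eye midpoint lies
in an axis-aligned rectangle, min-edges inclusive and max-edges exclusive
so adjacent zones never double-count.

Manual score tables use the same file schema as automated ones, so a
transparent-sheet coding protocol can be digitized directly.  Agreement is
per-sector Pearson (or Spearman) correlation over frames valid in both
tables, pooled and per subject; a zero-variance series yields a missing
correlation, never 0.  Tracking accuracy is the fraction of frames whose
six-sector vectors agree within 1e-9 (frames invalid in both tables count
as agreeing).

## Synthetic sessions

The generator emulates a restrained viewing trial at the validation
experiment's scale: eye separation 58 px, head length 40 px (≈1.4 cm at
the implied ~29 px/cm), ~25 fps for 750 frames (~30 s), and a circular
stimulus of radius 29 px placed 580 px away (a 2-cm cylinder 20 cm from
the head).  The noise-free pose follows a wrapped Gaussian random walk in
heading (3°/frame) and a Gaussian walk in position (1 px/frame); landmarks
sit on a rigid template — fixed eye separation and head length, which
makes the distance filter's null distribution controllable — then receive
isotropic Gaussian noise (default 1 px).  Outlier frames (Bernoulli, 2%
by default) teleport one uniformly chosen landmark by a fixed magnitude in
a uniform direction and give it a likelihood drawn from the "bad"
distribution (clipped normal, mean 0.6); good landmarks draw from mean
0.99.  Randomness comes from a single PCG64 generator; the draw order
(heading steps, position steps, landmark noise, outlier mask, landmark
choice, direction, likelihoods) is fixed, so outputs are bit-reproducible
per seed.

Ground truth is scored from the noise-free poses with the same scoring
code, so a noise-free session reproduces it exactly — that is the
end-to-end identity the tests assert.  What the generator does *not*
emulate: appearance-driven tracking failure modes (noise here is i.i.d.
and isotropic, whereas real trackers fail in bursts and drift), occlusion,
lens distortion, variable frame rate, or non-rigid head geometry.  Passing
tests therefore validate the post-processing chain, not any tracker.

A consequence worth knowing when interpreting the noisy-recovery tests:
with 1-px landmark noise on a 40-px head, the per-frame heading noise is
√1.5·σ/L ≈ 2°, which is material relative to the 15° frontal sector and to
the ~5.7° arc the default stimulus subtends.  Near sector boundaries the
attribution consequently flips or shifts, and per-sector frame-by-frame
correlations with ground truth settle in the 0.93–0.99 range rather than
above 0.99; narrow (frontal) sectors and sectors the stimulus rarely
visits are affected most.  Reducing the noise, enlarging the stimulus, or
lengthening the head all raise the correlations; the defaults were kept at
the realistic values above rather than tuned.

## Problem sizes and numerics

Property suites run 100–1000 random configurations with dense-sampling
oracles of 2×10⁴–10⁵ angles; end-to-end and QC-recovery checks use
2000-frame sessions.  Angles are degrees throughout, wrapped with IEEE
`remainder` so that (−180, 180] is exact; score normalisation holds to
1e-9 without renormalisation; correlations are checked against the
covariance formula to 1e-12.  CSV round-trips are exact because files are
written at full precision and re-read with the `round_trip` float parser.

## Command-line interface

`eyeuse` wraps the library as `simulate`, `qc`, `score`, `summarize` and
`compare`; CLI flags override config values, which override defaults.
Exit codes: 0 success, 1 usage, 2 data/format, 3 geometry.  The CLI writes
only files the library APIs produce, byte-identically.
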