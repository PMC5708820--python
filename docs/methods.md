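# Methods

## Model and assumptions

The pipeline estimates lateral gaze from the asymmetry of visible sclera.
When an eye fixates one side of a screen, the iris translates toward the
corresponding eye corner and the sclera on that side disappears behind the
canthus; the sclera on the opposite side widens and stays bright. Reading a
horizontal lightness profile through the iris center therefore yields two
flank maxima — LR (left region) and RR (right region) — whose ratio encodes
gaze without any per-subject calibration. The method assumes a roughly
frontal face at a fixed viewing distance (≈30 cm in the intended protocol),
so that lateral fixation produces a detectable iris displacement; it cannot
measure vertical gaze, and a strongly rotated head aliases into the wrong
side.

Sign convention: with an un-mirrored front camera, a subject fixating the
*right* half of the screen turns the eyes so the iris sits toward image
*left*; this makes LR small and fires LR/RR ≤ t → RIGHT. The fixture
generator encodes the same convention (`iris_offset_for_label`), and the
`camera_mirrored` flag in session aggregation handles devices that mirror
the preview. Screen-side-to-scene mapping (default: social right, abstract
left) is part of the stimulus configuration, not the classifier.

## Stages and parameters

**Enhancement.** CIELab under sRGB/D65. The L channel is range-remapped to
0–255 with gamma 0.5 (brightens mid-tones; the sclera saturates toward the
top of the range); the remap window defaults to each image's observed
(min, max), with an optional 1st/99th-percentile window for robustness to
outlier pixels. The K channel of a device-naive CMYK split
(K = 1 − max(R,G,B)/255) is remapped with gamma 3, suppressing everything
but genuinely dark regions. The iris localizer consumes the K-enhanced
raster; the brightness profile reads the remapped L raster. Both operations
are pixelwise and commute with mirroring.

**Detection.** Face detection uses a pretrained multi-scale sliding-window
cascade (the bundled LBP frontal-face model of scikit-image by default; any
model file in the same XML format can be configured). Eye search is
restricted to the face box when one is found and falls back to the whole
frame otherwise — losing the face never aborts eye detection. Individual
eyes are found as the largest dark compact blob in each half of the upper
face band (K-channel connected components), padded to include surrounding
sclera. Multiple face candidates keep the largest, ties to smallest x
(single-subject assumption). For synthetic sessions and any source with
known geometry, bypass mode injects ground-truth regions, which makes all
downstream stages a deterministic function of pixel content — this is the
tested configuration, separating the bespoke stages from third-party
detector behavior.

**Iris localization.** Prewitt gradient magnitude (un-normalized 3×3
kernels, reflected borders; an ideal vertical step of height h gives
interior magnitude 3h) followed by a circular accumulator: every
(center, radius) candidate is scored by the mean edge magnitude along its
circle (ring half-width 0.75 px), radii spanning 10–40% of the eye-box
height. The global maximum wins; ties resolve to the smallest radius and
first row-major center, so the result is deterministic. A best score below
`min_support` = 20 mean-gradient units means no iris (uniform or occluded
eye) and the frame becomes a distraction.

**Profile and rule.** The profile half-length is
`half_length_factor × radius` with factor 2.0 by default (it must exceed
the iris radius so each flank contains sclera or eye-corner pixels); the
window is clipped at the raster edge with the center index adjusted. The
iris span ±radius is excluded from both flanks. Decision threshold
t = 0.85, boundary inclusive; LR = RR resolves to CENTER even at t = 1. An
alternative reading of LR/RR as pixel *distances* from the iris center to
each flank's brightest pixel is available behind `distance_ratio`; the
brightness-ratio reading is the default because the rule compares to a
unitless threshold and the evidence is a brightness profile.

**Frame combination.** Both eyes must agree; the taxonomy's distraction
case (both eyes not simultaneously detected) is extended to per-eye
degeneracies and to disagreeing eyes — a child confidently fixating neither
scene — each logged with a distinct reason for audit.

**Calibration.** `calibrate_threshold` sweeps a grid of candidate models
(default 6 thresholds × 3 profile lengths = 18) and maximizes concordance —
the fraction of manually LEFT/RIGHT-labeled frames matched — with ties to
the smaller threshold. Because raising t never breaks a correctly lateral
frame under the rule's ordering, the maximal set is an interval of
thresholds; the tie-break selects its conservative end. Iris localization
is model-independent, so features are extracted once and only the rule
stage is re-swept.

**Statistics.** Scene percentages use the LEFT/RIGHT frames as denominator.
Binomial SE = 100·√(p(1−p)/n); proportion CIs Wald by default,
Clopper–Pearson behind a flag. The manual-vs-automatic proportion test is a
pooled two-sample z, two-sided by default with a one-sided option (for the
reference counts 1,436 vs 1,397 of 2,559 the one-sided p ≈ 0.136). Spearman
on the binary LEFT/RIGHT coding uses midrank ties (equivalent to the phi
coefficient up to sign). Group comparison is Student's t by default, Welch
behind a flag, reported as mean (SE) with t-based 95% CIs. Report
percentages round half-up to 2 dp.

## Synthetic data

The fixture renderer emulates exactly the features the classifier consumes:
a skin-toned face ellipse, bright sclera ellipses (gray 235), dark iris
discs (gray 45), optional Gaussian pixel noise, and exact mirror symmetry
(flipping a render equals rendering with negated offsets and swapped eye
boxes). Lateral-gaze frames place the iris flush against the sclera
boundary — the physical extreme where the iris abuts the eye corner —
because at intermediate offsets bright sclera remains inside both profile
flanks and the frame is genuinely central under the max-brightness rule.
Distraction frames occlude one eye (alternating sides) or omit the face.
Eye boxes default to 56×36 px inside a 192×128 frame, chosen once as a
plausible webcam scale for a face at 30 cm.

Cohort preference fractions are Beta-distributed with the specified group
means and a concentration (`dispersion`, default 20 — SE ≈ 3–4 percentage
points at n ≈ 20, comparable to a small clinical cohort); fractions are
bounded in (0,1) by construction, which a normal model would not guarantee.

What the fixtures do **not** model: photorealistic texture, head pose,
blinks, specular reflections, illumination gradients, or real cascade
detectability (rendered faces are not expected to trigger the pretrained
face model — detection is exercised separately on a real bundled portrait,
and synthetic sessions run in bypass mode). Passing fixture tests therefore
demonstrates the correctness of enhancement, iris localization, profiling,
the ratio rule, and all statistics — not detector robustness on real video.

## Problem sizes

Tests and the acceptance script use sessions of 24–150 frames at the
default render scale, a 15,000-frame protocol check at a miniature render
scale (16×10 px eyes), calibration on 60 frames, cohort recovery at n = 200
per group, and 1,000 equal-mean replicates at n = 20 per group for the
type-I-error check. Noise conditions are noise-free and Gaussian
noise_sd = 10 gray levels.

## Known limitations

- Gaze is resolved only laterally; objects above/below the screen register
  as lateral gaze or center, not distraction.
- The dark-blob eye finder is a heuristic suited to clean frontal frames;
  production use on real video should supply trained eye-cascade model
  files or ground-truth regions from an upstream tracker.
- Video containers require an imageio decoder plugin; the always-available
  session format is a directory of numbered PNG frames.
- The threshold calibration objective ignores CENTER frames (by design,
  matching the concordance definition), so it cannot penalize a threshold
  that over-calls lateral gaze on truly central frames; choose the grid
  accordingly.
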