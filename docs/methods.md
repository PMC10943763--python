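# Methods

## Coordinate and angle conventions

All coordinates are 0-based `(row, col)`, origin top-left. Angles are
degrees counter-clockwise from the +col axis, so the unit vector of angle
`a` is `(−sin a, cos a)` and a fly "pointing up" the image has heading
90°. A fly's left side is where the cross product of its heading with a
direction vector is positive. Calibration comes from the arena: the
chamber is 11 mm across, so `mm_per_px = 11 / (2·radius_px)`; every
millimetre threshold goes through this factor and every duration threshold
through the frame rate carried on each frame (default 24 frames/s).

## Arena detection

Arenas are bright discs on a dark surround, found once on the first frame
(the rig is static): Canny edges (σ = 2) feed a circle Hough transform
over an integer radius grid; the `expected_count` strongest accumulator
peaks, separated by at least one minimum radius, are accepted and sorted
row-major. Crops are squares of side 2·radius with the surround replaced
by the median in-circle intensity. That replacement is what the background
model needs (a dark surround would otherwise survive the maximum filter
and dominate the subtraction image), but it erases the arena's own edge,
so arena detection inside a crop is deliberately not meaningful.

## Segmentation

The background model is a per-channel spatial **maximum** filter with a
square window (default 61 px) wider than a fly: every fly pixel sees true
backlight somewhere in its window, so flies vanish and the model slightly
overestimates the background (by a few noise standard deviations — the
maximum of n noisy samples sits above the mean).

The silhouette threshold on `max_channel(background − frame)` defaults to
a **two-stage Otsu**: one Otsu cut lands between the faint wings and the
dark torso because the torso dominates the foreground histogram; a second
Otsu pass on the sub-threshold values separates wings from background
noise. A floor of 20 intensity units keeps the cut above the max-filter
bias. A fixed threshold can be configured instead (`seg.threshold`).
Small objects are removed with 8-connectivity so 1-px diagonal leg
segments stay attached to the body they belong to.

Wing pixels satisfy `round[(R/k)(G/k)(B/k)] > 0` with `k = 80`
(configurable, `seg.wing_divisor`): equivalently, the scaled channel
product reaches 0.5, which for equal channels means intensity above
`k·0.5^{1/3} ≈ 0.79 k`. The torso subtracts the *raw* wing-rule pixels
(before morphological cleanup) from the silhouette, so legs — thin and of
intermediate intensity, hence wing-like under the product rule — are also
excluded; an opening (disk 1) and closing (disk 2) then remove residual
1-px appendages and smooth the outline, keeping the largest components
(up to one per fly, at least 20 px).

## Pose

`fit_torso` uses the moment-equivalent ellipse (scikit-image region
properties; an explicit pixel-covariance computation serves as the test
oracle). Eccentricity is `√(1 − λ₂/λ₁)` of the second central moments.
The two major-axis endpoints are head/tail candidates; the head is the
one farther from the whole-body centroid, because folded wings trail
behind the abdomen. Two safeguards:

* a distance tie below 0.5 px sets an ambiguity flag and defers to the
  previous frame's heading;
* a near-180° heading reversal against the previous frame is overridden
  when the centroid evidence is weak (margin < 15 % of the axis length) —
  a fly cannot reverse within one frame interval, and the body centroid is
  easily contaminated by the partner's wing overlapping this fly. A
  decisive margin is trusted, so genuine fast turns survive.

Wing angles: boundary pixels of the wing mask are split into left/right
by the cross-product sign against the heading; per side the pixel farthest
from the torso centroid is the wingtip, and θ (left), θ′ (right) are the
unsigned angles between the tailward axis direction and the tip vectors,
in [0, 180). Folded wings therefore read ≈ 0°, right-angle extension
≈ 90°. Known limitation: wings swept far forward (≳ 110°) shift the body
centroid headward and can flip the head heuristic; courtship wing
extension stays well below this regime.

## Identity

Motion prediction is constant-velocity: `p̂ₜ = 2pₜ₋₁ − pₜ₋₂`. With two
detections the assignment minimizing total distance to the two
predictions wins; one detection means overlap. Detections are connected
silhouette components of at least one plausible fly area (default 120 px)
— smaller fragments (a detached wing sliver, a reflection) are debris.
On the first frame the smaller torso is the male (sexual size
dimorphism).

**Overlap splitting.** The merged blob's pixels are clustered by spectral
clustering (scikit-learn, RBF affinity on coordinates; bandwidth ≈ half a
torso minor axis estimated from the blob area; two clusters; k-means
assignment with a fixed random state). Blobs larger than 700 px are
subsampled deterministically and remaining pixels take their nearest
sample's label. A blob below twice the minimum fly area is one fly fully
occluding the other: both identities sit on its centroid.

**Shape verification** runs on the first clean frame after separation.
The torso is rotated so its axis is horizontal, flipped head-left, and
cropped. The Euclidean distance map of this aligned torso is negated so
the head/thorax/abdomen lobes become basins; maxima shallower than
`h = 0.25 × max(distance)` are suppressed (halved once if fewer than
three basins emerge), and the watershed from the surviving maxima yields
the parts, ordered left-to-right; spurious extra segments are folded into
the nearest part so the three parts tile the torso exactly. Two basins
are accepted as a headless fly (empty head mask): two headless torsos
still match (empty vs empty head counts as Dice 1) while a
headless/headed pairing is penalized. One basin (a featureless ellipse)
defers verification to the next frame.

Per-part Dice is computed after shifting each part's centroid to a common
grid center (translation-invariant, shape-only). A candidate matches a
reference when `max + min` of the three Dice values exceeds **1.6**; both
the straight and the swapped pairing are scored, and a pairing is adopted
only if both of its pairs clear the bar. Verification is skipped in
implausible postures (eccentricity outside [0.5, 0.99], or torso area
outside 0.5–2× the reference — wall climbing, partial occlusion) and
references refresh every 24 clean frames to track slow appearance change.

## Behavior recognition

Defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| `singing_deg` | 30° | wing-extension angle for singing (strict >) |
| `orient_ext` | 2.5 | sector radius as multiple of centroid→head distance |
| `orient_halfangle` | 10° | sector half-angle |
| `contact_mm` | 1.0 mm | male-head-to-female-tail gate (tapping, attempted copulation) |
| `ecc_factor` | 0.9 | standard value = factor × straight-male eccentricity |
| `cop_seconds` | 30 s | attempted-copulation run length beyond which copulation is declared |
| `filter.window`, `filter.min_hits` | 12, 5 | certified when hits exceed 5 within 12 frames |
| `filter.none_gap` | 12 | frames without any recognized behavior before "none" |

If the female's head/tail assignment is flagged ambiguous, the contact
gate also accepts her head point — a tail mix-up on the (often stationary)
female should not veto a genuine contact.

**Tapping cascade.** (1) the two bodies form one silhouette; (2) the
torsos are still two regions; (3) head-tail distance < 1 mm; (4) the
silhouette is partially thinned (5 iterations: legs collapse to their 1-px
skeleton, thick wings/torso survive), unioned with the torsos and the
thick body area (distance transform > 1.5 px, closed), and eroded by a
disk of radius 2 — a connection that disappears was a bare leg, one that
survives is wing-covered; (5, bare leg) leg branches are clipped to
outside the thick torso-and-wings area and re-attached to the torsos:
tapping iff the branched torsos connect (leg on torso), not if they stay
apart (leg only on a wing); (6, wing-covered) the raw image under the
silhouette is segmented by three-class Otsu — a leg under a translucent
wing multiplies down in intensity and forms a bridge that lands in the
middle or, when the darkening is strong, the darkest class; either class,
denoised and unioned with the torsos, connecting the two torsos means
tapping. Connectivity is 8-connected throughout.

**Eccentricity standard.** `manual` mode takes a user-chosen straight
frame; `auto` takes the 95th percentile of male eccentricity over the
first 30 s (a straight fly is maximally eccentric). A reference below 0.7
triggers a warning — the male may never have been straight.

**Temporal filter.** Per frame the raw flags collapse by priority to one
candidate. A behavior is certified at frame *t* when its candidate count
in the causal 12-frame window ending at *t* exceeds 5 (pro-rated at the
sequence start). Uncertified frames inherit the previous certified label,
except inside runs of ≥ 12 consecutive frames with *no recognized
behavior at all*, which are labeled "none" from the run's start — the
quiescence rule counts recognition, not certification, so the 12-frame
boundary is exact. The window is causal (ends at *t*), so labels trail a
true behavior onset by 5 frames; the scripted fixtures encode this lag in
their expected labels. Sustained attempted copulation (> `cop_seconds`)
becomes copulation from the run's start through the end of the recording
(post-copulation behavior is not analyzed).

## Ethogram analytics

Total courtship time counts orientation/tapping/singing/attempted-
copulation frames (not copulation, not none). Proportions divide each
element's frames by the observation window: full recording, up to
copulation onset, or a fixed duration — the mated/unmated comparison
duration is data-derived and therefore a parameter, never a constant.
Transitions count consecutive label changes A→B with A ≠ B;
"none" breaks a chain by default (configurable to bridge); probabilities
are row-normalized with undefined rows flagged.

## Synthetic scenes: what they emulate, and what they do not

The renderer reproduces the backlit contrast regime (background 200,
torso 30, wings 140, legs 110 on a 0–255 scale, σ = 2 Gaussian noise per
channel, channels equal up to noise so the channel-product wing rule is
exercised nontrivially), a three-lobed torso whose distance map has
head/thorax/abdomen basins, translucent paddle-shaped wings hinged at the
posterior quarter with tips at 1.2 × the semi-major axis from the torso
moment centroid, 1-px legs darkened multiplicatively under wings, and
sexual size dimorphism (male 42 × 16 px, female 56 × 24 px at
0.05 mm/px — about 2.1 vs 2.8 mm). Abdominal bending for attempted
copulation rotates the abdomen lobe about its anterior edge; a 130° bend
lowers the moment eccentricity from ≈ 0.95 to ≈ 0.80, crossing the 0.9×
standard with margin.

Not modeled: motion blur, photometric drift, specular reflection, wall
climbing and other out-of-plane postures, grooming, articulated legs,
female rejection behaviors, body-size variation within a sex. Passing the
fixture suites therefore demonstrates that the implemented definitions
and identity logic are correct and self-consistent under the stated
imaging model — not that the thresholds are optimal for any particular
rig, which is why every threshold is configuration.

## Problem sizes and benchmarks

The identity benchmark tracks a scripted 500-frame wander whose paths
fully coincide five times (approach, coincidence, separation); accuracy
is the fraction of separated frames where the male identity sits closer
to the scripted male than to the scripted female. The recognition
benchmark is a 120-frame scene library covering quiescence, orientation,
singing, tapping (leg-on-abdomen topology) and a sustained
attempted-copulation bout, scored against scripted labels that include
the 5-frame certification lag; the library runs at a 1 frame/s timebase
so the half-minute copulation rule is reachable within 40 scripted
frames. Both sizes were chosen so the full suite and the acceptance
script each run in well under a minute on one CPU while still exercising
every code path; boundary sweeps use bisection to 10⁻⁷.

## Known limitations

* Tapping step 6 can report a false contact when both flies' wings
  overlap and an unrelated dark region bridges the torsos; real systems
  share this failure mode when legs are hidden.
* The head heuristic fails for far-forward wing postures (≳ 110°); the
  temporal guard contains, but cannot fully eliminate, the error during
  prolonged contact.
* Verification needs the watershed to find at least two torso basins;
  featureless (perfectly elliptical) torsos defer verification until
  lobe structure is visible again.
* Licking is not detectable at this magnification and female behavior is
  not classified.
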