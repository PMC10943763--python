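# flycourt

Automatic recognition of *Drosophila* male courtship behavior from backlit
arena video, for behavioral neuroscientists and evolution labs who score
courtship assays (one male + one female in an 11-mm circular arena) and
want per-frame ethograms instead of hand stopwatching.

The system is a pure image-processing pipeline — no training data. Per
frame, per arena:

1. **Segmentation.** A spatial maximum filter over a window larger than a
   fly builds the bright background *B*; the silhouette is
   `max_channel(B − I) > τ`. Wing pixels inside the silhouette satisfy the
   channel-product rule `round[(R/80)·(G/80)·(B/80)] > 0` (wings are
   translucent: darker than the backlight, brighter than the torso); the
   torso is the silhouette minus the wing region.
2. **Pose.** The torso's moment-equivalent ellipse gives position (torso
   centroid), the major axis, and eccentricity `e = √(1 − (b/a)²)`. The
   head is the axis endpoint farther from the whole-body centroid (wings
   trail behind). Wing extension angles θ, θ′ are measured between the
   tailward axis and the vector from the torso centroid to each side's
   farthest wing-boundary pixel.
3. **Identity.** Constant-velocity prediction from the last two positions
   assigns detections to male/female. A merged silhouette (overlap) is
   split by spectral clustering on pixel coordinates. After every
   separation the torso is canonicalized (axis horizontal, head left),
   watershed-segmented into head/thorax/abdomen on its negated distance
   map, and compared to stored references: a pairing is the same fly when
   `max + min` of the three per-part Dice coefficients exceeds 1.6.
   A verified mismatch swaps the identities back, so overlap errors do not
   persist.
4. **Behavior.** Per frame the male is tested for: *singing*
   (max(θ, θ′) > 30°), *orientation* (female torso centroid inside a
   ±10° sector of radius 2.5 × the centroid-to-head distance),
   *tapping* (a six-step silhouette/skeleton cascade deciding whether a
   foreleg touches the female's torso, with her tail within 1 mm of his
   head), *attempted copulation* (torso eccentricity below 0.9 × a
   straight-male reference, head within 1 mm of her tail). Flags collapse
   by priority copulation > attempted copulation > tapping > singing >
   orientation, are certified when present in more than 5 of the last 12
   frames, and attempted copulation sustained beyond half a minute becomes
   *copulation* for the rest of the recording.
5. **Analytics.** Total courtship time (the four active elements),
   per-element time proportions over a configurable observation window,
   and the behavioral transition matrix (changes A→B, row-normalized,
   self-transitions excluded).

A parametric scene renderer (`flycourt.fixtures` / `flycourt.scenarios`)
draws two-fly arenas with exact ground truth — lobed torsos, translucent
wings, 1-px legs — so every stage is testable without recorded video.

## Worked example

Render the synthetic courtship scene library (quiescence → orientation →
singing → tapping → sustained attempted copulation) and track it:

```bash
flycourt render-fixtures --out frames --script library --seed 3
flycourt track frames --out run --arenas 1 --fps-override 1.0
```

`run/arena_0/` then contains `track.csv`, `pose.csv`, `behavior.csv`,
`ethogram.csv`, `proportions.csv`, the transition CSVs and
`summary.json`. For this script the summary reads:

```
total_courtship_s: 60.0
proportions: orientation 0.1667, tapping 0.1667, singing 0.1667,
             attempted_copulation 0.0, copulation 0.2917, none 0.2083
transitions: orientation->singing 1, singing->tapping 1, tapping->copulation 1
```

Read: of the 120-frame recording (1 frame/s here), 60 s were active
courtship — 20 s each of orientation, singing and tapping (1/6 of the
window apiece). The 40-frame attempted-copulation bout exceeded the
half-minute rule, so it is reported as copulation (35 frames after the
certification lag, 29 % of the window) and attempted copulation itself
ends at 0. The transition chain orientation → singing → tapping →
copulation is the scripted courtship sequence.

`flycourt analyze run/arena_0/ethogram.csv --fps 1 --window full`
recomputes the analytics from a saved ethogram;
`--window to-copulation` or `--window seconds:N` select the observation
conventions used for mated/unmated comparisons.

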