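# Methods

## Problem and model

`fallpose` classifies the posture of a single monitored person from 2D
BODY_25 pose keypoints, frame by frame, into NORMAL, one of four fall
directions (leftward, rightward, backward, forward — camera-frame:
"leftward" means toward the image's left edge), or UNKNOWN when the
skeleton carries no usable evidence. Frame labels are then debounced
into fall events with onset/offset times and a duration-derived severity
grade. The model is deliberately mechanistic: a small set of geometric
features and fixed thresholds, all exposed in configuration, so every
decision is auditable.

### Features

For each frame, with image coordinates (origin top-left, y downward):

- `trunk_angle` — angle of mid-hip→neck vs the vertical axis,
  `degrees(atan2(Δh, Δw) − π/2)` wrapped to (−180°, 180°] (exact −180°
  maps to +180° so lateral signs stay symmetric);
- `head_angle` — same for neck→nose;
- `hip_line_angle` — same for left-hip→right-hip (computed and exported,
  unused by the default cascade; kept for experimentation because the
  hip line is a plausible auxiliary direction cue);
- `trunk_hd = MID_HIP_h − NECK_h` and `head_hd = NECK_h − NOSE_h` in
  pixels (both positive for an upright subject);
- `body_scale` — the median standing trunk length over a calibration
  window (default: the sequence's first 10 frames), falling back to
  twice the median hip width, then to a configured default (80 px).
  Thresholds divide by this scale, which is what lets one configuration
  cover subjects filmed at different distances.

A feature is invalid iff a contributing keypoint's confidence is below
`min_confidence` (default 0.1) or its segment is degenerate; invalid
features are never read numerically. When MID_HIP is missing but both
hips are valid, their midpoint substitutes — consistent with the BODY_25
topology, where MID_HIP is itself a derived joint.

### Classification cascade

First match wins:

1. no usable trunk and no forward evidence → UNKNOWN;
2. trunk collapsed (`trunk_hd < 0.35·scale`) or lateral
   (`|trunk_angle| > 45°`), with `trunk_angle ≥ +45°` → FALL_RIGHT;
3. symmetrically with `trunk_angle ≤ −45°` → FALL_LEFT;
4. trunk collapsed, non-lateral, and the nose demonstrably *above* the
   neck (`head_hd` valid and `> head_hd_ratio·scale`) → FALL_BACK;
5. the configured forward indicator fires → FALL_FORWARD;
6. trunk collapsed, non-lateral (head evidence absent or neutral) →
   FALL_BACK;
7. otherwise NORMAL.

**Design choice — head-up evidence precedes the forward indicator.** The
waist-to-neck forward criterion (`e_hn_opose`) reacts to any collapsed
non-lateral trunk and so, taken alone, cannot distinguish a forward from
a backward fall. Positive head-up evidence can: if the nose is visible
and above the neck while the trunk is collapsed, the fall is backward,
whatever the forward indicator says. Placing that check before the
forward rule makes backward falls classifiable under every method while
leaving the indicator definitions — and therefore the disjunction
identity `e_opose = i_opose ∨ e_hn_opose` and its recall-dominance
consequence — untouched. The residual, irreducible confusion is a
backward fall whose face keypoints are lost: with the trunk-based
methods it is claimed forward (rule 5 before rule 6), which mirrors how
these detectors genuinely confuse out-of-plane directions when the head
is invisible. An UNKNOWN label (not part of the four directions) is
emitted rather than a fabricated direction when the skeleton is absent.

Defaults (`lying_hd_ratio` 0.35, `lateral_angle_deg` 45°,
`head_hd_ratio` 0.0 — the literal nose-at-or-below-neck reading) are
this package's calibration, co-designed with the simulator's kinematics
(below) so that clean sequences are classified perfectly; they are not
claimed to be optimal for any particular camera.

### Event engine

A fall event opens at the first frame of a run of ≥ `onset_frames` (3)
consecutive fall labels and closes at its last fall-labeled frame once
≥ `release_frames` (5) consecutive NORMAL frames follow (or at sequence
end). UNKNOWN inside an open event is continuation — losing the skeleton
mid-fall must not end the record — while outside an event it neither
opens one nor counts toward release. Event direction is the modal fall
label (ties → earliest observed), absorbing transition-frame misfires.
Severity has a single configurable breakpoint: duration ≥
`severe_after_s` (8 s) ⇒ SEVERE, else MODERATE. The debounce counts and
the 8 s cutoff are package choices; only the two-level grading and its
duration basis are given.

### Brightness normalization

Per RGB channel independently: compute the `p_low`/`p_high` percentile
values (linear interpolation between order statistics), clip the channel
to that range, map affinely so the percentiles land on
`[out_min, out_max]` (defaults 1/99 → [10, 245]), round half-up. A
constant channel maps to `out_min`. The output range stays inside
[0, 255] to avoid saturating the 8-bit rails. The 1/99 and 10/245
defaults are this package's choices; the operation, per-channel
treatment and sub-[0, 255] range are fixed by design. Rounding and
percentile conventions are pinned so independent implementations agree
bit-for-bit.

## The synthetic scenario generator

Real overhead fall footage with BODY_25 annotations is not publicly
available, so the test substrate is a seeded articulated-skeleton
simulator. A canonical upright skeleton (proportions of subject height
H: head 0.12 H, trunk 0.30 H, thigh and shin 0.25 H each, shoulder width
0.25 H, hip width 0.15 H) stands, falls with a cosine-eased profile over
a fall window, then lies still:

- **lateral falls**: rigid in-plane rotation about the ankle midpoint to
  ±90°;
- **forward/backward falls** happen out of the image plane; their 2D
  signature is modeled as foreshortening — every keypoint's height above
  the ground line compresses to a factor 0.25 — plus head ordering: in a
  forward fall the face swings symmetrically past the neck (nose ends
  below it), in a backward fall it stays above. No 3D projection model
  is used: the classifier only sees 2D geometry, and these are exactly
  the cues its detectors read.

Ground truth comes from the generator's kinematic state, not from the
classifier: frames are labeled with the scenario direction once the
compression factor (which *is* the generated trunk-HD ratio) drops below
0.35 or the rigid rotation exceeds 45°; earlier transition frames are
NORMAL. Evaluation therefore scores lying-phase frames by default — a
mid-fall frame's "true" label is genuinely ambiguous — with an
`--include-transition` flag to widen it.

Corruption is applied after generation, from an independently seeded
stream: per keypoint per frame, group-wise dropout (confidence forced to
0, coordinates zeroed per the upstream missing-keypoint convention),
otherwise i.i.d. Gaussian jitter on both coordinates. Confidences are
drawn uniform(0.7, 1.0) before dropout. Scenario presets name the study
conditions: `near`/`far` set subject height 400/240 px (camera-distance
proxy); the lighting presets set jitter 1.0–1.5 px and face dropout 0.05
(normal) / 0.3 (overexposed) / **0.7 (dim)** — dim lighting is modeled
as losing 70% of face keypoints per frame, the canonical failure mode of
pose estimators on shadowed faces; the background presets only widen the
confidence spread to uniform(0.5, 1.0), since skeleton input abstracts
the background away. The 0.7 dim face-dropout rate and the near/far
heights are fixed study conditions; jitter magnitudes and the milder
dropout rates are this package's realistic-noise choices, set once.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: correlated keypoint errors (occlusion
drops whole limb chains together, not independently), confidence values
correlated with position error, identity switches in multi-person
scenes, camera motion, rolling-shutter or motion blur, sitting/crouching
confusers, and genuinely 3D fall kinematics. Results on the simulator
demonstrate internal consistency (parameter recovery under the stated
noise model), not field accuracy.

## Numerical choices

- Angle wrap (−180°, 180°], exact −180° → +180°.
- Coincident segment endpoints raise a degenerate-geometry error, which
  the feature extractor maps to an invalid feature.
- Median via `numpy.median` (mean of central pair for even counts).
- Per-sequence benchmark seeds are `base_seed + sequence_index`, and the
  corruption stream is seeded separately from the generation stream, so
  every detector method is evaluated on byte-identical inputs — this is
  what turns the disjunctive method's recall dominance from a tendency
  into a per-frame theorem.
- Problem sizes: the default scenario is 100 frames at 10 fps (standing
  from frame 0, a 30-frame fall starting at frame 20, lying thereafter);
  the bundled analyses use 50 sequences per direction for clean
  parameter recovery, 200 dim sequences for the dominance check, and
  100-sequence batches in the acceptance script.

## Known limitations

- Camera-frame left/right: if a deployment needs subject-frame
  directions, a facing estimate must be added upstream.
- Thresholds are calibrated to the simulator's kinematics; real
  deployments should re-fit `lying_hd_ratio` and the debounce counts to
  their camera geometry and frame rate.
- A backward fall with no visible face is indistinguishable from a
  forward fall under the trunk-based detectors (see cascade notes).
- Severity is a duration proxy only; it encodes nothing about impact.
- Single-person: multi-person frames are reduced to one subject by the
  highest-mean-confidence policy at load time.
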