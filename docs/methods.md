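# Methods

## Problem setting

The package operates on per-frame detection streams from a farrowing
pen: one lactating sow and up to ~12 piglets viewed from above, at
1920×1080 px and 10 fps in 30-second clips (300 frames). Each detection
carries a box (center, size, pixels; origin top-left, y down), a
confidence score in [0, 1], a class (sow or piglet), and optionally a
unit-norm appearance embedding (default 64-dim) from an external
re-identification head and an inter-frame displacement estimate from an
external motion head. No image data is consumed; detection, embedding
and displacement inference are out of scope by design.

## Association model

Detection confidence tracks occlusion: a piglet sliding under the sow
loses score smoothly and regains it on reappearing. The tracker
therefore partitions each frame's work by motion state.

**Admission.** Detections with score < `score_low` (0.2) are discarded
before matching; they are overwhelmingly clutter at this level.

**Stage 1 — continuously visible.** Active tracks are predicted one
frame ahead with constant velocity (the detector displacement when
supplied, otherwise the last inter-frame finite difference). Candidate–
detection pairs within a gate of `gate_factor · √(w·h)` of the
detection box (same class only) are claimed greedily in ascending
distance order. Nearest-first claiming, rather than detection-score
order, was chosen after observing that score-ordered greedy hands a
reappearing detection (whose own track is lost) the track of an intact
neighbor whenever that neighbor sits inside the gate but its own
detection has not been processed yet; distance-first claiming gives
every track to its closest detection and eliminated all such swaps. The
box-scale gate adapts to image resolution and animal size.

**Stage 2 — reappeared.** Stage-1 leftovers are assigned to lost tracks
(age ≤ `max_lost_age` = 30 frames) plus any stage-1-unmatched active
tracks by maximizing total score–time-weighted appearance similarity

    sim(i, j) = g(α_i) · β_i · cos(e_i, e_j),   α_i = t − n_i,

with the Hungarian algorithm (`scipy.optimize.linear_sum_assignment`).
`α` is the lost duration, `β` the track's last matched confidence, and
`g` a decay — `1/α` by default, `exp(−λα)` as an alternative — so a
detection preferentially revives the most recently seen look-alike, and
tracks that vanished with low (occluded) scores assert weaker claims.
The raw product `α·β·cos` would *grow* with lost duration, contradicting
its purpose of favoring fresh tracks; the decay form is exposed as
configuration rather than hard-coded. Assignments below
`similarity_floor` (0.0 — i.e. negative similarity) are dropped; pairs
lacking an embedding on either side are unavailable.

**Stage 3 — new or still-occluded.** Remaining detections split on
`score_high` (0.6). Confident ones found new tracks (embedding adopted,
zero initial velocity). Low-score ones enter a save-and-iterate pool for
`reserve_frames` (3) frames, participating in stage 1 at their stored
position; a pool box claimed by a later detection seeds a new track
containing both observations (which identity, if any, a reserved box
resumes is undecidable from appearance — identity recovery is stage 2's
job), and unclaimed boxes expire.

**Track lifecycle.** Matched tracks update center/box/score, refresh
velocity, and fold the detection embedding into an exponentially
smoothed, renormalized track embedding (momentum 0.9; smoothing
aggregates appearance over frames instead of trusting the last,
possibly occluded, view). Unmatched active tracks become lost; lost
tracks beyond `max_lost_age` terminate. Track ids are strictly
increasing and never reused. All tie-breaks are deterministic (lowest
id, then lowest detection index), so identical input and configuration
reproduce identical output bit for bit.

## Evaluation metrics

CLEAR-MOT matching per frame: correspondences persist while IoU ≥ 0.5
(MOTChallenge convention); the remainder is resolved by maximum-total-
IoU assignment; a ground-truth identity whose matched hypothesis
changes (relative to its last matched frame, gaps included) counts one
ID switch. MOTA = 1 − (FP + FN + IDs)/GT. IDF1 follows the identity-
measures protocol: one global bipartite assignment between ground-truth
and hypothesis identities maximizing per-frame box matches, then
2·IDTP/(2·IDTP + IDFP + IDFN). The per-target tracking rate is
ID-agnostic coverage — the fraction of a target's present frames in
which any hypothesis box matches it — chosen because published
per-animal rates near 1.0 coexist with identity switches, which an
identity-strict reading could not produce. FP/FN/IDs are reported both
as counts and as fractions of ground-truth boxes.

## Behavior recognition

A posture change stresses only nearby piglets, so analysis is restricted
to a stress zone: a disc around the sow centroid with radius equal to
her body length, estimated as the median of the larger box side per
frame (boxes are axis-aligned; the major axis is the only available
proxy for body length). Membership is any-frame, so piglets entering or
leaving mid-episode are assessed.

Per piglet over the shared frames: the sow–piglet center distance
series `CD`, its differences `D_t = CD_t − CD_{t−1}` (negative =
approaching — the sign convention that makes the distance geometry and
the final labeling rule consistent), and per-frame direction marks from
the angle `O_ps` between the piglet's displacement and the piglet-to-sow
direction, wrapped to [0, 360): toward (0) if the signed angle is within
±75°, away (1) if 105° < O_ps < 255°, else no clear direction (2).
Displacements are smoothed with a centered 3-frame moving average, and
magnitudes below 0.5 px/frame carry no direction (mark 2): sub-pixel
motion is body sway, not locomotion. An individual is *gathering*
(B = 0) iff mean(D) < 0 and the modal mark is 0, *dispersing* (B = 1)
iff mean(D) > 0 and the modal mark is 1, else *other*; modal ties
resolve to 2 (conservative — no label without clear evidence). The
group label is a strict majority (> N/2) of B = 0 (aggregation) or
B = 1 (dispersion), else other.

Confusion matrices (rows = predicted, columns = ground truth) report
per-class accuracy as diagonal/column-total and the total accuracy as
the unweighted macro-average of per-class accuracies; empty columns are
excluded from the average.

## Synthetic scenes

The simulator emulates the trajectory-level structure of pen video, not
its appearance. The sow performs a slow random walk (σ 0.5 px/frame) at
pen center with a ~300×130 px box whose aspect changes at a scripted
event frame (the posture-change proxy; posture classification itself is
out of scope). Piglets start on a ring 0.45–0.95 sow-body-lengths out
and rest (jitter σ 0.3 px) until the event; afterwards each plays a
scripted role: *aggregating* piglets (staged in the outer zone, since a
gatherer needs somewhere to gather from) move toward the sow with 15°
heading jitter at a pace that reaches the udder near clip end, so the
directed phase spans the episode, as in real response clips chosen
around the event; *dispersing* piglets (staged nearer the sow) move away
at 0.8–1.5 px/frame; *other* piglets keep resting. The event frame
defaults to 10% into the clip. The group label implied by the scripted
role counts (strict majority) is the episode's ground-truth label.

Detections derive from ground truth by a declared noise model only:
center jitter (default σ 2 px), box jitter (σ 1 px), per-identity fixed
unit embeddings with spherical noise (σ 0.05) renormalized, one uniform
false positive per frame with probability 0.02, per-detection misses
with probability 0.01, and true displacements attached. Scripted
occlusions ramp the score linearly from 0.55 down to a floor across the
window with 3 px extra center jitter, then recover — the qualitative
score collapse seen when a piglet is progressively covered. Frames
whose ramped score falls below the admission threshold become detection
gaps; a 6-frame ramp to floor 0.01 yields a 3-frame gap. With all noise
zero and no occlusions the stream equals the ground truth at score 1.0.

Defaults (12 piglets, 300 frames, 1920×1080, behavior-label mix
41/36/23 aggregation/dispersion/other across 100 episodes, posture-event
mix mapped aggregation→downward, dispersion→upward, other→rolling)
mirror the study conditions the package targets. All randomness flows
from a single integer seed through `numpy.random.default_rng`; derived
episode seeds stay below 2³¹.

What the simulator does **not** model: photorealistic appearance, box
aspect changes from piglet deformation, temporally correlated detector
jitter, detector-specific score distributions, or piglets leaving the
pen. Passing tests therefore demonstrate the correctness and the
qualitative robustness of the association and recognition logic under
the declared noise model, not detector-level performance on real video.

## Problem sizes and numerical choices

The test suite and the acceptance script run occlusion scenes at 200
frames (the scripted windows end by frame 170) and behavior episodes at
the default 300 frames; metric cross-checks use ≤ 5 identities × ≤ 30
frames where the brute-force reference assignment is exhaustive.
Assignment problems are solved exactly (scipy Hungarian); IoU ties in
CLEAR matching are broken by the assignment solver deterministically and
are measure-zero for continuous boxes. Embedding normalization rejects
zero vectors; a cancelling embedding blend falls back to the detection
embedding. Empty frames, empty streams and empty ground truth raise
explicit, typed errors rather than returning silent zeros.

## Known limitations

- Crowded reappearances: when animals pack within each other's stage-1
  gate (e.g. at the udder), a reappearing detection can still be claimed
  by a neighboring track before appearance evidence is consulted;
  identity errors after occlusion *with* severe crowding or deformation
  remain the dominant residual failure mode.
- The recognizer's direction statistic degrades when per-frame detector
  jitter exceeds true locomotion speed; resting piglets then cast
  near-random individual votes, and episodes whose true label is
  "other" are occasionally tipped to a spurious majority.
- The save-and-iterate pool resumes *positions*, not identities; a
  reserved box confirmed later always founds a new track id.
- Tracking-rate is coverage-based and deliberately blind to identity.
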