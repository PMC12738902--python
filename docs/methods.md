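# Methods

This note records the models, parameter choices and numerical decisions
behind `cabtrack`, and what the synthetic test conditions do and do not
establish about real field video.

## Tracking model

Each identity carries an 8-dimensional state
(cx, cy, a, h, vẋ, vẏ, ȧ, ḣ): box center, aspect ratio w/h, height, and
their per-frame velocities. Dynamics are constant-velocity with unit frame
step. Process and measurement noise standard deviations scale with the
current box height — weights 1/20 (position) and 1/160 (velocity), the
convention of the appearance-augmented SORT lineage — so uncertainty grows
with apparent target size. The four measured coordinates evolve as
decoupled position/velocity pairs; the test suite exploits this by checking
the x-center block against an independently written scalar filter to 1e-9.
When both noise weights are set to zero the filter is noise-free: initial
uncertainty is kept at unity and the innovation covariance is ridged at
1e-9 so updates remain well-posed, and the filter locks onto a noiseless
constant-velocity track exactly after two updates.

Association is a two-stage cascade per frame:

1. **Appearance stage** (confirmed tracks): cost is the minimum cosine
   distance between the detection embedding and the track's gallery (ring
   buffer, budget 100). Costs above 0.2, or pairs whose squared Mahalanobis
   distance in measurement space exceeds the chi-square 0.95 quantile at
   4 dof (9.4877), are forbidden. Matching proceeds in rounds of increasing
   `time_since_update` so recently seen tracks get priority; each round is
   solved exactly with the Hungarian algorithm (scipy's
   `linear_sum_assignment`, which breaks ties deterministically).
2. **IoU stage**: tentative tracks and confirmed tracks missed only this
   frame are matched to leftover detections on cost 1 − IoU, threshold
   IoU ≥ 0.3, with the same motion gate.

Whether appearance and IoU should be fused into one cost or staged was an
open design point; the classical two-stage cascade was chosen because it
keeps the appearance threshold and the IoU threshold independently
interpretable.

Lifecycle: a new detection spawns a tentative track; `n_init = 3`
consecutive hits confirm it; a tentative track that misses one frame is
dropped; any track unseen for more than `max_age = 30` frames is deleted
and its id never reused. Detections below confidence 0.5 are ignored. A
track's class label is the majority vote over its matched detection labels,
ties broken by the most recent label — the vote makes the crossing-time
label robust to single-frame misclassifications.

If no embeddings are supplied the cascade is skipped and association is
motion-gated IoU only (the CLI `track` subcommand exposes this).

## Counting rule

The gate is a horizontal segment from (xA0, y0) to (xB0, y0); default
placement is full width at y0 = 0.6 × frame height (configurable — the
placement is an operational choice, not part of the rule). An identity is
tallied exactly once, at the frame where its box center passes from
y < y0 to y > y0 with xA0 ≤ cx ≤ xB0, under the class label the track
carries at that frame. Only the downward direction counts (the direction
row targets traverse the view); an identity first observed below the line
can never be counted. The regression suite includes the known failure mode:
if an identity splits mid-crossing (track death + rebirth straddling the
line), both fragments can cross and the plant is double-counted — which is
precisely why counting is tied to the crossing event rather than to id
creation, and why tracking quality still matters.

## Counting metrics

For manual count ŷ and algorithm count y per (video, category) cell:

* per-video RMSE over its categories (n = number of categories, 3 here);
* per-category MAE and RMSE over videos (n = number of videos);
* cell MCA = 100·min(y,ŷ)/max(y,ŷ). The symmetric min/max form is used
  because it is the only reading consistent with every published cell this
  package reproduces (e.g. 96.4 = 163/169 where the prediction undershoots,
  90 = 18/20 where it overshoots); a one-sided ratio would exceed 100% on
  overshoot. A 0/0 cell has no defined MCA and is excluded from means.
* per-category MCA = mean of defined cell MCAs; overall average MCA = mean
  of per-video total-count MCAs.

The shipped four-video table regenerates every derivable published cell.
Two source quirks are flagged rather than reproduced: video 2's published
RMSE of 0.58 is inconsistent with its own error-free counts (the computed
value is 0), and the bare-root category RMSE √1.5 = 1.2247 prints as 1.22
at two decimals where the source shows 1.23 (double rounding); comparisons
are made within 0.01.

Average precision uses greedy confidence-ordered matching at IoU ≥ 0.5
(each ground-truth box absorbs at most one prediction) and all-point
interpolation over the monotone precision envelope; mAP is the unweighted
class mean.

## Classification loss and attention numerics

The combined loss is L = j·L_QFL + k·L_BCE, elementwise then batch-mean,
with L_QFL = −α_t·|y−σ|^γ·[(1−y)log(1−σ) + y log σ] and
α_t = y·α + (1−y)·(1−α). Defaults γ = 1.5, α = 0.3, j = k = 0.5.
Probabilities are clipped to [1e-7, 1−1e-7] before logs; the clip bound is
a numerical-stability choice. Identities pinned by tests: γ = 0 collapses
L_QFL to α_t·BCE; with α = 0.5, j = k = 0.5 the combined loss equals
0.75·BCE; the loss is γ-monotone at fixed moderate error and its σ-gradient
matches central differences.

Triplet attention operates on C×H×W tensors. Z-pool stacks per-position max
and mean over the leading axis into two channels. Each of three branches —
channel↔height swapped, channel↔width swapped, identity — applies
Z-pool → 2-in/1-out convolution (default kernel 7, zero padding 3, the
lineage default) → sigmoid, multiplies the (rotated) tensor by the map, and
rotates back; the output is the plain average of the branches. Rotation is
implemented as axis transposition (self-inverse, so orientation sign is
immaterial), and batch normalization is modeled as the identity so the
forward pass is self-contained. With all-zero kernels every map is 0.5 and
the output is half the input to one ulp — the algebraic anchor used in
tests.

## Appearance preprocessing and embeddings

Re-identification crops follow the square convention: the detector box is
clipped to the image, padded symmetrically with white (255) on the shorter
axis to 1:1 — seedling boxes cluster near square, unlike the 1:2 pedestrian
convention — and resampled to 128×128 with bilinear interpolation (odd pad
remainders go right/bottom; an already-square 128×128 patch passes through
bit-identically). Embeddings are unit-norm vectors of dimension 128 under
cosine distance; both follow the appearance-tracking lineage since no
dimension or metric is prescribed by the problem. Any provider can stand
behind the tracker; the synthetic provider assigns each identity a fixed
base direction (hash-seeded, process-stable) and draws
normalize(base + N(0, σ_e I)).

## Synthetic scenes: what they emulate and what they don't

`SceneConfig` defaults describe a quarter-scale 3840×2160 pass at ~4 px/cm:
frame 960×540, plant spacing 140 px and row spacing 180 px (the 35/45 cm
field layout), camera speed 5 px/frame (0.35 m/s machine speed at 30 fps),
box side ~64 ± 6 px with aspect jitter near 1:1, and state proportions
0.82/0.11/0.07 — the manual totals of the four scored field videos
(409/54/35 of 498 plants). Plants translate downward through a fixed frame
(only image-plane center motion matters to the counting rule, so no
projective geometry is simulated). Detection noise: each visible plant is
detected with probability 1 − miss_prob, corners jittered N(0, jitter_sd);
false positives arrive Poisson(fp_rate) per frame with random positions,
states and throwaway identities — they specifically stress the
tentative-track filter, which is the mechanism that suppresses them.
Embedding noise σ_e defaults to 0.05 per component. All randomness flows
from one seed through fixed substreams, so toggling one noise source leaves
the other draws unchanged and scenes are byte-reproducible.

These scenes exercise the association, lifecycle, gating, counting and
evaluation logic under controlled noise. They do not contain images, so
they say nothing about detector or embedding quality on real video:
illumination, mulch reflection, occlusion by soil clods, leaf wilting and
motion blur are all outside the generator. Passing the end-to-end checks
means the counting machinery is correct given detections of the modeled
quality, not that a deployed system achieves these accuracies.

## Problem sizes and checks

The end-to-end checks use a noise-free 20-plant pass (counts must be exact
with zero identity switches at IoU ≥ 0.5 against ground truth) and ten
moderate-noise passes of 50 plants (10% misses, 2 px jitter) whose mean
total MCA must stay at or above 95% — a band fixed when the pipeline was
first assembled. Assignment optimality is verified against exhaustive
permutation search for n ≤ 6; the Kalman recursion against an independent
closed-form scalar filter to 1e-9; AP against direct PR-curve enumeration
on toy sets of ≤ 8 predictions.

## Known limitations

* Counting is downward-only and single-line; region gates and bidirectional
  flows are out of scope.
* No camera-motion compensation: the simulator's fixed-camera/translating-
  target geometry matches the intended rig, not handheld video.
* The tracker is online and greedy per frame; no offline smoothing or
  re-linking of fragmented tracks.
* MOT-style tracking metrics (MOTA/IDF1) are not computed; tracker output
  is exportable in the annotation CSV format for external evaluation.
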