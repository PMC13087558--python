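# Methods

This note records the modelling assumptions, default parameters, generator
design, and numerical choices behind `cstt`, and what the test suite does
and does not establish.

## Problem setting

Four activities are classified from fixed-length motion windows recorded in
a seated care-facility context: sitting (0), eating (1), stand up (2),
trying to stand up (3). Each window carries 17 COCO-17 2-D key points per
frame with confidences, one 64×64 depth heatmap per frame (values in
[0, 1]), and the subject's care level — an integer 1–5 quantifying
assistance needs for meals, bathing, excretion, movement and dressing,
grouped as low (1–2), mid (3), high (4–5). Two domain facts shape
everything downstream:

1. high-assistance subjects are predominantly immobile, so stand-up-type
   activities are structurally absent from the high group (enforced at data
   validation, generation, and reflected as N/A cells in similarity
   tables);
2. motion alone is ambiguous across care levels — eating and trying to
   stand up share a forward lean with extended hands — which is the
   motivation for conditioning the classifier on the care level.

## Architecture

Defaults: latent dimension d = 64, 4 attention heads, 2 temporal encoder
layers, feed-forward width 128, dropout 0.1, window T = 16 frames, heatmap
patch 8 (so T_p = 64 patch tokens), positional-encoding base ρ = 10 000.
This configuration has ≈ 0.12 M parameters — deliberately an order of
magnitude below a deployed-scale model of the same shape — so that full
training runs fit in CPU test budgets.

Choices the architecture description leaves open, fixed here:

- **Keypoint normalization.** Coordinates are divided by the frame size and
  centered on the hip midpoint per frame. This makes the skeleton features
  invariant to seating position; only confidences are stored, not used (the
  keypoint embedding consumes exactly the 34 coordinate values).
- **Heatmap embedding.** The "3-D convolution" over a 1×64×64 input is
  read as a per-frame spatial convolution (temporal kernel 1): a 3×3
  convolution with 2 output channels followed by 8×8 patchification and a
  linear projection of each flattened patch. Channels and kernel size are
  free parameters; 2 channels keep the CPU cost low.
- **Care embedding.** The scalar level is rescaled to (c − 3)/2 ∈ [−1, 1]
  before projection so the conditioning input is centered.
- **CAM block.** The care embedding is the sole attention query; keys and
  values are the concatenated keypoint + heatmap tokens. One CAM layer per
  frame, followed by a residual two-layer ReLU MLP on a layer-normalized
  input (pre-norm placement). The ReLU choice and the single CAM layer are
  defaults where the block structure is otherwise unspecified.
- **Temporal encoder.** Standard pre-norm encoder layers (self-attention +
  residual FFN, layer normalization without learned affine parameters).
  Zero layers degrade gracefully to the identity.
- **TSTT baseline.** Identical network with the care query replaced by a
  learned care-independent token; a variant (`tstt+c`) instead appends the
  care embedding to the key/value set, giving the care-as-plain-feature
  comparison. Partial-skeleton modes zero 30 % of the joints, the subset
  fixed per sample by a stable seed.
- **Prediction ties** break to the lowest class index.

The model runs on a minimal reverse-mode autodiff over NumPy
(`cstt.autograd`), float64 by default; training casts parameters to float32
for speed. Every primitive is verified against central finite differences,
and the whole forward pass against an independent plain-NumPy
reimplementation (tolerance 1e-6).

## Training protocol

Batch size 8, initial learning rate 0.001, weight decay 0.0005, 25 epochs —
the published deployment hyperparameters. Where the protocol is silent, the
defaults are: Adam with decoupled weight decay, constant learning rate (no
schedule), unweighted cross-entropy (no class rebalancing — the natural
imbalance is part of the problem), no validation split or early stopping,
windows of 16 frames with stride 8 as the training unit. The **cross-day
split** assigns whole recording sessions to train or test, greedily toward
an 80/20 sample fraction, deterministically given the seed; leakage is
asserted before every run. The (dataset seed, split seed, init seed) triple
fully determines a single-threaded run.

## Similarity statistics

- **Joint angles** (for MPJAD) are defined at each joint with two incident
  limb bones under the COCO-17 topology — shoulders, elbows, hips, knees —
  as the interior angle between the inbound and outbound bone vectors;
  endpoint joints (nose, eyes, ears, wrists, ankles) are NaN-masked and the
  averaging denominator renormalizes to defined entries. Zero-length bones
  also give NaN. This is the only per-joint angle definition consistent
  with 2-D key points.
- **MPJAD** averages |Δθ| over the intersection of frame indices (the
  common prefix after truncation to the shorter sequence) and unmasked
  joints; pairs pool over all cross pairs of two sample sets.
- **Cosine dissimilarity** flattens keypoint sequences after truncating a
  pair to the common minimum length.
- **HOG** uses the canonical configuration: 8×8-pixel cells, 2×2-cell
  blocks, 9 unsigned orientation bins, L2-Hys normalization
  (scikit-image). A constant image has a zero descriptor; its similarity is
  undefined and raises rather than returning a number. The image compared
  is each sample's temporal-mean heatmap — an explicit choice, since the
  comparison input is otherwise unspecified.
- **Tables** report raw statistic values averaged over cross pairs (pool
  capped at `max_pool` samples per cell for tractability); an optional
  min-max normalization flag is off by default. Cells whose group lacks the
  activity are N/A. Raw values are therefore not directly comparable to any
  externally rescaled similarity tables.

## Synthetic data generator

The generator emulates the statistical structure of care-facility motion
data, not its appearance. Skeletons come from hand-designed parametric
archetypes in a virtual 640×640 frame (frontal view): sitting is a static
seated pose; eating hovers the trunk forward over the tray with both hands
extended while the right wrist cycles twice to the mouth; trying to stand
leans the trunk forward (the same hover magnitude as eating — the source of
the real-world confusion) with a partial (45 %) hip rise; stand up is a
full logistic sit-to-stand transition. Depth heatmaps are rendered from the
skeleton as Gaussian joint blobs (σ = 1.6 px) plus limb segments (σ = 1.1
px) on the 64×64 canvas (scale 1/10), peak-normalized to 1.

Care-level modulation (generator defaults, not measured estimates):
amplitude × (1 − 0.15 (c − 1)), forward lean 0.08 (c − 1) rad, plus small
per-subject jitter drawn once per subject — so for a fixed subject seed the
modifiers are monotone in the care level. Tremor is white positional noise
(default σ = 2 px). A **confusability dial** λ ∈ [0, 1] blends the eating
and trying-to-stand trajectories toward each other (by λ/2 each) for
mid-group subjects, raising their HOG similarity monotonically; default
0.6. The default world uses the study cohort's care-group proportions
(low 35 %, mid 51 %, high 14 %) and per-subject class counts 4/4/2/1 with
trying-to-stand rarest; high-assistance subjects get sitting/eating only.
Each (subject, class, repeat) triple draws from its own named random stream
keyed off the master seed, so inserting samples never perturbs existing
ones. Samples are spread over 5 global recording sessions with every
multi-sample subject covering at least two, so cross-day splitting is
meaningful.

Two stated worlds used by the tests:

- `separable_spec` — zero tremor, dial 0: a nearest-centroid classifier on
  flattened keypoints is perfect within each care group, so a model that
  fails to fit it is broken (learning-sanity ceiling).
- `interaction_spec` — mid-group subjects perform the eating and
  trying-to-stand archetypes *swapped* relative to the low group, with the
  care-dependent posture modulation switched off: motion alone cannot
  disambiguate the confusable pair and the care level is the only
  disambiguating signal. This isolates exactly the care × motion
  interaction the care-aware attention is for.

What a green test does **not** establish: the generator has no camera
model, occlusion, caregiver interaction, multi-person scenes or realistic
depth, and its motion amplitudes are stated defaults rather than estimates
of facility data — so results on it bound implementation correctness and
the value of care conditioning *in the stated world*, not clinical
performance.

## Evaluation conventions

Macro precision/recall/F1 exclude classes absent from the ground truth
(NaN per class) — the high-care group structurally lacks classes 2–3.
One-vs-rest ROC uses rank-averaged ties, making the trapezoidal AUC equal
the pair-counting definition (asserted against a brute-force oracle);
micro-AUC pools all (sample, class) decisions. Cumulative gain sorts by
descending class probability and reports the captured-positives fraction
per inspected fraction. Confusion matrices are row-normalized with absent
rows reported as structurally absent rather than zero. The attention export
averages the care query's weight mass per token group (keypoint token vs.
heatmap patches) per care level; rows sum to 1 by softmax normalization.

## Numerical notes and limitations

- Softmax subtracts a detached per-row maximum; cross-entropy clamps at
  1e-12. Layer normalization uses ε = 1e-5 and no affine parameters.
- Float32 training changes results vs. float64 at the usual rounding level;
  determinism holds per dtype on a single thread.
- Heatmaps quantize to 16-bit PNGs on disk (max round-trip error
  1/65535); keypoint CSVs use a round-tripping float format.
- The windowing of continuous recordings into clips, and the clip length
  itself, are not externally specified; 16-frame windows with stride 8 are
  package defaults, uniform within a run.
- Training at desk scale (tens of subjects, ≈ 10³ windows) is the intended
  regime; the implementation is memory-bandwidth-bound and has no GPU path.
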