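# Methods

`gaitpd` implements a complete computational pipeline for screening
Parkinson's disease (PD) from dual-view gait videos that have already been
converted to 2-D skeletal keypoints by an external pose estimator. This
note records the model, the choices behind every tunable, and what the
synthetic test bed does and does not establish.

## Problem setting and data model

A recording is a pair of synchronized keypoint sequences — one frontal,
one lateral camera — at 30 fps, each frame holding 17 COCO-layout joints
as (x px, y px, confidence). Eyes and ears carry no gait information and
are dropped, leaving 13 joints (nose, shoulders, elbows, wrists, hips,
knees, ankles). All coordinates follow the image convention (y grows
downward) by default; a `y_axis` flag flips the elevation sign for y-up
data.

The classification unit is the **single step**: the span from one
right-foot landing to the next left-foot landing. Landings are local
minima of the ankle's elevation, which the lateral view measures directly.

## Single-step segmentation

1. **Smoothing.** The lateral ankle-y series is filtered with a
   Savitzky–Golay filter (window 45 frames, polynomial order 6). SG
   smoothing is exact on polynomials up to its order and preserves the
   *positions* of extrema, which is the property that matters here; edges
   use a polynomial fit on the truncated edge window rather than padded
   data, because landings can occur near the bout boundaries.
2. **Landing detection.** Local minima of the smoothed elevation are
   found by scanning windowed extrema (neighbourhood 30 frames) on the
   negated curve, rejecting candidates whose peak prominence falls below
   `mean_height / 20`, where `mean_height` is the average per-frame
   head-to-midfoot pixel distance. Tying prominence to apparent body size
   makes the threshold camera-distance invariant and suppresses flat
   ("stable") regions. Candidates closer than 30 frames are resolved
   greedily by prominence, earlier frame winning ties (determinism).
   Prominence at the first/last frame is computed one-sided instead of
   being rejected outright.
3. **Pairing and gating.** Each right landing is paired with the first
   later left landing that precedes the next right landing; unpaired
   starts are dropped. Steps shorter than 20 or longer than 120 frames
   are discarded (the population average is ~50 frames; the gate guards
   against missed detections merging cycles). A step is also dropped if
   it intersects a *stationary span* — frames where the smoothed
   elevation's peak-to-trough amplitude over a 30-frame sliding window
   stays below the prominence threshold (the subject is standing). The
   resulting frame boundaries are applied to both views, which are
   temporally aligned by recording.

## Normalization

Per step and per view, with statistics over all frames and all 13 joints
of the step:

    x' = (x − mean(x)) / (max(y) − min(y))
    y' = (y − min(y))  / (max(y) − min(y))

so y' ∈ [0, 1], mean(x') = 0, and the common divisor preserves the aspect
ratio; the transform is invariant to translation and uniform scaling of
the raw pixels (camera distance). Confidences are untouched at this
stage. Steps are then brought to exactly 50 frames by piecewise-linear
interpolation on a uniform grid including both endpoints — used in both
directions rather than trimming long steps, for determinism and endpoint
preservation (a `trim` mode exists). Finally the assembled dataset is
z-scored per feature column (39 columns = 13 joints × x/y/conf,
view-specific), with mean/sd fitted on the *training folds only* and the
stored statistics reused for validation and inference. Columns that are
constant in training pass through centred.

The model input per view is a (50, 39) matrix.

## Network

Two weight-independent streams (frontal, lateral) of four layers each.
Layers 1 and 3 are post-norm transformer blocks (3-head scaled
dot-product self-attention, feed-forward width 64, dropout 0.2); layers 2
and 4 are Mamba-2-style state-space blocks. After every layer the streams
exchange information through bidirectional cross-attention: both
directions are computed from the pre-exchange features and added
residually, so the exchange is symmetric and order-free. Final stream
features are mean-pooled over time, concatenated (78 dims) and classified
by a linear + softmax head (2 classes; PD is positive).

### State-space block

The temporal core is the scalar-per-head SSM

    h_t = a_t h_{t−1} + B_t x_t ,   y_t = C_t^T h_t ,

with per-timestep decay `a_t ∈ (0, 1)` (scalar per head times the
identity), and input/output maps `B_t, C_t ∈ R^32` shared across the 3
heads. Unrolled, the map x → y is multiplication by a lower-triangular
semiseparable matrix `M`, `M[j,i] = C_j^T (∏_{k=i+1..j} a_k) B_i`. Three
routes compute it:

* `ssm_scan` — the literal recursion (reference);
* `ssm_materialize` — dense `M` (O(T²) oracle, guarded to T ≤ 256);
* `ssd_forward` — the chunked semiseparable algorithm used in training:
  the sequence is split into chunks of 10 frames; within-chunk terms use
  a dense masked product, across-chunk terms pass a per-head rank-N state
  with scalar decays. All routes agree to 1e−5 on random instances (a
  core test surface).

Around the SSM: an expansion-1 input projection, a kernel-1 depthwise
convolution, SiLU, data-dependent parameter generation
(`a_t = exp(−softplus(dt_t)·softplus(a_base))` with `dt_t` linear in the
input; `B_t`, `C_t` linear), a SiLU-gated output projection, dropout, and
a post-norm residual. These internals follow the standard scalar-decay
design of the architecture family; the scalar-times-identity structure is
what makes the semiseparable factorization valid.

## Objective

    L = L_w + λ1·L_d + λ2·‖W‖₁ + λ3·‖W‖₂²
    (w1 = 0.9, w2 = 1.1, λ1 = 0.01, λ2 = 1e−4, λ3 = 1e−3)

* `L_w`: class-weighted cross-entropy, mean over the batch (a mean rather
  than a sum keeps the λ scale independent of batch size). w1 weights
  the PD-label (y = 1) term and w2 the HC-label term; the tuned values
  are w1 = 0.9, w2 = 1.1.
* `L_d`: mean over the four layers of the squared maximum mean
  discrepancy between the two streams' post-exchange features, clamped at
  zero per layer (the unbiased estimator can be slightly negative; a
  square root would have an unstable gradient at 0). Features are
  flattened per sample (time × dim); the Gaussian kernel bandwidth
  follows the median heuristic `γ = 1/median(‖Z_i − Z_j‖)²` on the pooled
  batch, recomputed per batch per layer and treated as a constant w.r.t.
  gradients. Batches larger than 64 are subsampled to 64 points per view
  for this term: the kernel is O(n²d) with d = 1950, and a 64-point
  unbiased estimate regularizes just as well at a fraction of the cost.
* `‖W‖` terms run over weight matrices only (biases, normalization gains
  and per-channel vectors excluded).

## Training protocol

AdamW (β₁ = 0.9, β₂ = 0.99, decoupled weight decay 0 — the explicit
L1/L2 terms play that role), global gradient-norm clip 1.0. The full
protocol is batch 3072, 1000 epochs with a piecewise learning rate:
linear warm-up 1e−8 → 1e−4 over epochs 0–200, constant to epoch 600,
linear decay to 1e−6 at epoch 1000 (cosine decay available). Evaluation
runs every epoch on the held-out fold; the checkpoint with the best
validation F1 is kept.

Cross-validation is grouped by subject: folds partition subjects (never
samples), balancing subject counts and class ratio by greedy assignment
(minority class first, descending sample count, seeded tie-shuffle), so
no individual contributes steps to both training and validation of a
fold. Z-scoring statistics are fitted per fold on its training portion.
Metrics (accuracy, precision, recall, F1 in percent; rank-based AUC with
ties counted ½) are computed per step sample, reported per fold and as
the arithmetic fold mean; a subject-level majority-vote summary is also
available.

**Desk scale.** The test suite and the acceptance script run a reduced
configuration chosen to finish on one CPU: ~60-subject cohorts with 25 s
walking bouts (~5–6 steps each), 3 folds, batch 256, 60 epochs with the
same 20/40/40 schedule shape at peak lr 2e−3 (the full protocol's 1e−4
over ~10² optimizer steps cannot train a fresh network). The null
calibration uses 90 subjects, 16 s bouts and 24 epochs, and reports the
AUC of validation predictions pooled across folds — the pooled estimator
concentrates better than per-fold means, and with ~340 steps over 90
subjects the ±0.05 chance band is still a statistically tight check.

## Prior-information head

Seven physiological priors (sex coded +1 male / −1 female, age, height,
weight, BMI, shoe size, mean single-step duration; BMI recomputed from
height/weight when absent) are z-scored with training-subject statistics
and passed through a bias-free 7 × 2 linear map. The adjustment is added
to the frozen model's *softmax output* and renormalized by a final
softmax — implemented literally, with a `logit` mode as the conventional
alternative. Only the 7 × 2 matrix is trained (500 epochs by default,
same class-weighted loss with L1/L2; the stream-discrepancy term has no
analogue here). Because inputs are standardized and the map has no bias,
the column difference (PD − HC) of each row is directly interpretable as
that prior's signed influence on the PD decision; `weight_table()`
exports it.

## Synthetic gait generator

Clinical gait recordings are not distributable, so the package ships a
generator that emulates the study conditions: dual synchronized views at
30 fps, stationary prefix/suffix pads (60 frames), ~0.72:0.28 HC:PD
cohort imbalance, and single steps averaging ~50 frames. Kinematics are
phenomenological: each foot follows a lift curve
`amp·|sin(φ/2)|^0.7` (one ground contact per gait cycle with a sharp
final descent, emulating the fast approach before heel strike — this
sharpness is what makes landing frames well-defined under noise), with a
half-cycle phase offset between feet, a rigid vertical body stack with
bob, arm/leg swing, an initiation/termination envelope of half a cycle,
per-frame Gaussian "tremor" noise on all joints, and Beta-distributed
confidences. The frontal view adds lateral sway and a linear
distance-dependent scale (subject approaching the camera), so the two
views' feature distributions genuinely differ and the MMD term is
non-trivial. Exact landing frames are recorded as ground truth.

The PD phenotype scales with an `effect_size` knob: stride amplitude
×0.55, step length ×0.60, cadence ×0.90 (slightly longer step duration),
tremor +1.2 px, sway ×1.3 at effect 1; priors shift correspondingly
(age +6.9 y, weight −2.9 kg). Effect 0 produces statistically identical
classes (the null cohort).

What passing tests on this generator shows: the pipeline's *computation*
is correct — segmentation recovers known boundaries, normalization has
its invariants, the network trains, grouping prevents leakage, and a
separable signal is found while a null signal is not. What it does not
show: performance on real clinical gait, which involves pose-estimator
failure modes, turning, occlusion, heterogeneous phenotypes and much
subtler class differences than the synthetic effect. The clinical
headline numbers of the source study are not reproducible from this
package for that reason; only their internal arithmetic is.

## Numerical choices and degenerate inputs

* Computation runs in float32 on a small tape-based reverse-mode
  autodiff core (NumPy); softmax and layer norm are fused single-node
  ops, and backward frees intermediate buffers as it walks the tape.
* SSD guards: decays must be strictly positive on the chunked route
  (guaranteed by the exp parameterization); masked entries are zeroed
  *before* exponentiation so the upper triangle cannot overflow.
* Degenerate steps (flat y-range, single frame) are rejected, not
  imputed; singleton mini-batches are skipped (the unbiased MMD needs
  n ≥ 2); σ = 0 columns pass through centred with a flag; probabilities
  are clamped to [1e−7, 1 − 1e−7] inside the cross-entropy.
* All randomness flows through seeded `numpy` generators: cohort
  generation, fold assignment, weight init, dropout, batching, MMD
  subsampling. Same seed, same run.

## Known limitations

* Kernel-1 convolution only (matching the tuned configuration); larger
  depthwise kernels are not implemented.
* Frontal-only segmentation is deliberately absent (out of scope; the
  lateral view defines landings).
* The generator's confidence channel is i.i.d. Beta noise, uncorrelated
  with occlusion events — adequate for exercising the 39-feature
  contract, not for studying confidence-aware modeling.
* Training speed is CPU-bound NumPy; the full 3072 × 1000-epoch protocol
  is supported but intended for patient hardware.
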