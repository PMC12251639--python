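# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `pulsemil`, and what the tests do and do not establish.

## Problem setting

A session is a 30 Hz blood-volume-pulse (BVP) waveform with one 1–9
self-report rating per affect dimension (arousal, valence). Ratings are
binarized at the scale midpoint (≤4 low, ≥5 high); ratings are integer so
the midpoint never ties, and non-integer ratings are rejected rather than
rounded. The waveform is cut into non-overlapping 128-sample chunks (~4 s);
trailing remainder samples are dropped, not padded. Splitting is
session-level 80/10/10 by a seeded shuffle; val and test sizes round
half-up and train takes the remainder (527 sessions → 421/53/53). Only the
subject-mixed split is implemented; a subject-disjoint mode is out of scope.

## Model

**MTDE.** Chunks are encoded channels-last by a stem of two k=3
convolutions (1→16→16), then three dilated branches on the stem output:

| branch | layers | receptive field |
|---|---|---|
| short  | 16→64 k2 d1            | 6 frames = 0.2 s |
| medium | 16→32 k3 d15, 32→64 k2 d31 | 66 frames = 2.2 s |
| long   | 16→32 k3 d31, 32→64 k3 d31 | 129 frames = 4.3 s |

The receptive field of a stride-1 stack is `1 + Σ (kernel−1)·dilation`;
the three spans sit on the HF/LF/VLF heart-rate-variability timescales.
Branch outputs are concatenated (192 channels), fused by a 1×1 convolution
to 256 channels, and pooled over the 128 time steps by softmax temporal
attention (affine 256→1 scorer). All convolutions are stride 1 with
same-length zero padding and GELU activations (the tanh approximation,
which is an order of magnitude cheaper on CPU than the erf form and agrees
with it to ~1e-3); there are no normalisation layers — their affine
parameters would break the exact parameter budget.
These layer widths were chosen to satisfy simultaneously the target
receptive fields (0.2 / 2.2 / 4.3 s) and the target parameter budgets
(164,996 inference / 197,892 training) exactly; the per-module sums are
asserted in the tests.

**Attention.** The scorer is a 2-layer MLP (256→81→1, GELU). Raw scores
are scaled by γ/(σ+ε) where σ is a running estimate of the per-session
score standard deviation (momentum 0.99, ε=1e-5, γ trainable, init 1).
The scale is applied with the current σ and σ is then updated; scaling is
per session, feeding one global running estimate. Scores become a
distribution via α-entmax, computed exactly by 50 bisection iterations on
the threshold τ ∈ [max((α−1)z)−1, max((α−1)z)] (bracket shrinkage ≈1e-15),
followed by renormalisation to |Σp−1| < 1e-9. The backward pass uses the
exact sparse Jacobian J = diag(s) − ssᵀ/Σs with s_i = p_i^{2−α} on the
support. α ≤ 1 routes to softmax only behind an explicit flag.

**Gated pooling.** h_pooled = Σ α_i (g_i ⊙ h_i), g_i = sigmoid(affine(h_i)).
The gate bias is initialised at +2 so gates start nearly open (~0.88):
the shared classifier is trained on raw chunk embeddings in phase 1, and
open gates keep the pooled vector on that scale at the phase-2 handover
instead of abruptly halving every feature.
Ablations: `attention` forces g ≡ 1; `average` additionally forces
α ≡ 1/T. Attention is always normalised within one session.

**Heads.** The classifier (256→47→2, GELU, softmax) is one parameter set
shared between the chunk-level auxiliary role and the session role — the
classifier "handover" between training phases is therefore an identity,
validated and logged. Only this sharing is consistent with the training
minus inference parameter gap being exactly the projection head's
256·128+128 = 32,896. The projection head L2-normalises, with an ε-floor
of 1e-12 on the norm for the degenerate zero vector.

## Curriculum

Defaults (epochs 15/15/21, i.e. 0–50; AdamW; batch of 8 whole sessions;
gradient clipped at global norm 5; cosine-annealed learning rate restarting
at each phase boundary, since each phase has its own base rate):

* **Phase 0** (lr 3e-4, wd 1e-4): supervised contrastive loss (τ = 0.1) on
  chunk projections — positives are chunks sharing the same binary label
  within the batch; up to 32 chunks per session enter the contrastive term —
  plus λ=0.01 times the negative entropy of the scorer's internal softmax
  attention. Trainable: encoder, scorer, projection.
* **Phase 1** (lr 2e-4, wd 5e-4): focal loss (γ=2, class weights = inverse
  training-class frequency normalised to mean 1) on the Top-K chunks of the
  scorer's entmax (α=1.5) attention, each chunk inheriting its session
  label; K = max(1, ⌈ratio·T⌉) with the ratio annealed linearly 0.9→0.3
  across the phase, ties broken toward the smaller index. The projection
  head is frozen. From two-thirds through the phase the gate parameters are
  unfrozen, but the session loss is *not* yet in the objective (they
  receive no gradient until phase 2; the unfreeze is bookkeeping that marks
  the transition).
* **Phase 2** (lr 1e-4, scorer at 0.1×, wd 5e-4): session cross-entropy
  only, through gated pooling with the pooling entmax α_g annealed linearly
  1.5→1.8 across the phase (epochs 30→50 at default lengths).

The scorer's α is fixed at 1.5 throughout (only the pooling α_g is
scheduled). Schedules are linear. One model is trained per affect
dimension. The best-validation-accuracy checkpoint is retained (later
epochs win ties), together with the α_g in force at that epoch for
inference. Curriculum ablations: `no-topk` pins the ratio at 1.0,
`no-aux` drops phase 1, `no-supcon` drops phase 0, `direct` trains phase 2
only. When the phase lengths are compressed (see below) all schedules
stretch or shrink with their phase.

Numerical substrate: the model runs on a small reverse-mode autograd over
numpy arrays (float32 parameters), with every operator's gradient checked
against central finite differences in the test suite. Entropy uses the
convention 0·ln 0 = 0 (implemented with an additive 1e-30 inside the log);
cross-entropy clamps zero probabilities at 1e-12 with a warning; a
non-finite training loss aborts with a diagnostic.

## Synthetic data

The generator emulates what matters to this architecture and nothing more:

* beat times from an integrate-to-threshold pulse train whose inter-beat
  interval is 60/HR plus sinusoids at the HRV band centres — HF 0.25 Hz
  (amp 0.03 s), LF 0.10 Hz (0.04 s), VLF 0.02 Hz (0.05 s), random phases;
* a two-lobe pulse template (systolic Gaussian, sd 60 ms; dicrotic lobe at
  0.35 relative amplitude, 250 ms delay), unit amplitude;
* high-arousal "events" confined to whole 128-frame chunks: +20 bpm heart
  rate and ×1.5 pulse amplitude inside event chunks (chosen as a clearly
  separable caricature of a sympathetic burst; the amplitude and shape of
  real emotional BVP events are not well characterised, so these are
  synthetic conventions, not measured values);
* white noise (sd 0.05 of pulse amplitude) and Poisson motion artifacts
  (1/min, ±5× amplitude, 3 samples wide);
* baseline heart rate uniform in 55–75 bpm per session; high-arousal
  sessions get ratings 5–9, low 1–4; valence ratings are uniform 1–9 and
  carry no physiological signal.

It does **not** emulate: rPPG extraction noise structure, subject identity
effects, respiration coupling, valence physiology, or gradual (non-chunk-
aligned) affective drift. Passing the benchmark therefore shows the
architecture and curriculum can find and exploit sparse, weakly labelled
events in plausible cardiovascular noise — not that it reaches any
particular accuracy on real affective corpora.

## Benchmark problem sizes

The end-to-end benchmark trains on 200 sessions × 20 chunks (86 s), three
event chunks per high-arousal session, 50/50 classes, with the curriculum
compressed to 5/5/10 epochs at batch 8 — small enough for a single CPU
while leaving every mechanism (all three phases, both annealing schedules,
the handover) active. Expected behaviour, asserted in the acceptance
tests: test accuracy ≥ 0.90, entmax attention mass on event chunks ≥ 3×
the uniform share, and median entmax attention entropy below the softmax
median. The directional ablation comparisons (full ≥ direct, gated ≥
average pooling, 3 ≥ 1 branches; medians over seeds 0–2) keep 200 sessions
and the 5/5/10 epoch budget but shorten sessions to 12 chunks (52 s, two
event chunks): training-set size, not chunks per session, is what governs
whether the curriculum converges at this scale, so shortening sessions is
the cut that preserves a meaningful comparison while keeping twelve
training runs desk-scale. Branch-count ablation variants do not
meet the canonical parameter budget (their fusion width differs); that
budget is a property of the 3-branch canonical configuration only.

## Known limitations

* The canonical layer widths are one consistent choice among several that
  meet the receptive-field and parameter-budget constraints simultaneously;
  they are a reconstruction, not a transcription of a reference
  implementation.
* Training on the numpy autograd is single-threaded BLAS; wall-clock is
  minutes at benchmark scale, and no GPU path exists.
* The σ-γ scale uses one global running σ; per-head or per-batch variants
  were not explored.
* `average`-pooling mode still trains the scorer (its parameters simply
  receive no gradient through pooling in phase 2).
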