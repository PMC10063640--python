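# Methods

## Problem setting

The package studies feedback systems that assess a performer's skill from a
short activity clip (the motivating domain is robot-assisted suturing:
20–30 s needle-handling or needle-driving clips at 1 frame/s) and
*explain* the assessment by scoring each frame's importance.  Two questions
are quantified:

1. **Reliability** — how well do the AI's frame-importance scores align
   with the time segments human experts mark as relevant?
2. **Fairness** — is that alignment equally good across sub-cohorts of
   performers (an uneven alignment is an *explanation bias*)?

and one intervention is implemented: **TWIX** (training with explanations),
which adds a supervised per-frame importance head to the skill model so
human explanations become a training signal rather than only an evaluation
target.

## Annotation model

A rater's explanation annotation is a set of half-open time segments
`[start, end)`; segments are canonicalized (sorted, overlapping/touching
segments merged) before use.  Rasterization to a per-frame binary mask uses
the frame-midpoint rule: frame `t` (0-based, covering `[t/fps, (t+1)/fps)`)
is relevant iff its midpoint lies in some segment; `T = round(duration·fps)`.
Multi-rater explanation masks aggregate by elementwise intersection (the
conservative default: a frame counts only if every rater flagged it; union
is available).  Skill scores aggregate by the minimum — the most severe
assessment wins.  Rater agreement is measured by mask IoU; two all-empty
masks are defined to agree (IoU 1.0, with a warning) since "nothing is
important" is a shared judgement, although the annotation protocol (only
low-skill clips are annotated) makes this case rare.

Normalized-time heatmaps map frame `t` of a length-`T` mask to `(t+0.5)/T`
and average pooled frame values in 100 equal-width bins over [0, 1]
(configurable); unpopulated bins are filled by linear interpolation between
populated neighbours, clamping at the edges.  The bin count and fill rule
are free choices — clips differ in length, so some resolution/coverage
trade-off is unavoidable.

## Synthetic data: what it emulates, and what it does not

Real data for this problem are private surgical videos; the generator
produces sequences with the *statistical structure* the analysis depends
on, not realistic video features:

* per-sample T×D Gaussian background features (`noise_sd`, default 1.0,
  D = 8) in `M = 2` streams — a base stream and a motion-like stream equal
  to the frame difference of the base plus noise;
* "events": non-overlapping segments (default 1.5–2.5 s) placed uniformly
  at random, within which a fixed unit-norm motif vector scaled by
  `event_amplitude` (default 5.0) is added to the base features.  The
  default amplitude puts the study in an easy, high-signal regime where a
  linear read-out separates event from background frames;
* skill classes driven by the event count, mirroring criteria of the form
  "three or more needle grasps ⇒ low skill": class 0 (low) draws 3–5
  events, class 1 (high) 1–2; a three-class variant uses 3–5 / 2 / 1.
  Classes are assigned in balanced proportion (counts differ by ≤ 1);
* ground-truth explanation mask = the event frames.  With the default
  durations (20–30 s) and event geometry, the expected low-skill mask
  prevalence is ≈ 0.30, matching the reported real-data figure that about
  30% of a clip is typically marked important;
* two raters per sample whose annotations jitter the true segment
  boundaries with zero-mean Gaussian noise (`rater_jitter_sd`, default
  0.2 s).  The default keeps pairwise rater IoU above the 0.8 agreement
  level that trained human raters reach; only low-skill samples are
  annotated;
* parent videos (16 samples per video, as in the instrumented training
  environment; 12 videos per site at the default desk scale) that share
  cohort covariates: a categorical `cohort` (a/b, balanced) and a numeric
  `caseload`;
* optional cohort effects — multiplying `event_amplitude` (model-driven
  degradation) or `rater_jitter_sd` (annotation-driven degradation) for one
  cohort — and whole shifted sites via config overrides with independent
  seed streams.  The motif direction is drawn from its own `motif_seed`,
  shared by all sites unless overridden: deployment sites represent the
  same underlying activity semantics under shifted acquisition conditions,
  not a different signal altogether.

What passing tests on these data do **not** show: anything about pixel
feature extractors, about temporal structure richer than
"motif-in-noise" (the events are exchangeable given their count), or about
real annotator behaviour beyond boundary jitter (no missed events, no
systematic rater bias).  The synthetic results validate the *pipeline and
metrics*, and reproduce directional findings, not the published magnitudes,
which come from private multi-hospital video.

## Model

Each stream is linearly projected to `model_dim = 16`, learned positional
embeddings are added (disable for permutation-equivariance testing), a
learned classification token is prepended, and `n_layers = 1` standard
pre-softmax transformer encoder layers (2 heads, FFN width 32, residual +
LayerNorm) are applied.  The token's output is the stream's video
representation; streams are averaged into `v`.  Frame representations
`h_t` are the final-layer outputs at the frame positions.

* **Attention explanation**: the final layer's token→frame attention row,
  averaged over heads, renormalized over frames, averaged over streams and
  min–max rescaled per sample.  Which layer/head combination best reflects
  the model's reasoning is genuinely open; final-layer head-average is the
  convention adopted.
* **TWIX head**: `ŷ_t = σ(w·h_t + b)` on the first stream's frame
  representations (configurable to the stream mean), zero-initialized so
  untrained output is exactly 0.5.

Training minimizes `L = L_InfoNCE(θ) + L_importance(ω)`.  The contrastive
term is the supervised InfoNCE over the batch's video representations
(cosine similarity, temperature 0.1, positives = same-class members,
per-anchor mean over positives, averaged over anchors).  The importance
term is binary cross-entropy of `ŷ_t` against the human mask, computed only
for annotated (low-skill) samples.

Two loss conventions deserve comment.  First, the published form of the
importance loss pairs `(1−y_t)` with `log ŷ_t`, which would train the head
to output *low* values on important frames — inconsistent with `ŷ` being
used directly as frame importance at deployment; the standard orientation
is implemented.  Second, the importance term as a plain per-frame *sum*
(≈ T·ln 2 ≈ 17 nats at initialization for a 25-frame clip) is an order of
magnitude larger than the contrastive term (≈ 2–3 nats) and, empirically,
dominates the shared encoder's gradients enough to *hurt* classification —
the opposite of the reported effect of explanation supervision.  The
training objective therefore normalizes each sample's importance term by
its frame count before averaging over annotated samples; the standalone
`importance_loss` function keeps the summed form.

Because training is purely contrastive, class probabilities come from a
nearest-class-prototype read-out: prototypes are the normalized class means
of training representations (refreshed each epoch, stored with the fitted
parameters), and `p(k|v) = softmax(cos(v, c_k)/τ)`.  Optimization is Adam
(lr 0.015, 12 epochs, class-balanced batches of 16) — sized for
minutes-scale CPU training; model selection picks the epoch with the best
validation AUC when a validation split is provided.

## Evaluation

Explanation scores are normalized per sample (min–max for attention
sources; TWIX outputs are already probabilities and pass through), then all
frames of a fold's annotated test samples are pooled into a single
score/mask pair — one precision–recall curve per fold rather than a mean of
per-sample areas, matching the one-curve-per-hospital presentation style.
AUPRC is right-step average precision over the distinct score values, no
interpolation; an all-negative mask is an error (reliability is defined on
annotated low-skill samples).  Classification uses ROC AUC (Mann–Whitney,
ties ½; macro one-vs-rest for K > 2).

Fairness stratifies the pooled per-fold AUPRC by a covariate: categorical
covariates partition by value; numeric ones are cut at a threshold
(default: the median of the provided values, the balanced-cohort
convention).  Sub-cohort reliability aggregates as the cross-fold mean;
**worst-case AUPRC** is the minimum across sub-cohorts and the **bias gap**
is max − min.  Folds where a sub-cohort has no annotated sample are skipped
for that sub-cohort (counted); a sub-cohort empty everywhere is an error.
Cross-fold summaries report mean, sample SD (n−1) and a normal-theory 95%
CI.

## Protocol

Monte Carlo cross-validation draws `n_folds = 10` *independent* random
splits (not a rotating partition).  Videos — not samples — are shuffled and
partitioned 70/10/20 into train/val/test, samples inherit their video's
set, and each set is then undersampled to exact class balance (balancing
after splitting preserves video disjointness).  The with- and
without-supervision training runs share each fold's seed (identical
initialization and batch order), so their comparison is a paired design
that isolates the effect of the importance term rather than training-run
noise; epoch selection on validation AUC considers trained epochs only and
prefers the latest epoch among ties, since tiny validation sets tie often
and the earliest tied epoch can carry an under-trained importance head.  Deployment evaluates every
fold's model on a held-out site's full data (inference only; balanced
draws for AUC); site metrics are per-fold metrics averaged, never averaged
predictions.  A master seed drives a spawned seed tree (generator, folds,
per-fold training, deployment draws), making `metrics.csv` byte-identical
across reruns.

The cohort-bias study (`run_bias_study`) regenerates its dataset per
replicate (default 10 replicates) with an injected effect — e.g. a ×3
rater-jitter multiplier on one cohort — trains with and without the
importance head, and reports each source's bias gap and worst-case AUPRC.
Replicates use 3–4 folds and a 14-video × 12-sample site by default: large
enough that the no-effect control's bias gap stays small relative to the
0.05 detection level, small enough for a ten-replicate study on one CPU in
minutes.

## Numerical choices and degenerate inputs

* Constant score vectors (no ranking information) normalize to 0.5
  everywhere with a warning; constant attention likewise.
* BCE probabilities are clipped to [1e-7, 1−1e-7].
* InfoNCE requires every anchor to have a same-class positive; batches are
  class-balanced by construction, and the loss raises otherwise.
* The InfoNCE log-sum-exp subtracts the detached row maximum for stability.
* Attention renormalization divides by the row sum after excluding the
  token's self-attention; a single-frame clip yields attention [1.0].
* Gradient correctness of the autodiff engine (numpy reverse-mode; the
  only nonstandard dependency choice, sized for this model family) is
  pinned by central finite differences at 1e-4 relative tolerance, with an
  absolute floor that tolerates FD noise on exactly-zero gradients such as
  softmax-invariant key biases.
* Event placement retries rejection sampling up to a bound before raising;
  rasterized-empty truths are re-placed (possible only for sub-frame
  events).

## Known limitations

* The encoder is one attention layer at toy width; it demonstrates the
  training dynamics and explanation read-outs, not production-scale
  capacity.
* The InfoNCE is the standard supervised-contrastive form; exact
  equivalence to the original system's prototype variant is not claimed.
* Pooled-fold AUPRC and per-sample-averaged AUPRC differ when sample
  lengths or prevalences vary strongly; pooling is the default, the
  alternative is a one-line change in caller code.
* The no-effect bias gap is positive by construction (it is a max − min of
  noisy means); it is small, not zero, and shrinks with fold count and
  cohort sample size.
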