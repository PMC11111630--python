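# Methods

## Model and procedure

The package trains a softmax classifier semi-supervised in three coupled
stages per run:

1. **Warm-up.** `warmup_epochs` epochs of supervised cross-entropy on the
   labeled set give the network enough accuracy for its predictions on
   unlabeled data to carry signal. Thresholds are frozen at their
   initialisation during warm-up.
2. **Self-feedback thresholds.** For every unlabeled batch the model's
   probabilities drive two EMA statistics: the global threshold `T_g`
   (EMA of the batch-mean max probability) and per-class thresholds
   `T_c(c)` (EMA of the batch-mean probability assigned to class `c`).
   Both start at `1/N_c`. The applied per-class cutoff is
   `T_c(c)/max(T_c) · T_g`: max-normalisation anchors the best-learned
   class at `T_g` and lowers the bar for classes the model is collectively
   unsure about — under class imbalance these are the rare classes, which
   is what re-balances selection.
3. **Selection and learning.** Samples whose max probability strictly
   exceeds their argmax class's cutoff are kept with the argmax as
   pseudo-label. The SGD step minimises
   `λ1·L_ce + λ2·L_T + λ3·L_f`, where `L_T` is pseudo-label cross-entropy
   averaged over the *full* unlabeled batch with the selection indicator
   inside the sum, and `L_f` is the focal loss `(1−p)^γ(−log p)` averaged
   over the *selected* subset. The two unlabeled terms deliberately share
   one selection of one batch; the redundancy (CE + focal on the same
   samples) is part of the method's design, not collapsed.

Assumptions: unlabeled data comes from the same class-conditional
distributions as labeled data; a sample's max predicted probability is a
usable (if biased) proxy for pseudo-label reliability; pseudo-label noise
that survives selection is tolerable because focal down-weighting limits
the influence of confidently-fit samples.

### Readings of the per-class update

The per-class EMA target admits two readings. The default ("expected")
uses the batch mean of the probability column for class `c` — the model's
expected prediction for that class — which is what lets rare-class
thresholds fall below `1/N_c` and drive the re-balancing. The alternative
("argmax_mean": mean max-confidence of samples whose argmax is `c`,
skipping classes absent from a batch) is available via
`per_class_mode="argmax_mean"`. Consequently the invariant
`T ∈ [1/N_c, 1]` holds for `T_g` (its update targets are max-probabilities,
which are at least `1/N_c`) but only `T_c ∈ [0, 1]` is guaranteed under the
default reading.

### Ordering and pairing choices

Threshold updates use the current batch's predictions *before* selection,
and the same batch is then selected with the freshly combined thresholds,
making each iteration self-contained. `t` counts unlabeled batches, not
epochs. Labeled and unlabeled loaders run in lock-step with the shorter
loader cycling (reshuffled every pass); in semi-supervised modes an epoch
is one pass over the unlabeled set, in `supervised_only` one pass over the
labeled set. Pseudo-labels are regenerated every iteration from the
current model — no frozen teacher, no caching. State updates are pure
(each returns a new `ThresholdState`); the trainer owns all mutation.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `ema_momentum` (λ) | 0.999 | EMA decay; standard for confidence EMAs — larger is smoother but slower to adapt. The desk-scale benchmark uses 0.99 so the EMA equilibrates within its ~800 iterations. |
| `lambda1, lambda2, lambda3` | 1, 0.5, 0.5 | objective weights; supervised term dominates, the two unlabeled terms share the remainder |
| `gamma` | 2 | focal exponent; 2 is the canonical choice — larger focuses harder on misfit samples |
| `fixed_threshold` | 0.95 | baseline-mode cutoff (fixed-threshold pseudo-labeling convention) |
| `epochs / batch_size / learning_rate / sgd_momentum` | 150 / 64 / 0.001 / 0.9 | full-scale defaults (lr 0.001 suits fine-tuning a pretrained deep backbone); the synthetic benchmark overrides lr to 0.05, the usual SGD scale for a small CNN from scratch, and trains 30 epochs |
| `warmup_epochs` | 5 | long enough for above-chance pseudo-labels at desk scale; configurable |
| `prob_floor` | 1e-7 | probability clamp for log-safety; value-level only |

All randomness (weight init, shuffling, flips, generators) derives from a
single seed, split into independent streams for init, the labeled loader
and the unlabeled loader, so modes consuming different amounts of
unlabeled randomness still see identical labeled batches.

## Backbone

`tiny_cnn` is a 3-block NumPy CNN (3×3 conv → ReLU → 2×2 max-pool twice,
3×3 conv → ReLU → global average pool, linear head; channels 8/16/32,
~6.5k parameters, 32×32 inputs) with hand-derived backprop (im2col
convolutions) and heavy-ball SGD. It exists so the whole algorithm is
exercisable and bit-reproducible on one CPU in seconds; it is a genuine,
gradient-checked network, not a mock. The classification head is a single
linear layer + softmax. The large ImageNet-era backbones are accepted
names that require an optional PyTorch runtime; nothing in the package or
its tests depends on them.

## What the synthetic generator emulates — and what it does not

`generate_image_dataset` reproduces the two properties of dermoscopy
collections that the method targets: (a) heavy class imbalance (the
default proportions follow the 7-class lesion-type frequencies of the
HAM10000 collection; the benchmark uses a 4-class .60/.25/.10/.05
profile) and (b) class-dependent appearance with controllable difficulty.
Each class is a parametric lesion — an ellipse on a skin-toned background
whose color, axes, orientation and border waviness are functions of the
class index scaled by `signal_strength` — plus per-sample center/size
jitter and i.i.d. Gaussian pixel noise (`noise_sd`). At
`signal_strength=0` all classes share one template, so the data is
unlearnable beyond the priors; learnability rises monotonically with
signal. Benchmark defaults `signal_strength=0.8`, `noise_sd=0.1` make the
task learnable but not trivial for 80 labels.

It does **not** emulate photographic texture, intra-class style shifts,
acquisition artifacts, or label noise in the *labeled* set. Passing tests
therefore demonstrate the algorithm's mechanics (selection balance,
threshold adaptation, the value of unlabeled data) under controlled
conditions — not clinical-grade performance on real dermoscopy.

`generate_confidence_stream` removes the model entirely: per-sample
max-confidence is Beta-distributed per true class (clipped into
`[1/N_c, 1)` so the designated slot is the argmax), the argmax is wrong
with probability `corruption_rate`, and the remaining mass is spread
uniformly over the other classes — the simplest valid simplex completion,
sufficient because only the max enters the threshold updates. These
streams test the threshold policies exactly, with analytically known
marginals.

## Numerical choices

- Strict `>` in selection; a max probability exactly at the threshold is
  excluded. Argmax ties break toward the lowest class index (and class
  ids follow alphabetical vocabulary order at the I/O boundary, which
  pins down that tie-break for datasets on disk).
- Probabilities are clamped to `[1e-7, 1−1e-7]` inside the losses;
  analytic gradients ignore the clamp (it is inactive at the logit
  magnitudes training produces) and are finite-difference-checked.
- Forward/backward in float32; probabilities and threshold state in
  float64. Max-pool backprop splits gradient equally across exact ties.
- Zero-denominator metrics (class never predicted/absent) report 0 with a
  warning; AUC for a class without both positives and negatives is
  excluded from the macro mean with a warning. AUC uses the midrank
  Mann–Whitney formulation (identical to trapezoidal curve integration,
  exact under ties).
- The headline aggregate for precision/recall/F1 is frequency-weighted
  (under which weighted recall ≡ accuracy); macro aggregates are reported
  alongside.

## Problem sizes

Desk-scale sizes were chosen so the full suite runs comfortably on one
CPU: the standard benchmark uses 80 labels / 2,000 unlabeled / 600 test
images at 32×32 for 30 epochs (batch 64, 3 seeds) for the ablation, and
1,500 unlabeled / 20 epochs for the 100/250/500-label sweep. The
threshold-policy analyses use model-free streams of 100–200 batches of
64.

## Known limitations

- Selection balance is measured against the *terminal* EMA state on a
  stationary stream; real training confidence is non-stationary, where
  the EMA lags by design.
- In semi-supervised modes the labeled loader cycles once per unlabeled
  pass, so semi-supervised runs take more labeled gradient steps than the
  supervised-only ablation at equal epochs; the ablation therefore
  measures the value of the whole semi-supervised schedule, not a
  step-matched comparison.
- The supervised-only and fixed-threshold(T=1) trajectories coincide
  exactly only when the two loaders have equal length (same per-epoch
  iteration count).
- No learning-rate schedule, early stopping, distribution alignment, or
  curriculum beyond the EMA thresholds; single-device only.
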