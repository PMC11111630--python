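# stfl — self-feedback threshold focal learning

Semi-supervised training for **class-imbalanced image classification**,
built around the diagnostic setting where labeling is expensive: a handful
of annotated lesion images (e.g. dermoscopy, where melanocytic nevi
outnumber dermatofibromas ~60:1) and a large pool of unlabeled ones.

The package implements the full method — adaptive pseudo-label selection
thresholds plus focal learning — together with a fixed-threshold baseline,
a supervised-only ablation mode, the complete evaluation-metric stack
(accuracy, precision, sensitivity, specificity, F1, Cohen's κ, one-vs-rest
ROC AUC), dataset I/O in the HAM10000 PNG + metadata-CSV layout, and
synthetic generators so every component is testable at desk scale with no
downloads.

## The method

A classifier `p(f(x))` is warm-started on the labeled set with
cross-entropy. Each subsequent iteration predicts on an unlabeled batch
and maintains two EMA statistics of its own confidence
(`λ` is the EMA momentum, `N_c` the number of classes, `B` the batch):

- **global threshold** — `T_g(0) = 1/N_c`, then
  `T_g(t) = λ T_g(t−1) + (1−λ)·mean_B max_j p_i(j)`;
- **per-class thresholds** — `T_c(c, 0) = 1/N_c`, then
  `T_c(c, t) = λ T_c(c, t−1) + (1−λ)·mean_B p_i(c)`
  (the model's expected prediction for class `c`).

They combine by max-normalisation,
`T(c) = T_c(c)/max_c' T_c(c') · T_g`, so the best-learned class is gated at
`T_g` while uncertain (typically rare) classes get proportionally lower
cutoffs. A sample is kept when `max_j p_i(j) > T(argmax_j p_i(j))`; its
pseudo-label is the argmax. The training objective is

```
L = λ1·L_ce + λ2·L_T + λ3·L_f        (defaults λ1=1, λ2=0.5, λ3=0.5)
```

with `L_ce` supervised cross-entropy, `L_T` the indicator-gated
pseudo-label cross-entropy (full-batch mean), and
`L_f = mean_selected (1−p)^γ (−log p)` the focal term (γ = 2) that keeps
learning focused on hard samples. Thresholds start low — admitting many
samples while the model is weak — and rise with model confidence,
progressively excluding unreliable pseudo-labels; the per-class
modulation is what keeps selection from collapsing onto majority classes.

## Worked example

```python
from stfl.benchmark import run_benchmark

# 4-class imbalanced synthetic benchmark (proportions .60/.25/.10/.05),
# 80 labels + 640 unlabeled, tiny CNN, 10 epochs
res = run_benchmark("stfl", seed=0, epochs=10, n_unlabeled=640)
print(res.final_metrics.summary_row())
print(res.threshold_history[0].T_g, "->", round(res.threshold_history[-1].T_g, 4))
print([round(x, 4) for x in res.threshold_history[-1].T_c])
```

prints

```
{'Accuracy': 0.8583, 'Kappa': 0.7291, 'Recall': 0.8583, 'Precision': 0.7699, 'F1-score': 0.8039}
0.25 -> 0.481
[0.4337, 0.2326, 0.1734, 0.1604]
```

The global threshold has risen from the chance level 1/4 to 0.48 as the
model gained confidence; the per-class thresholds are lower for the rare
classes (2 and 3), which is exactly the mechanism that lets their
pseudo-labels through while the majority class is gated hard. Accuracy
0.86 and κ 0.73 on the held-out test set come from 80 labels plus
unlabeled data only.

A command-line surface mirrors the library:

```bash
stfl make-synthetic --out data/            # PNG + metadata.csv dataset
stfl train --data data/ --mode stfl --out run/
stfl evaluate --model run/checkpoint.npz --data data/
stfl simulate-stream --spec stream.yaml --out traj.csv
```

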