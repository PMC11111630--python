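"""Training orchestration: supervised warm-up, then joint semi-supervised
training with per-batch pseudo-labeling, self-feedback threshold updates,
selection, and the combined objective.

One semi-supervised iteration processes one labeled and one unlabeled
batch in lock-step (the shorter loader cycles, reshuffling each pass):

1. predict probabilities on the unlabeled batch;
2. EMA-update the global and per-class thresholds from those predictions;
3. combine them (max-normalisation) and select reliable samples — the
   same batch is selected with the freshly updated thresholds;
4. compute supervised CE on the labeled batch, indicator-gated CE and
   focal loss on the selection, weight them, and take one SGD step.

Modes: ``stfl`` (adaptive thresholds), ``fixed_threshold`` (constant
``T_fix`` cutoff for every class; the classic baseline), and
``supervised_only`` (no unlabeled data touched — the ablation).

All randomness flows from the single config seed, split into independent
streams for weight init, the labeled loader (shuffling + flips), and the
unlabeled loader, so modes that consume different amounts of unlabeled
randomness still see identical labeled batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses as L
from . import thresholds as T
from .losses import LossBreakdown, LossConfig
from .metrics import MetricsReport, evaluate_predictions
from .model import ClassifierModel, SGDOptimizer, build_model, predict_probs
from .synthetic import ImageSet

__all__ = ["TrainConfig", "TrainResult", "warmup_supervised", "train_stfl", "evaluate"]

MODES = ("stfl", "fixed_threshold", "supervised_only")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 64
    learning_rate: float = 0.001
    sgd_momentum: float = 0.9
    warmup_epochs: int = 5
    mode: str = "stfl"
    loss_config: LossConfig = field(default_factory=LossConfig)
    ema_momentum: float = 0.999
    per_class_mode: str = "expected"
    seed: int = 0
    augment_hflip: bool = True
    image_size: int = 32
    backbone: str = "tiny_cnn"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.warmup_epochs < 0 or self.warmup_epochs > self.epochs:
            raise ValueError("need 0 <= warmup_epochs <= epochs")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 < self.ema_momentum < 1.0:
            raise ValueError("ema_momentum must lie in (0, 1)")


@dataclass
class TrainResult:
    model: ClassifierModel
    threshold_history: list        # ThresholdState snapshots; [0] is init
    loss_history: list             # LossBreakdown per SGD iteration
    selection_history: list        # per-class selected counts per unlabeled batch
    final_metrics: MetricsReport | None = None

    def threshold_log(self) -> pd.DataFrame:
        """Trajectory table: t, T_g, T_c_*, n_selected_* per iteration."""
        rows = []
        for i, st in enumerate(self.threshold_history):
            row = {"t": st.t, "T_g": st.T_g}
            row.update({f"T_c_{c}": st.T_c[c] for c in range(st.n_classes)})
            counts = (
                self.selection_history[i - 1]
                if 1 <= i <= len(self.selection_history)
                else np.zeros(st.n_classes, dtype=int)
            )
            row.update({f"n_selected_{c}": int(counts[c]) for c in range(st.n_classes)})
            rows.append(row)
        return pd.DataFrame(rows)

    def loss_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.loss_history)),
                "supervised": [b.supervised for b in self.loss_history],
                "unsupervised_selected": [
                    b.unsupervised_selected for b in self.loss_history
                ],
                "focal": [b.focal for b in self.loss_history],
                "total": [b.total for b in self.loss_history],
                "n_selected": [b.n_selected for b in self.loss_history],
            }
        )


def _maybe_flip(x: np.ndarray, rng: np.random.Generator, enabled: bool) -> np.ndarray:
    if not enabled:
        return x
    flips = rng.random(len(x)) < 0.5
    if flips.any():
        x = x.copy()
        x[flips] = x[flips, :, ::-1, :]
    return x


def _labeled_cycler(images, labels, batch_size, rng):
    """Endless labeled batches; reshuffles at every pass through the set."""
    n = len(images)
    while True:
        perm = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = perm[i:i + batch_size]
            yield images[idx], labels[idx]


def _derive_seeds(seed: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=3)


def _n_classes_of(dataset: ImageSet, what: str) -> int:
    nc = dataset.n_classes
    if nc is None:
        raise ValueError(f"{what} set has no class information")
    return nc


def _supervised_epoch(model, optimizer, images, labels, config, rng, loss_history,
                      weight: float = 1.0):
    n = len(images)
    perm = rng.permutation(n)
    for i in range(0, n, config.batch_size):
        idx = perm[i:i + config.batch_size]
        xb = _maybe_flip(images[idx], rng, config.augment_hflip)
        logits, cache = model.forward(xb, want_cache=True)
        sup, dlog = L.cross_entropy_grad(logits, labels[idx], config.loss_config.prob_floor)
        optimizer.step(model.backward(cache, weight * dlog))
        loss_history.append(L.total_loss(sup, 0.0, 0.0, config.loss_config, 0))


def warmup_supervised(
    model: ClassifierModel,
    labeled: ImageSet,
    config: TrainConfig,
    optimizer: SGDOptimizer | None = None,
    rng: np.random.Generator | None = None,
    loss_history: list | None = None,
) -> ClassifierModel:
    """Supervised-only warm-up: ``warmup_epochs`` epochs of plain CE + SGD.

    With ``warmup_epochs=0`` the model is returned untouched.
    """
    if labeled.labels is None or len(labeled) == 0:
        raise ValueError("warm-up requires a non-empty labeled set")
    if config.warmup_epochs == 0:
        return model
    if optimizer is None:
        optimizer = SGDOptimizer(model, config.learning_rate, config.sgd_momentum)
    if rng is None:
        rng = np.random.default_rng(_derive_seeds(config.seed)[1])
    if loss_history is None:
        loss_history = []
    for _ in range(config.warmup_epochs):
        _supervised_epoch(
            model, optimizer, labeled.images, labeled.labels, config, rng, loss_history
        )
    return model


def train_stfl(
    labeled: ImageSet,
    unlabeled: ImageSet | None,
    config: TrainConfig,
    test_set: ImageSet | None = None,
) -> TrainResult:
    """Run the full training loop; see the module docstring for the schedule.

    ``epochs`` counts warm-up epochs plus main epochs.  In semi-supervised
    modes an epoch is one pass over the unlabeled set; in
    ``supervised_only`` it is one pass over the labeled set and unlabeled
    data is never read.
    """
    if labeled.labels is None or len(labeled) == 0:
        raise ValueError("training requires a non-empty labeled set")
    n_classes = _n_classes_of(labeled, "labeled")
    if config.mode != "supervised_only":
        if unlabeled is None or len(unlabeled) == 0:
            raise ValueError(f"mode={config.mode!r} requires a non-empty unlabeled set")
        if _n_classes_of(unlabeled, "unlabeled") != n_classes:
            raise ValueError(
                "labeled and unlabeled sets disagree on the number of classes"
            )

    seeds = _derive_seeds(config.seed)
    model = build_model(
        config.backbone, n_classes, image_size=config.image_size, seed=int(seeds[0])
    )
    optimizer = SGDOptimizer(model, config.learning_rate, config.sgd_momentum)
    rng_lab = np.random.default_rng(int(seeds[1]))
    rng_unlab = np.random.default_rng(int(seeds[2]))

    loss_history: list[LossBreakdown] = []
    warmup_supervised(model, labeled, config, optimizer, rng_lab, loss_history)

    state = T.init_state(n_classes, config.ema_momentum)
    threshold_history = [state]
    selection_history: list[np.ndarray] = []
    lcfg = config.loss_config
    main_epochs = config.epochs - config.warmup_epochs

    if config.mode == "supervised_only":
        for _ in range(main_epochs):
            _supervised_epoch(
                model, optimizer, labeled.images, labeled.labels, config,
                rng_lab, loss_history, weight=lcfg.lambda1,
            )
    else:
        lab_batches = _labeled_cycler(
            labeled.images, labeled.labels, config.batch_size, rng_lab
        )
        fixed_thr = np.full(n_classes, lcfg.fixed_threshold)
        n_u = len(unlabeled)
        for _ in range(main_epochs):
            perm = rng_unlab.permutation(n_u)
            for i in range(0, n_u, config.batch_size):
                xl, yl = next(lab_batches)
                xl = _maybe_flip(xl, rng_lab, config.augment_hflip)
                xu = _maybe_flip(
                    unlabeled.images[perm[i:i + config.batch_size]],
                    rng_unlab,
                    config.augment_hflip,
                )

                logits_l, cache_l = model.forward(xl, want_cache=True)
                sup, dlog_l = L.cross_entropy_grad(logits_l, yl, lcfg.prob_floor)

                logits_u, cache_u = model.forward(xu, want_cache=True)
                probs_u = L.softmax(logits_u)
                state = T.update_global(state, probs_u)
                state = T.update_per_class(state, probs_u, config.per_class_mode)
                thr = (
                    T.combined_thresholds(state)
                    if config.mode == "stfl"
                    else fixed_thr
                )
                sel = T.select_samples(probs_u, thr)

                unsup, dlog_u = L.selected_ce_grad(logits_u, sel, lcfg.prob_floor)
                foc, dlog_f = L.focal_grad(logits_u, sel, lcfg.gamma, lcfg.prob_floor)

                grads = model.backward(cache_l, lcfg.lambda1 * dlog_l)
                if sel.n_selected:
                    gu = model.backward(
                        cache_u, lcfg.lambda2 * dlog_u + lcfg.lambda3 * dlog_f
                    )
                    for k in grads:
                        grads[k] += gu[k]
                optimizer.step(grads)

                loss_history.append(
                    L.total_loss(sup, unsup, foc, lcfg, sel.n_selected)
                )
                threshold_history.append(state)
                selection_history.append(sel.per_class_counts)

    final = evaluate(model, test_set) if test_set is not None else None
    return TrainResult(
        model=model,
        threshold_history=threshold_history,
        loss_history=loss_history,
        selection_history=selection_history,
        final_metrics=final,
    )


def evaluate(model: ClassifierModel, test_set: ImageSet) -> MetricsReport:
    """Full metrics report on a labeled test set (no augmentation)."""
    if test_set.labels is None:
        raise ValueError("evaluation requires a labeled test set")
    probs = predict_probs(model, test_set.images)
    return evaluate_predictions(test_set.labels, probs, model.n_classes)
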