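"""Self-feedback confidence thresholds for pseudo-label selection.

The selection machinery maintains two exponential-moving-average (EMA)
statistics of the model's predictions on unlabeled data:

* a **global threshold** ``T_g`` — the EMA of the batch-mean maximum
  predicted probability (the model's overall confidence), and
* **per-class thresholds** ``T_c`` — the EMA, per class ``c``, of the
  model's expected predicted probability for class ``c``.

Both start at the uninformative value ``1/n_classes`` and rise as the model
grows confident.  The two are combined by max-normalisation,

    combined(c) = T_c(c) / max_c' T_c(c') * T_g,

so that the best-learned class is gated at ``T_g`` while classes the model
is less sure about (typically the rare ones) receive proportionally lower
cutoffs — the mechanism that re-balances pseudo-label selection under class
imbalance.  A sample is kept when its maximum probability *strictly*
exceeds the combined threshold of its argmax class.

State updates are pure: every update returns a new :class:`ThresholdState`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ThresholdState",
    "SelectionResult",
    "init_state",
    "update_global",
    "update_per_class",
    "combined_thresholds",
    "select_samples",
]


@dataclass(frozen=True)
class ThresholdState:
    """Immutable snapshot of the adaptive-threshold state.

    Attributes
    ----------
    t : int
        Number of unlabeled batches consumed so far.
    T_g : float
        Global confidence threshold in [0, 1].
    T_c : np.ndarray
        Per-class thresholds, shape ``(n_classes,)``.
    momentum : float
        EMA decay factor in (0, 1); larger = smoother/slower.
    n_classes : int
    """

    t: int
    T_g: float
    T_c: np.ndarray
    momentum: float
    n_classes: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "T_c", np.asarray(self.T_c, dtype=np.float64))


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of thresholding one batch of unlabeled predictions."""

    keep_mask: np.ndarray          # bool, (batch,)
    pseudo_labels: np.ndarray      # int, (batch,); valid where keep_mask
    per_class_counts: np.ndarray   # int, (n_classes,)
    thresholds_used: np.ndarray    # float, (n_classes,)

    @property
    def n_selected(self) -> int:
        return int(self.keep_mask.sum())


def _check_probs(batch_probs: np.ndarray, n_classes: int) -> np.ndarray:
    probs = np.asarray(batch_probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError(f"batch_probs must be 2-D, got shape {probs.shape}")
    if probs.shape[0] == 0:
        raise ValueError("batch_probs is empty: batch mean undefined")
    if probs.shape[1] != n_classes:
        raise ValueError(
            f"batch_probs has {probs.shape[1]} columns, expected n_classes={n_classes}"
        )
    return probs


def init_state(n_classes: int, momentum: float = 0.999) -> ThresholdState:
    """Initial state: every threshold at the chance level ``1/n_classes``."""
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    if not 0.0 < momentum < 1.0:
        raise ValueError(f"momentum must lie strictly in (0, 1), got {momentum}")
    u = 1.0 / n_classes
    return ThresholdState(
        t=0, T_g=u, T_c=np.full(n_classes, u), momentum=momentum, n_classes=n_classes
    )


def update_global(state: ThresholdState, batch_probs: np.ndarray) -> ThresholdState:
    """EMA step of the global threshold toward the batch-mean max-probability."""
    probs = _check_probs(batch_probs, state.n_classes)
    lam = state.momentum
    batch_conf = float(probs.max(axis=1).mean())
    new_tg = lam * state.T_g + (1.0 - lam) * batch_conf
    return replace(state, t=state.t + 1, T_g=new_tg)


def update_per_class(
    state: ThresholdState, batch_probs: np.ndarray, mode: str = "expected"
) -> ThresholdState:
    """EMA step of the per-class thresholds.

    mode="expected" (default): for each class ``c`` the update target is the
    batch mean of the probability the model assigns to class ``c`` over *all*
    unlabeled samples (the model's expected prediction for that class).

    mode="argmax_mean": alternative reading — the target for class ``c`` is
    the mean max-confidence of the samples whose argmax is ``c``; classes
    absent from the batch keep their previous threshold.
    """
    probs = _check_probs(batch_probs, state.n_classes)
    lam = state.momentum
    if mode == "expected":
        target = probs.mean(axis=0)
        new_tc = lam * state.T_c + (1.0 - lam) * target
    elif mode == "argmax_mean":
        argmax = probs.argmax(axis=1)
        conf = probs.max(axis=1)
        new_tc = state.T_c.copy()
        for c in range(state.n_classes):
            sel = argmax == c
            if sel.any():
                new_tc[c] = lam * state.T_c[c] + (1.0 - lam) * conf[sel].mean()
    else:
        raise ValueError(f"unknown per-class update mode: {mode!r}")
    return replace(state, T_c=new_tc)


def combined_thresholds(state: ThresholdState) -> np.ndarray:
    """Max-normalised per-class thresholds scaled by the global threshold.

    Returns ``v`` with ``v[c] = T_c[c] / max(T_c) * T_g``; hence
    ``max(v) == T_g`` exactly and ``v <= T_g`` elementwise.
    """
    tc_max = float(state.T_c.max())
    if tc_max <= 0.0:
        raise ValueError("max of per-class thresholds must be positive")
    return state.T_c / tc_max * state.T_g


def select_samples(
    batch_probs: np.ndarray, class_thresholds: np.ndarray
) -> SelectionResult:
    """Keep samples whose max probability strictly exceeds their class cutoff.

    The pseudo-label is the argmax class (ties broken toward the lowest
    class index).  With a constant threshold vector this is the classic
    fixed-threshold baseline; with :func:`combined_thresholds` it is the
    adaptive selection rule.
    """
    probs = np.asarray(batch_probs, dtype=np.float64)
    thr = np.asarray(class_thresholds, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError(f"batch_probs must be 2-D, got shape {probs.shape}")
    if thr.shape != (probs.shape[1],):
        raise ValueError(
            f"class_thresholds has shape {thr.shape}, expected ({probs.shape[1]},)"
        )
    if thr.size and (thr.min() < 0.0 or thr.max() > 1.0):
        raise ValueError("class_thresholds must lie in [0, 1]")
    pseudo = probs.argmax(axis=1)
    conf = probs.max(axis=1)
    keep = conf > thr[pseudo]
    counts = np.bincount(pseudo[keep], minlength=probs.shape[1]).astype(np.int64)
    return SelectionResult(
        keep_mask=keep,
        pseudo_labels=pseudo,
        per_class_counts=counts,
        thresholds_used=thr,
    )
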