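"""Training objectives: supervised CE, selected-sample CE, focal loss, total.

All loss *values* are computed from class probabilities (row-stochastic
arrays), clamped away from 0/1 for log-safety.  Companion ``*_grad``
functions take raw logits, evaluate the same loss through a softmax, and
return the analytic gradient with respect to the logits — the quantities
the trainer backpropagates.

Divisor conventions (deliberate, and different between the two unlabeled
terms): the selected-sample cross-entropy averages over the *full* unlabeled
batch with the selection indicator inside the sum, while the focal loss
averages over the *selected* subset only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thresholds import SelectionResult

__all__ = [
    "LossConfig",
    "LossBreakdown",
    "softmax",
    "cross_entropy_loss",
    "unsupervised_selected_loss",
    "focal_loss",
    "total_loss",
    "cross_entropy_grad",
    "selected_ce_grad",
    "focal_grad",
]

_DEFAULT_FLOOR = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Weights and constants of the combined objective.

    ``total = lambda1 * supervised + lambda2 * unsupervised_selected
            + lambda3 * focal``
    with focal exponent ``gamma`` and fixed-baseline threshold
    ``fixed_threshold`` (used only in fixed-threshold mode).
    """

    lambda1: float = 1.0
    lambda2: float = 0.5
    lambda3: float = 0.5
    gamma: float = 2.0
    fixed_threshold: float = 0.95
    prob_floor: float = _DEFAULT_FLOOR

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.fixed_threshold <= 1.0:
            raise ValueError("fixed_threshold must lie in (0, 1]")
        if not 0.0 < self.prob_floor < 0.5:
            raise ValueError("prob_floor must lie in (0, 0.5)")


@dataclass(frozen=True)
class LossBreakdown:
    supervised: float
    unsupervised_selected: float
    focal: float
    total: float
    n_selected: int
    weights: tuple = field(default=(1.0, 0.5, 0.5))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax in float64 (rows sum to 1 to ~1e-15)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _clamp(p: np.ndarray, floor: float) -> np.ndarray:
    return np.clip(p, floor, 1.0 - floor)


def _check_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(labels)
    if y.size and (y.min() < 0 or y.max() >= n_classes):
        raise ValueError(
            f"labels must lie in [0, {n_classes}); got range [{y.min()}, {y.max()}]"
        )
    return y.astype(np.int64)


def cross_entropy_loss(
    probs: np.ndarray, labels: np.ndarray, prob_floor: float = _DEFAULT_FLOOR
) -> float:
    """Mean negative log probability of the true class."""
    p = np.asarray(probs, dtype=np.float64)
    y = _check_labels(labels, p.shape[1])
    if len(y) != len(p):
        raise ValueError("probs and labels have mismatched lengths")
    py = _clamp(p[np.arange(len(y)), y], prob_floor)
    return float(-np.log(py).mean())


def unsupervised_selected_loss(
    probs: np.ndarray,
    selection: SelectionResult,
    prob_floor: float = _DEFAULT_FLOOR,
) -> float:
    """Indicator-gated pseudo-label CE averaged over the full batch."""
    p = np.asarray(probs, dtype=np.float64)
    if len(selection.keep_mask) != len(p):
        raise ValueError("selection and probs have mismatched lengths")
    if selection.n_selected == 0:
        return 0.0
    keep = selection.keep_mask
    py = _clamp(p[np.arange(len(p)), selection.pseudo_labels], prob_floor)
    return float(-(keep * np.log(py)).sum() / len(p))


def focal_loss(
    probs: np.ndarray,
    selection: SelectionResult,
    gamma: float = 2.0,
    prob_floor: float = _DEFAULT_FLOOR,
) -> float:
    """Focal term ``(1-p)^gamma * (-log p)`` averaged over selected samples.

    ``p`` is the probability of the pseudo-label class.  Down-weights
    already-confident samples so learning focuses on hard ones; with
    gamma=0 this reduces to plain CE on the selected subset.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p = np.asarray(probs, dtype=np.float64)
    if len(selection.keep_mask) != len(p):
        raise ValueError("selection and probs have mismatched lengths")
    if selection.n_selected == 0:
        return 0.0
    keep = selection.keep_mask
    py = _clamp(
        p[np.arange(len(p)), selection.pseudo_labels][keep], prob_floor
    )
    return float(((1.0 - py) ** gamma * -np.log(py)).mean())


def total_loss(
    supervised: float,
    unsupervised: float,
    focal: float,
    config: LossConfig,
    n_selected: int = 0,
) -> LossBreakdown:
    """Weighted sum of the three terms, returned with its full breakdown."""
    total = (
        config.lambda1 * supervised
        + config.lambda2 * unsupervised
        + config.lambda3 * focal
    )
    return LossBreakdown(
        supervised=float(supervised),
        unsupervised_selected=float(unsupervised),
        focal=float(focal),
        total=float(total),
        n_selected=int(n_selected),
        weights=(config.lambda1, config.lambda2, config.lambda3),
    )


# ---------------------------------------------------------------------------
# Gradients with respect to logits (what the trainer backpropagates).
# Values are computed through the same prob-space functions above so the
# finite-difference check against the analytic gradient is meaningful.
# ---------------------------------------------------------------------------

def cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray, prob_floor: float = _DEFAULT_FLOOR
) -> tuple[float, np.ndarray]:
    p = softmax(logits)
    y = _check_labels(labels, p.shape[1])
    loss = cross_entropy_loss(p, y, prob_floor)
    grad = p.copy()
    grad[np.arange(len(y)), y] -= 1.0
    grad /= len(y)
    return loss, grad


def selected_ce_grad(
    logits: np.ndarray,
    selection: SelectionResult,
    prob_floor: float = _DEFAULT_FLOOR,
) -> tuple[float, np.ndarray]:
    """Pseudo-labels are treated as constants (no gradient through targets)."""
    p = softmax(logits)
    loss = unsupervised_selected_loss(p, selection, prob_floor)
    grad = np.zeros_like(p)
    if selection.n_selected:
        keep = selection.keep_mask
        g = p[keep].copy()
        g[np.arange(keep.sum()), selection.pseudo_labels[keep]] -= 1.0
        grad[keep] = g / len(p)
    return loss, grad


def focal_grad(
    logits: np.ndarray,
    selection: SelectionResult,
    gamma: float = 2.0,
    prob_floor: float = _DEFAULT_FLOOR,
) -> tuple[float, np.ndarray]:
    p = softmax(logits)
    loss = focal_loss(p, selection, gamma, prob_floor)
    grad = np.zeros_like(p)
    n_sel = selection.n_selected
    if n_sel:
        keep = selection.keep_mask
        pk = p[keep]                                   # (m, C)
        t = selection.pseudo_labels[keep]
        m = len(pk)
        pt = np.clip(pk[np.arange(m), t], prob_floor, 1.0 - prob_floor)
        # d/dp of (1-p)^g * (-log p)
        dldp = gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt) - (
            1.0 - pt
        ) ** gamma / pt
        # dp_t/dz_j = p_t (delta_tj - p_j)
        dz = -pk * pt[:, None]
        dz[np.arange(m), t] += pt
        grad[keep] = dldp[:, None] * dz / n_sel
    return loss, grad
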