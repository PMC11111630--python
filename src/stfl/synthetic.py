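"""Synthetic class-imbalanced image datasets and confidence streams.

Real dermoscopy collections such as HAM10000 pair a heavy class imbalance
(6,705 melanocytic nevi against 115 dermatofibromas) with class-dependent
visual difficulty.  The generator here emulates exactly those two
properties at desk scale, not the photographic appearance: each class is a
parametric "lesion" — an ellipse on a skin-toned background whose color,
axes, orientation, and border waviness are functions of the class index,
scaled by a global ``signal_strength`` — plus per-sample geometric jitter
and i.i.d. Gaussian pixel noise.  At ``signal_strength=0`` all classes
share one template, so the data carries no learnable class signal beyond
the priors.

A second generator emits model-free *confidence streams*: batches of
class-probability vectors whose max-confidence is Beta-distributed per
true class.  These exercise the threshold policies without any trained
model in the loop.

Hidden true labels of "unlabeled" samples are stored on the returned set
but are meant for test oracles only (pseudo-label precision measurement);
no training-path API reads them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticSpec",
    "ConfidenceStreamSpec",
    "ImageSet",
    "HAM10000_CLASS_COUNTS",
    "ham10000_proportions",
    "generate_image_dataset",
    "generate_confidence_stream",
    "hidden_labels",
]

#: Class frequencies of the HAM10000 dermoscopy collection (7 lesion types).
HAM10000_CLASS_COUNTS = {
    "akiec": 327, "bcc": 514, "bkl": 1099, "df": 115,
    "mel": 1113, "nv": 6705, "vasc": 142,
}


def ham10000_proportions() -> np.ndarray:
    """Class proportions of the 7 lesion types, in alphabetical class order."""
    counts = np.array([HAM10000_CLASS_COUNTS[k] for k in sorted(HAM10000_CLASS_COUNTS)])
    return counts / counts.sum()


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic imbalanced image dataset."""

    n_classes: int = 7
    class_proportions: np.ndarray = field(default_factory=ham10000_proportions)
    image_size: int = 32
    signal_strength: float = 0.8
    noise_sd: float = 0.1
    n_labeled: int = 500
    n_unlabeled: int = 2000
    n_test: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=np.float64)
        object.__setattr__(self, "class_proportions", props)
        if self.n_classes < 1:
            raise ValueError(f"n_classes must be positive, got {self.n_classes}")
        if props.shape != (self.n_classes,):
            raise ValueError(
                f"class_proportions has length {props.size}, expected n_classes={self.n_classes}"
            )
        if (props <= 0).any():
            raise ValueError("class_proportions must all be positive")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class_proportions must sum to 1 (got {props.sum():.12f})"
            )
        if self.image_size < 8 or self.image_size % 4:
            raise ValueError(f"image_size must be a multiple of 4 >= 8, got {self.image_size}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError(f"signal_strength must lie in [0, 1], got {self.signal_strength}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        for name in ("n_labeled", "n_unlabeled", "n_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")


@dataclass
class ImageSet:
    """A split of image samples.  ``labels`` is None for unlabeled sets."""

    images: np.ndarray                    # (N, H, W, 3) float32 in [0, 1]
    labels: np.ndarray | None
    class_names: list[str] | None = None
    _hidden_labels: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int | None:
        if self.class_names is not None:
            return len(self.class_names)
        ref = self.labels if self.labels is not None else self._hidden_labels
        return int(ref.max()) + 1 if ref is not None and len(ref) else None


def hidden_labels(imageset: ImageSet) -> np.ndarray:
    """Test-oracle side channel: true labels of an 'unlabeled' set.

    Never used on the training path; exists so tests can measure
    pseudo-label precision without leaking labels into training.
    """
    if imageset.labels is not None:
        return imageset.labels
    if imageset._hidden_labels is None:
        raise ValueError("this set carries no hidden labels")
    return imageset._hidden_labels


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

_SKIN = np.array([0.86, 0.71, 0.60])
_BASE_LESION = np.array([0.52, 0.34, 0.26])


def _class_color(c: int, n_classes: int, s: float) -> np.ndarray:
    """Lesion color: base brown at s=0, spread around a hue wheel at s=1."""
    h = c / max(n_classes, 1)
    wheel = 0.5 + 0.45 * np.array(
        [np.cos(2 * np.pi * h), np.cos(2 * np.pi * (h + 1 / 3)), np.cos(2 * np.pi * (h + 2 / 3))]
    )
    return (1.0 - s) * _BASE_LESION + s * wheel


def _render_class_batch(
    c: int, n: int, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render ``n`` jittered instances of class ``c``'s lesion template."""
    size, s = spec.image_size, spec.signal_strength
    ax = np.linspace(-1.0, 1.0, size)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")

    # class-dependent geometry, all deviations scaled by signal_strength
    u = (c + 0.5) / spec.n_classes
    a0 = 0.52 * (1.0 + 0.30 * s * np.cos(2 * np.pi * u))
    b0 = 0.38 * (1.0 + 0.30 * s * np.sin(2 * np.pi * u))
    theta0 = s * np.pi * u
    k = 3 + c                      # border sinusoid frequency
    amp = 0.10 * s                 # border roughness amplitude
    color = _class_color(c, spec.n_classes, s)

    out = np.empty((n, size, size, 3), dtype=np.float32)
    for i in range(n):
        cx, cy = rng.uniform(-0.08, 0.08, size=2)
        scale = rng.uniform(0.9, 1.1)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        xr = (xx - cx) * np.cos(theta0) + (yy - cy) * np.sin(theta0)
        yr = -(xx - cx) * np.sin(theta0) + (yy - cy) * np.cos(theta0)
        r2 = (xr / (a0 * scale)) ** 2 + (yr / (b0 * scale)) ** 2
        phi = np.arctan2(yr, xr)
        boundary = (1.0 + amp * np.sin(k * phi + phase)) ** 2
        mask = (r2 <= boundary)[..., None]
        img = np.where(mask, color, _SKIN).astype(np.float32)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
        out[i] = np.clip(img, 0.0, 1.0)
    return out


def _make_split(
    n: int, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    labels = rng.choice(spec.n_classes, size=n, p=spec.class_proportions)
    images = np.empty((n, spec.image_size, spec.image_size, 3), dtype=np.float32)
    for c in range(spec.n_classes):
        idx = np.flatnonzero(labels == c)
        if len(idx):
            images[idx] = _render_class_batch(c, len(idx), spec, rng)
    return images, labels.astype(np.int64)


def generate_image_dataset(
    spec: SyntheticSpec,
) -> tuple[ImageSet, ImageSet, ImageSet]:
    """Generate (labeled, unlabeled, test) splits from one seed.

    Identical specs give bit-identical datasets.  The unlabeled split's
    true labels are stored only on the hidden side channel (see
    :func:`hidden_labels`).
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"class_{c}" for c in range(spec.n_classes)]
    xl, yl = _make_split(spec.n_labeled, spec, rng)
    xu, yu = _make_split(spec.n_unlabeled, spec, rng)
    xt, yt = _make_split(spec.n_test, spec, rng)
    labeled = ImageSet(images=xl, labels=yl, class_names=names)
    unlabeled = ImageSet(images=xu, labels=None, class_names=names, _hidden_labels=yu)
    test = ImageSet(images=xt, labels=yt, class_names=names)
    return labeled, unlabeled, test


# ---------------------------------------------------------------------------
# model-free confidence streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfidenceStreamSpec:
    """Recipe for a stream of per-batch class-probability vectors.

    ``per_class_confidence_params[c] = (alpha, beta)`` governs the Beta
    distribution of the max-confidence of samples whose true class is c;
    ``corruption_rate`` is the probability that a sample's argmax slot is a
    uniformly chosen wrong class.  Remaining probability mass is spread
    uniformly over the non-argmax classes.
    """

    n_classes: int
    batch_size: int
    n_batches: int
    per_class_confidence_params: tuple
    class_priors: np.ndarray
    corruption_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        priors = np.asarray(self.class_priors, dtype=np.float64)
        object.__setattr__(self, "class_priors", priors)
        params = tuple(tuple(map(float, p)) for p in self.per_class_confidence_params)
        object.__setattr__(self, "per_class_confidence_params", params)
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.batch_size < 1 or self.n_batches < 1:
            raise ValueError("batch_size and n_batches must be positive")
        if len(params) != self.n_classes:
            raise ValueError("need one (alpha, beta) pair per class")
        for c, (a, b) in enumerate(params):
            if a <= 0 or b <= 0:
                raise ValueError(
                    f"per_class_confidence_params[{c}] must be positive, got ({a}, {b})"
                )
        if priors.shape != (self.n_classes,) or abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("class_priors must have length n_classes and sum to 1")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must lie in [0, 1]")


def generate_confidence_stream(
    spec: ConfidenceStreamSpec,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return ``n_batches`` pairs (probs (B, n_classes), true classes (B,)).

    Max-confidences are clipped into [1/n_classes, 1) so the designated
    slot is genuinely the argmax; every row sums to 1 exactly up to float
    rounding.
    """
    rng = np.random.default_rng(spec.seed)
    nc, bs = spec.n_classes, spec.batch_size
    alphas = np.array([p[0] for p in spec.per_class_confidence_params])
    betas = np.array([p[1] for p in spec.per_class_confidence_params])
    batches = []
    for _ in range(spec.n_batches):
        true = rng.choice(nc, size=bs, p=spec.class_priors)
        m = rng.beta(alphas[true], betas[true])
        m = np.clip(m, 1.0 / nc + 1e-9, 1.0 - 1e-9)
        argmax = true.copy()
        corrupt = rng.random(bs) < spec.corruption_rate
        if corrupt.any():
            shift = rng.integers(1, nc, size=int(corrupt.sum()))
            argmax[corrupt] = (argmax[corrupt] + shift) % nc
        probs = np.full((bs, nc), ((1.0 - m) / (nc - 1))[:, None])
        probs[np.arange(bs), argmax] = m
        batches.append((probs, true.astype(np.int64)))
    return batches
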