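"""Backbone feature extractor and classification head.

The desk-scale backbone is ``tiny_cnn``: a compact 3-block convolutional
network (3x3 conv -> ReLU -> 2x2 max-pool, twice; 3x3 conv -> ReLU ->
global average pool; linear head) written directly in NumPy with im2col
convolutions and hand-derived backprop.  It accepts square RGB images whose
side is a multiple of 4 (default 32) and is fully seeded, so two builds
with the same seed are bit-identical.

The large ImageNet-era backbones the method was originally run with
(``resnet50``, ``vgg16``, ``googlenet``) are recognised names but require
an optional deep-learning runtime (PyTorch) that this package does not
depend on; requesting them raises :class:`ConfigurationError`.  Every
algorithmic component of the method is backbone-agnostic and is exercised
with ``tiny_cnn``.
"""

from __future__ import annotations

import numpy as np

from .losses import softmax

__all__ = [
    "ConfigurationError",
    "ClassifierModel",
    "SGDOptimizer",
    "build_model",
    "predict_probs",
    "save_checkpoint",
    "load_checkpoint",
]

SUPPORTED_BACKBONES = ("tiny_cnn", "resnet50", "vgg16", "googlenet")
_TORCH_BACKBONES = ("resnet50", "vgg16", "googlenet")


class ConfigurationError(ValueError):
    pass


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patches for stride-1 'same' convolution."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
    i = 0
    for di in range(k):
        for dj in range(k):
            cols[..., i * c:(i + 1) * c] = xp[:, di:di + h, dj:dj + w, :]
            i += 1
    return cols.reshape(n * h * w, k * k * c)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int = 3, pad: int = 1) -> np.ndarray:
    n, h, w, c = xshape
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dcols.dtype)
    d = dcols.reshape(n, h, w, k * k * c)
    i = 0
    for di in range(k):
        for dj in range(k):
            dxp[:, di:di + h, dj:dj + w, :] += d[..., i * c:(i + 1) * c]
            i += 1
    return dxp[:, pad:pad + h, pad:pad + w, :]


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    return out, mask


def _maxpool2_backward(dout: np.ndarray, mask: np.ndarray, xshape: tuple) -> np.ndarray:
    n, h, w, c = xshape
    # distribute over ties equally (rare with continuous activations)
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dxr = mask * (dout[:, :, None, :, None, :] / counts)
    return dxr.reshape(n, h, w, c).astype(dout.dtype)


class ClassifierModel:
    """tiny_cnn classifier: parameters, forward/backward, inference."""

    backbone_name = "tiny_cnn"
    channels = (8, 16, 32)

    def __init__(self, n_classes: int, image_size: int = 32, seed: int = 0):
        if n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {n_classes}")
        if image_size < 8 or image_size % 4:
            raise ConfigurationError(
                f"image_size must be a multiple of 4 and >= 8, got {image_size}"
            )
        self.n_classes = int(n_classes)
        self.image_size = int(image_size)
        self.seed = int(seed)
        self.feature_dim = self.channels[-1]
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        self.params = {
            "W1": he((27, c1), 27), "b1": np.zeros(c1, np.float32),
            "W2": he((9 * c1, c2), 9 * c1), "b2": np.zeros(c2, np.float32),
            "W3": he((9 * c2, c3), 9 * c2), "b3": np.zeros(c3, np.float32),
            "Wf": he((c3, n_classes), c3) * 0.1, "bf": np.zeros(n_classes, np.float32),
        }

    # -- forward / backward -------------------------------------------------

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        s = self.image_size
        if x.ndim != 4 or x.shape[1:] != (s, s, 3):
            raise ValueError(
                f"expected images of shape (N, {s}, {s}, 3), got {x.shape}"
            )
        return x

    def forward(self, images: np.ndarray, want_cache: bool = False):
        """Return logits (N, n_classes) and, optionally, the backprop cache."""
        x = self._check_images(images)
        p = self.params
        n = len(x)
        c1, c2, c3 = self.channels
        s = self.image_size

        cols1 = _im2col(x)
        a1 = (cols1 @ p["W1"] + p["b1"]).reshape(n, s, s, c1)
        r1 = np.maximum(a1, 0.0)
        h1, m1 = _maxpool2(r1)                       # s/2

        cols2 = _im2col(h1)
        a2 = (cols2 @ p["W2"] + p["b2"]).reshape(n, s // 2, s // 2, c2)
        r2 = np.maximum(a2, 0.0)
        h2, m2 = _maxpool2(r2)                       # s/4

        cols3 = _im2col(h2)
        a3 = (cols3 @ p["W3"] + p["b3"]).reshape(n, s // 4, s // 4, c3)
        r3 = np.maximum(a3, 0.0)
        feat = r3.mean(axis=(1, 2))                  # global average pool

        logits = feat @ p["Wf"] + p["bf"]
        if not want_cache:
            return logits
        cache = dict(
            x=x, cols1=cols1, a1=a1, m1=m1, h1=h1,
            cols2=cols2, a2=a2, m2=m2, h2=h2,
            cols3=cols3, a3=a3, r3=r3, feat=feat,
        )
        return logits, cache

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        """Gradients of the loss w.r.t. all parameters given d(loss)/d(logits)."""
        p = self.params
        dlogits = dlogits.astype(np.float32)
        n = len(dlogits)
        s = self.image_size
        c1, c2, c3 = self.channels

        grads = {}
        grads["Wf"] = cache["feat"].T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["Wf"].T                          # (n, c3)

        hw3 = (s // 4) * (s // 4)
        dr3 = np.broadcast_to(
            dfeat[:, None, None, :] / hw3, cache["r3"].shape
        ) * (cache["a3"] > 0)
        dcols3 = dr3.reshape(-1, c3) @ p["W3"].T
        grads["W3"] = cache["cols3"].T @ dr3.reshape(-1, c3)
        grads["b3"] = dr3.sum(axis=(0, 1, 2))
        dh2 = _col2im(dcols3, cache["h2"].shape)

        dr2 = _maxpool2_backward(dh2, cache["m2"], cache["a2"].shape) * (
            cache["a2"] > 0
        )
        dcols2 = dr2.reshape(-1, c2) @ p["W2"].T
        grads["W2"] = cache["cols2"].T @ dr2.reshape(-1, c2)
        grads["b2"] = dr2.sum(axis=(0, 1, 2))
        dh1 = _col2im(dcols2, cache["h1"].shape)

        dr1 = _maxpool2_backward(dh1, cache["m1"], cache["a1"].shape) * (
            cache["a1"] > 0
        )
        grads["W1"] = cache["cols1"].T @ dr1.reshape(-1, c1)
        grads["b1"] = dr1.sum(axis=(0, 1, 2))
        return grads

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


class SGDOptimizer:
    """Plain SGD with (heavy-ball) momentum on the model's parameter dict."""

    def __init__(self, model: ClassifierModel, lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("sgd momentum must lie in [0, 1)")
        self.model = model
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.velocity = {k: np.zeros_like(v) for k, v in model.params.items()}

    def step(self, grads: dict) -> None:
        for k, g in grads.items():
            v = self.velocity[k]
            v *= self.momentum
            v -= self.lr * g.astype(v.dtype)
            self.model.params[k] += v


def build_model(
    backbone_name: str,
    n_classes: int,
    pretrained: bool = False,
    image_size: int = 32,
    seed: int = 0,
) -> ClassifierModel:
    """Construct a classifier with the requested backbone.

    Only ``tiny_cnn`` is bundled; the ImageNet-era backbones need the
    optional PyTorch runtime and pretrained weights, neither of which this
    package requires.
    """
    if backbone_name not in SUPPORTED_BACKBONES:
        raise ConfigurationError(
            f"unknown backbone {backbone_name!r}; supported: {', '.join(SUPPORTED_BACKBONES)}"
        )
    if backbone_name in _TORCH_BACKBONES:
        raise ConfigurationError(
            f"backbone {backbone_name!r} requires the optional PyTorch runtime "
            "(and, if pretrained=True, downloaded weights); install it separately "
            "or use 'tiny_cnn'"
        )
    if pretrained:
        raise ConfigurationError("pretrained weights are not available for tiny_cnn")
    return ClassifierModel(n_classes=n_classes, image_size=image_size, seed=seed)


def predict_probs(
    model: ClassifierModel, images: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Row-stochastic class probabilities; deterministic (no augmentation)."""
    x = model._check_images(np.asarray(images, dtype=np.float32))
    out = np.empty((len(x), model.n_classes), dtype=np.float64)
    for i in range(0, len(x), batch_size):
        out[i:i + batch_size] = softmax(model.forward(x[i:i + batch_size]))
    return out


def save_checkpoint(model: ClassifierModel, path, threshold_state=None) -> None:
    """Single-file checkpoint (.npz): weights + metadata + threshold state."""
    payload = {f"param_{k}": v for k, v in model.params.items()}
    payload["backbone_name"] = np.array(model.backbone_name)
    payload["n_classes"] = np.array(model.n_classes)
    payload["image_size"] = np.array(model.image_size)
    payload["seed"] = np.array(model.seed)
    if threshold_state is not None:
        payload["thr_t"] = np.array(threshold_state.t)
        payload["thr_Tg"] = np.array(threshold_state.T_g)
        payload["thr_Tc"] = threshold_state.T_c
        payload["thr_momentum"] = np.array(threshold_state.momentum)
    np.savez(path, **payload)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint` -> (model, threshold_state or None)."""
    from .thresholds import ThresholdState

    with np.load(path, allow_pickle=False) as data:
        model = ClassifierModel(
            n_classes=int(data["n_classes"]),
            image_size=int(data["image_size"]),
            seed=int(data["seed"]),
        )
        for k in model.params:
            model.params[k] = data[f"param_{k}"]
        state = None
        if "thr_t" in data:
            tc = data["thr_Tc"]
            state = ThresholdState(
                t=int(data["thr_t"]),
                T_g=float(data["thr_Tg"]),
                T_c=tc,
                momentum=float(data["thr_momentum"]),
                n_classes=len(tc),
            )
    return model, state
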