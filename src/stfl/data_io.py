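"""Dataset readers/writers and labeled-subset splitting.

On disk a dataset is a directory of 8-bit PNG images plus ``metadata.csv``
with columns ``image_id``, ``dx`` (class string; empty for unlabeled rows)
and ``split`` (``train_labeled`` | ``train_unlabeled`` | ``test``) — the
layout of the HAM10000 metadata table.  All quantisation lives at this
boundary: pixels are stored as 8-bit and decoded back to floats in [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import ImageSet

__all__ = ["write_dataset", "load_dataset", "make_label_subset"]

SPLITS = ("train_labeled", "train_unlabeled", "test")


def write_dataset(
    root,
    labeled: ImageSet | None = None,
    unlabeled: ImageSet | None = None,
    test: ImageSet | None = None,
    class_names: list[str] | None = None,
) -> Path:
    """Write splits as PNGs + metadata.csv under ``root``; returns the
    manifest path."""
    root = Path(root)
    img_dir = root / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    if class_names is None:
        for part in (labeled, unlabeled, test):
            if part is not None and part.class_names is not None:
                class_names = part.class_names
                break
    if class_names is None:
        raise ValueError("class_names could not be inferred; pass them explicitly")

    rows = []
    counter = 0
    for split, part in zip(SPLITS, (labeled, unlabeled, test)):
        if part is None:
            continue
        for i in range(len(part)):
            image_id = f"img_{counter:06d}"
            counter += 1
            arr = np.clip(part.images[i] * 255.0 + 0.5, 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(img_dir / f"{image_id}.png")
            dx = "" if part.labels is None else class_names[int(part.labels[i])]
            rows.append({"image_id": image_id, "dx": dx, "split": split})
    manifest = root / "metadata.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _decode(paths: list[Path], image_size: int) -> np.ndarray:
    out = np.empty((len(paths), image_size, image_size, 3), dtype=np.float32)
    for i, p in enumerate(paths):
        with Image.open(p) as im:
            im = im.convert("RGB")
            if im.size != (image_size, image_size):
                im = im.resize((image_size, image_size), Image.BILINEAR)
            out[i] = np.asarray(im, dtype=np.float32) / 255.0
    return out


def load_dataset(
    root, image_size: int = 32, class_vocabulary: list[str] | None = None
) -> tuple[ImageSet, ImageSet, ImageSet]:
    """Load (labeled, unlabeled, test) from a dataset directory.

    The class vocabulary defaults to the alphabetically sorted set of
    ``dx`` strings in the manifest (class ids follow that order, which
    matters for argmax tie-breaking); rows are ordered by ``image_id``.
    """
    root = Path(root)
    manifest = root / "metadata.csv" if root.is_dir() else root
    root = manifest.parent
    meta = pd.read_csv(manifest, dtype=str, keep_default_na=False)
    for col in ("image_id", "dx", "split"):
        if col not in meta.columns:
            raise ValueError(f"manifest {manifest} lacks required column {col!r}")
    meta = meta.sort_values("image_id", kind="stable").reset_index(drop=True)

    seen = sorted({dx for dx in meta["dx"] if dx})
    vocab = class_vocabulary if class_vocabulary is not None else seen
    class_to_id = {name: i for i, name in enumerate(vocab)}
    for idx, row in meta.iterrows():
        if row["dx"] and row["dx"] not in class_to_id:
            raise ValueError(
                f"row {idx} (image_id={row['image_id']}): unknown class "
                f"{row['dx']!r}; vocabulary is {vocab}"
            )
        if row["split"] not in SPLITS:
            raise ValueError(
                f"row {idx} (image_id={row['image_id']}): unknown split "
                f"{row['split']!r}; expected one of {SPLITS}"
            )

    sets = {}
    for split in SPLITS:
        part = meta[meta["split"] == split]
        paths = []
        for idx, row in part.iterrows():
            p = root / "images" / f"{row['image_id']}.png"
            if not p.exists():
                raise FileNotFoundError(
                    f"row {idx}: image file missing for image_id={row['image_id']}"
                )
            paths.append(p)
        images = _decode(paths, image_size)
        if split == "train_unlabeled":
            labels = None
        else:
            labels = np.array(
                [class_to_id[dx] for dx in part["dx"]], dtype=np.int64
            ) if len(part) else np.empty(0, dtype=np.int64)
        sets[split] = ImageSet(images=images, labels=labels, class_names=list(vocab))
    return sets["train_labeled"], sets["train_unlabeled"], sets["test"]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` over classes proportionally to ``weights``."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(np.int64)
    rem = total - base.sum()
    if rem:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def make_label_subset(
    labeled: ImageSet, n_labels: int, seed: int, stratified: bool = True
) -> tuple[ImageSet, ImageSet]:
    """Split a labeled set into a size-``n_labels`` subset and a remainder
    whose labels are hidden (moved to the unlabeled pool).

    Stratified mode (default) apportions the subset over classes by
    largest-remainder rounding of ``n_labels x class frequencies``, so rare
    classes survive small label budgets; ``stratified=False`` is a simple
    random draw.
    """
    if labeled.labels is None:
        raise ValueError("make_label_subset requires a labeled set")
    n = len(labeled)
    if not 0 < n_labels <= n:
        raise ValueError(f"n_labels must lie in (0, {n}], got {n_labels}")
    rng = np.random.default_rng(seed)
    y = labeled.labels
    if stratified:
        classes, counts = np.unique(y, return_counts=True)
        take = _largest_remainder(counts.astype(float), n_labels)
        chosen = np.concatenate(
            [
                rng.choice(np.flatnonzero(y == c), size=k, replace=False)
                for c, k in zip(classes, take)
            ]
        )
    else:
        chosen = rng.choice(n, size=n_labels, replace=False)
    chosen = np.sort(chosen)
    rest = np.setdiff1d(np.arange(n), chosen)
    subset = ImageSet(
        images=labeled.images[chosen],
        labels=y[chosen],
        class_names=labeled.class_names,
    )
    remainder = ImageSet(
        images=labeled.images[rest],
        labels=None,
        class_names=labeled.class_names,
        _hidden_labels=y[rest],
    )
    return subset, remainder
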