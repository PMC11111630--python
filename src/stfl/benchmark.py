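"""The standard desk-scale synthetic benchmark.

A 4-class imbalanced problem (class proportions 0.60 / 0.25 / 0.10 / 0.05)
with 32x32 synthetic lesion images: 80 labeled, 2,000 unlabeled and 600
test samples by default, trained with the tiny CNN for 30 epochs at batch
size 64.  The learning rate (0.05) is the from-scratch SGD scale for a
small CNN; all other optimisation settings follow the package defaults.

This is the shared substrate for the ablation (semi-supervised vs
supervised-only) and labeled-scale comparisons in the tests and in
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .losses import LossConfig
from .synthetic import SyntheticSpec, generate_image_dataset
from .trainer import TrainConfig, train_stfl

__all__ = ["benchmark_spec", "benchmark_config", "run_benchmark"]

BENCHMARK_PROPORTIONS = (0.60, 0.25, 0.10, 0.05)


def benchmark_spec(
    seed: int,
    n_labeled: int = 80,
    n_unlabeled: int = 2000,
    n_test: int = 600,
) -> SyntheticSpec:
    return SyntheticSpec(
        n_classes=4,
        class_proportions=np.array(BENCHMARK_PROPORTIONS),
        image_size=32,
        signal_strength=0.8,
        noise_sd=0.1,
        n_labeled=n_labeled,
        n_unlabeled=n_unlabeled,
        n_test=n_test,
        seed=seed,
    )


def benchmark_config(mode: str, seed: int, epochs: int = 30) -> TrainConfig:
    return TrainConfig(
        epochs=epochs,
        batch_size=64,
        learning_rate=0.05,
        warmup_epochs=5,
        mode=mode,
        loss_config=LossConfig(),
        ema_momentum=0.99,
        seed=seed,
        image_size=32,
    )


def run_benchmark(
    mode: str = "stfl",
    seed: int = 0,
    epochs: int = 30,
    n_labeled: int = 80,
    n_unlabeled: int = 2000,
    n_test: int = 600,
):
    """Generate the benchmark dataset and train once; returns a TrainResult
    with ``final_metrics`` filled in."""
    labeled, unlabeled, test = generate_image_dataset(
        benchmark_spec(seed, n_labeled, n_unlabeled, n_test)
    )
    config = benchmark_config(mode, seed, epochs)
    return train_stfl(labeled, unlabeled, config, test_set=test)
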