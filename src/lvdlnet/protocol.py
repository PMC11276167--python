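"""Training protocol: stratified 7:1:2 split, white-noise augmentation,
and train-fitted feature standardization.

The split is stratified per class; within each class the test share is
round(0.2 n), the validation share round(0.1 n), and the remainder goes to
training, so 1200 balanced samples give 840/120/240. Augmentation doubles
the training rows by appending copies perturbed with zero-mean Gaussian
noise whose per-feature standard deviation is ``sigma_rel`` times the
feature's own standard deviation; validation and test rows are never
augmented. The z-score scaler is fitted on (original) training rows only to
avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplitIndices", "split_dataset", "augment_with_noise", "ZScorer"]


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in (self.train, self.val, self.test)]
        object.__setattr__(self, "train", parts[0])
        object.__setattr__(self, "val", parts[1])
        object.__setattr__(self, "test", parts[2])
        joined = np.concatenate(parts)
        if joined.size != np.unique(joined).size:
            raise ValueError("split partitions overlap")

    @property
    def n(self) -> int:
        return self.train.size + self.val.size + self.test.size

    def sizes(self) -> tuple[int, int, int]:
        return (self.train.size, self.val.size, self.test.size)


def split_dataset(
    labels: np.ndarray, seed: int, ratio: tuple[int, int, int] = (7, 1, 2)
) -> SplitIndices:
    """Stratified random train/validation/test split at the given ratio."""
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n < 10:
        raise ValueError("need at least 10 samples to split 7:1:2")
    total = sum(ratio)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < total:
            raise ValueError(
                f"class {c} has {idx.size} samples; need >= {total} to stratify"
            )
        idx = rng.permutation(idx)
        n_test = round(idx.size * ratio[2] / total)
        n_val = round(idx.size * ratio[1] / total)
        test.append(idx[:n_test])
        val.append(idx[n_test : n_test + n_val])
        train.append(idx[n_test + n_val :])  # remainder to train
    return SplitIndices(
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )


def augment_with_noise(
    X: np.ndarray, y: np.ndarray, sigma_rel: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Originals followed by one noisy copy per row (labels duplicated)."""
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    flat = X.reshape(X.shape[0], -1)
    scale = sigma_rel * flat.std(axis=0, ddof=0)
    rng = np.random.default_rng(seed)
    noisy = flat + rng.normal(0.0, 1.0, size=flat.shape) * scale[None, :]
    X_aug = np.concatenate([flat, noisy], axis=0).reshape((2 * X.shape[0],) + X.shape[1:])
    return X_aug, np.concatenate([y, y])


class ZScorer:
    """Per-feature z-score fitted on training rows only.

    Constant features (e.g. positions that are always zero-padded) get unit
    scale so they pass through as zeros.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ZScorer":
        flat = np.asarray(X, dtype=float).reshape(X.shape[0], -1)
        self.mean_ = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=0)
        sd[sd < 1e-12] = 1.0
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")
        shape = X.shape
        flat = np.asarray(X, dtype=float).reshape(shape[0], -1)
        return ((flat - self.mean_) / self.scale_).reshape(shape)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
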