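"""Classifier models and fit results.

The three classifiers follow a model/results idiom: a model object is built
from data (feature arrays plus labels, or straight from a
:class:`~lvdlnet.spectra.SpectraDataset`), ``fit()`` runs the full training
protocol — stratified 7:1:2 split, white-noise augmentation of training rows,
train-fitted z-scoring, Adam at learning rate 5e-4, batch size 32, best
validation-accuracy checkpointing — and returns a :class:`ClassifierResults`
carrying the per-epoch history, the test-set confusion matrix and
macro-averaged metrics, and a ``summary()`` table.

Thin functional wrappers (``build_dl_libs``, ``build_dl_vnir``,
``build_lvdlnet``, ``train``) expose the same machinery for pipeline-style
use.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .libs_features import TARGET_POINTS, batch_line_features, batch_peak_features
from .nn import Adam, cross_entropy
from .nn.networks import FusionNet, LibsNet, VnirNet, _Network
from .protocol import SplitIndices, ZScorer, augment_with_noise, split_dataset
from .spectra import SpectraDataset
from .vnir_features import batch_slope_features

__all__ = [
    "ModelConfig",
    "ClassifierResults",
    "DLLibsClassifier",
    "DLVnirClassifier",
    "LVDLNetClassifier",
    "build_dl_libs",
    "build_dl_vnir",
    "build_lvdlnet",
    "train",
    "featurize_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyperparameters shared by all three classifiers.

    Protocol-level defaults are fixed (epochs 500,
    batch size 32, learning rate 5e-4, kernel width 14 matching the
    standardized interval length) and stay deliberately small elsewhere
    (hidden sizes sized for ~1e3 training samples).
    """

    n_lines: int = 18
    kernel_width: int = TARGET_POINTS
    n_vnir_features: int = 370
    lstm_hidden: int = 32
    dense: int = 64
    fusion_dim: int = 64
    dropout: float = 0.3
    n_classes: int = 6
    epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 5e-4
    weight_decay: float = 0.03
    sigma_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        for name in ("n_lines", "kernel_width", "n_vnir_features", "lstm_hidden",
                     "dense", "fusion_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be non-negative")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be non-negative")

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Network builders (functional surface)


def build_dl_libs(cfg: ModelConfig) -> LibsNet:
    """Untrained element-branch classifier (conv -> Bi-LSTM -> dense head)."""
    return LibsNet(
        n_lines=cfg.n_lines,
        kernel=cfg.kernel_width,
        lstm_hidden=cfg.lstm_hidden,
        dense=cfg.dense,
        n_classes=cfg.n_classes,
        dropout=cfg.dropout,
        seed=cfg.seed,
    )


def build_dl_vnir(cfg: ModelConfig) -> VnirNet:
    """Untrained molecular-branch classifier (dense + BN + dropout head)."""
    return VnirNet(
        n_features=cfg.n_vnir_features,
        dense=cfg.dense,
        n_classes=cfg.n_classes,
        dropout=cfg.dropout,
        seed=cfg.seed,
    )


def build_lvdlnet(cfg: ModelConfig) -> FusionNet:
    """Untrained Add-fusion classifier over both branch extractors."""
    return FusionNet(
        n_lines=cfg.n_lines,
        kernel=cfg.kernel_width,
        n_vnir_features=cfg.n_vnir_features,
        lstm_hidden=cfg.lstm_hidden,
        dense=cfg.dense,
        fusion_dim=cfg.fusion_dim,
        n_classes=cfg.n_classes,
        dropout=cfg.dropout,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# Training engine


def _as_tuple(X) -> tuple[np.ndarray, ...]:
    return X if isinstance(X, tuple) else (X,)


def _take(Xs: tuple[np.ndarray, ...], idx) -> tuple[np.ndarray, ...]:
    return tuple(x[idx] for x in Xs)


def _pack(Xs: tuple[np.ndarray, ...]):
    return Xs if len(Xs) > 1 else Xs[0]


def train(
    net: _Network,
    X,
    y: np.ndarray,
    split: SplitIndices,
    cfg: ModelConfig,
) -> "ClassifierResults":
    """Fit ``net`` on pre-extracted features under the full protocol.

    ``X`` is one feature array, or a (libs, vnir) tuple for the fusion
    model; rows are indexed by ``split``. Returns the results object with
    the network restored to its best-validation-accuracy checkpoint.
    """
    Xs = _as_tuple(X)
    y = np.asarray(y, dtype=int)
    for part, name in ((split.train, "train"), (split.val, "val"), (split.test, "test")):
        if part.size == 0:
            raise ValueError(f"{name} partition is empty")

    ss = np.random.SeedSequence(cfg.seed).spawn(2 + len(Xs))
    shuffle_rng = np.random.default_rng(ss[0])

    # augmentation (train rows only, per modality), then train-fitted z-score
    y_train = y[split.train]
    aug_parts, scalers = [], []
    for j, Xj in enumerate(Xs):
        Xj_train = Xj[split.train]
        aug_seed = int(ss[2 + j].generate_state(1)[0] % (2**31))
        Xa, ya = augment_with_noise(Xj_train, y_train, cfg.sigma_rel, aug_seed)
        scaler = ZScorer().fit(Xj_train)
        aug_parts.append(scaler.transform(Xa))
        scalers.append(scaler)
    y_aug = np.concatenate([y_train, y_train])
    X_val = tuple(s.transform(Xj[split.val]) for s, Xj in zip(scalers, Xs))
    X_test = tuple(s.transform(Xj[split.test]) for s, Xj in zip(scalers, Xs))
    y_val, y_test = y[split.val], y[split.test]

    opt = Adam(net.param_layers(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    n_aug = y_aug.size
    history = {"epoch": [], "train_loss": [], "val_loss": [], "val_acc": []}
    best_acc, best_epoch, best_state = -np.inf, -1, None

    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n_aug)
        losses = []
        for start in range(0, n_aug, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if idx.size < 2:  # batch norm needs a real batch
                continue
            logits = net.forward(_pack(_take(tuple(aug_parts), idx)), train=True)
            loss, dlogits = cross_entropy(logits, y_aug[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; reduce the"
                    " learning rate or check the input features"
                )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_logits = net.forward(_pack(X_val), train=False)
        val_loss, _ = cross_entropy(val_logits, y_val)
        val_acc = float(np.mean(np.argmax(val_logits, axis=1) == y_val))
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch, best_state = val_acc, epoch, net.get_state()

    net.set_state(best_state)
    proba_test = net.predict_proba(_pack(X_test))
    y_pred = np.argmax(proba_test, axis=1)
    cm = evaluation.confusion(y_test, y_pred, cfg.n_classes)
    metrics = evaluation.macro_metrics(cm)

    return ClassifierResults(
        network=net,
        config=cfg,
        split=split,
        scalers=scalers,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
        best_val_acc=float(best_acc),
        test_confusion=cm,
        test_metrics=metrics,
        test_proba=proba_test,
        test_pred=y_pred,
        y_test=y_test,
    )


# ---------------------------------------------------------------------------
# Feature extraction helpers


def featurize_dataset(ds: SpectraDataset) -> dict[str, np.ndarray]:
    """All four feature representations for every sample of a dataset."""
    return {
        "libs_intervals": batch_line_features(ds.libs, ds.libs_axis),
        "libs_peaks": batch_peak_features(ds.libs, ds.libs_axis),
        "vnir_slopes": batch_slope_features(ds.vnir, ds.vnir_axis),
        "vnir_full": ds.vnir.copy(),
    }


# ---------------------------------------------------------------------------
# Model classes


@dataclass
class ClassifierResults:
    """Everything a fit produced: checkpointed network, history, metrics."""

    network: _Network
    config: ModelConfig
    split: SplitIndices
    scalers: list[ZScorer]
    history: pd.DataFrame
    best_epoch: int
    best_val_acc: float
    test_confusion: np.ndarray
    test_metrics: "evaluation.MetricsReport"
    test_proba: np.ndarray
    test_pred: np.ndarray
    y_test: np.ndarray

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities for new raw (unscaled) feature rows."""
        Xs = _as_tuple(X)
        scaled = tuple(s.transform(np.asarray(x, dtype=float)) for s, x in zip(self.scalers, Xs))
        return self.network.predict_proba(_pack(scaled))

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=-1)

    @property
    def test_accuracy(self) -> float:
        return self.test_metrics.acc

    def summary(self) -> str:
        m = self.test_metrics
        lines = [
            f"{type(self.network).__name__} fit results",
            "=" * 44,
            f"train/val/test sizes : {self.split.sizes()}",
            f"epochs run           : {len(self.history)}",
            f"best epoch (val acc) : {self.best_epoch} ({self.best_val_acc:.4f})",
            f"final train loss     : {self.history['train_loss'].iloc[-1]:.4f}",
            "-" * 44,
            f"test Acc   : {m.acc:.4f}",
            f"test Mac_P : {m.mac_p:.4f}",
            f"test Mac_R : {m.mac_r:.4f}",
            f"test Mac_F : {m.mac_f:.4f}",
            "=" * 44,
        ]
        return "\n".join(lines)


class _BaseClassifier:
    """Model object: features + labels + config; ``fit()`` -> results."""

    def __init__(self, X, y, config: ModelConfig | None = None,
                 split: SplitIndices | None = None):
        self.config = config or ModelConfig()
        self.X = X
        self.y = np.asarray(y, dtype=int)
        self.split = split or split_dataset(self.y, seed=self.config.seed)

    def _build(self) -> _Network:
        raise NotImplementedError

    def fit(self) -> ClassifierResults:
        return train(self._build(), self.X, self.y, self.split, self.config)


class DLLibsClassifier(_BaseClassifier):
    """Element-information classifier on 18 x 14 line-interval matrices."""

    def _build(self):
        return build_dl_libs(self.config)

    @classmethod
    def from_dataset(cls, ds: SpectraDataset, config: ModelConfig | None = None,
                     split: SplitIndices | None = None):
        X = batch_line_features(ds.libs, ds.libs_axis)
        return cls(X, ds.labels, config=config, split=split)


class DLVnirClassifier(_BaseClassifier):
    """Molecular-information classifier on 370-dimensional slope vectors."""

    def _build(self):
        return build_dl_vnir(self.config)

    @classmethod
    def from_dataset(cls, ds: SpectraDataset, config: ModelConfig | None = None,
                     split: SplitIndices | None = None):
        X = batch_slope_features(ds.vnir, ds.vnir_axis)
        return cls(X, ds.labels, config=config, split=split)


class LVDLNetClassifier(_BaseClassifier):
    """Fused classifier over (line-interval matrix, slope vector) pairs."""

    def _build(self):
        return build_lvdlnet(self.config)

    @classmethod
    def from_dataset(cls, ds: SpectraDataset, config: ModelConfig | None = None,
                     split: SplitIndices | None = None):
        X = (
            batch_line_features(ds.libs, ds.libs_axis),
            batch_slope_features(ds.vnir, ds.vnir_axis),
        )
        return cls(X, ds.labels, config=config, split=split)


# ---------------------------------------------------------------------------
# Checkpoint persistence (trained network + config sidecar)

_MODEL_KINDS = {"LibsNet": build_dl_libs, "VnirNet": build_dl_vnir,
                "FusionNet": build_lvdlnet}


def save_checkpoint(results: ClassifierResults, path: str | Path) -> None:
    """Write network weights (.npz) with a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, s in enumerate(results.network.get_state()):
        for k, v in s["params"].items():
            arrays[f"l{i}.p.{k}"] = v
        for k, v in s["state"].items():
            arrays[f"l{i}.s.{k}"] = v
    for j, sc in enumerate(results.scalers):
        arrays[f"scaler{j}.mean"] = sc.mean_
        arrays[f"scaler{j}.scale"] = sc.scale_
    np.savez(path, **arrays)
    meta = {
        "format_version": 1,
        "network": type(results.network).__name__,
        "config": results.config.to_dict(),
        "best_epoch": int(results.best_epoch),
        "best_val_acc": float(results.best_val_acc),
        "n_scalers": len(results.scalers),
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_checkpoint(path: str | Path) -> tuple[_Network, ModelConfig, list[ZScorer]]:
    """Rebuild a trained network (and its scalers) from a checkpoint."""
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    cfg = ModelConfig(**meta["config"])
    net = _MODEL_KINDS[meta["network"]](cfg)
    data = np.load(path if path.suffix else path.with_suffix(".npz"))
    state = []
    for i, layer in enumerate(net.param_layers()):
        state.append(
            {
                "params": {k: data[f"l{i}.p.{k}"] for k in layer.params},
                "state": {k: data[f"l{i}.s.{k}"] for k in layer.state},
            }
        )
    net.set_state(state)
    scalers = []
    for j in range(meta["n_scalers"]):
        sc = ZScorer()
        sc.mean_ = data[f"scaler{j}.mean"]
        sc.scale_ = data[f"scaler{j}.scale"]
        scalers.append(sc)
    return net, cfg, scalers
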