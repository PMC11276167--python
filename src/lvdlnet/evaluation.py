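"""Evaluation metrics and conventional-chemometrics baselines.

Metrics are the macro-averaged multiclass scores: overall accuracy, macro
precision and recall (arithmetic means of per-class precision/recall with a
zero convention for empty denominators), and macro-F (arithmetic mean of the
per-class F1 scores, each the harmonic mean of that class's precision and
recall).

Baselines are the classical pipeline: feature input (LIBS peaks or
intervals, VNIR slopes or full spectra) -> train-fitted z-score ->
train-fitted principal-component projection -> one of LDA / KNN / SVM / ELM.
The ELM (extreme learning machine: random fixed input weights, sigmoid
hidden layer, least-squares output weights) is implemented here; the other
three are delegated to scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.manifold import TSNE
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .protocol import SplitIndices, ZScorer

__all__ = [
    "MetricsReport",
    "confusion",
    "macro_metrics",
    "pca_reduce",
    "ELMClassifier",
    "train_elm",
    "BaselineSpec",
    "run_baseline",
    "comparison_table",
    "embed_tsne",
]


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class MetricsReport:
    """Acc, Mac_P, Mac_R, Mac_F — all in [0, 1]."""

    acc: float
    mac_p: float
    mac_r: float
    mac_f: float

    def to_dict(self) -> dict[str, float]:
        return {
            "Acc": self.acc,
            "Mac_P": self.mac_p,
            "Mac_R": self.mac_r,
            "Mac_F": self.mac_f,
        }


def confusion(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> np.ndarray:
    """k x k count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from zero samples")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.min() < 0 or y.max() >= k:
            raise ValueError(f"{name} contains labels outside 0..{k - 1}")
    return np.bincount(y_true * k + y_pred, minlength=k * k).reshape(k, k)


def macro_metrics(cm: np.ndarray) -> MetricsReport:
    """Macro-averaged scores from a confusion matrix.

    Per-class precision (resp. recall) with an empty predicted (resp. true)
    class is defined as 0, with a warning; per-class F1 is 0 when precision
    and recall are both 0.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm).astype(float)
    colsum = cm.sum(axis=0).astype(float)
    rowsum = cm.sum(axis=1).astype(float)
    if np.any(colsum == 0) or np.any(rowsum == 0):
        warnings.warn(
            "empty predicted or true class: its precision/recall is set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(colsum > 0, diag / colsum, 0.0)
        rec = np.where(rowsum > 0, diag / rowsum, 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2.0 * prec * rec / np.where(denom > 0, denom, 1.0), 0.0)
    return MetricsReport(
        acc=float(diag.sum() / total),
        mac_p=float(prec.mean()),
        mac_r=float(rec.mean()),
        mac_f=float(f1.mean()),
    )


# ---------------------------------------------------------------------------
# PCA reduction


def pca_reduce(
    X_train: np.ndarray, X_eval: np.ndarray, n_components: int | float
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Principal-component projection fitted on training rows only.

    ``n_components`` may be an integer count or a variance fraction in
    (0, 1), as in scikit-learn.
    """
    if isinstance(n_components, (int, np.integer)):
        limit = min(X_train.shape[0], X_train.shape[1])
        if n_components > limit:
            raise ValueError(
                f"n_components={n_components} exceeds min(n_train, dim)={limit}"
            )
    model = PCA(n_components=n_components, svd_solver="full")
    scores_train = model.fit_transform(X_train)
    return scores_train, model.transform(X_eval), model


# ---------------------------------------------------------------------------
# Extreme learning machine


class ELMClassifier:
    """Single-hidden-layer network with random fixed input weights.

    Hidden activations are sigmoid; output weights are the ridge-regularized
    least-squares (pseudoinverse) map from hidden activations to one-hot
    targets. Prediction is the argmax of the linear output.
    """

    def __init__(self, n_hidden: int = 200, seed: int = 0, ridge: float = 1e-6):
        if n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        self.n_hidden = n_hidden
        self.seed = seed
        self.ridge = ridge

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.W_ + self.b_
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ELMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.unique(y)
        self.W_ = rng.normal(0.0, 1.0, size=(X.shape[1], self.n_hidden))
        self.b_ = rng.normal(0.0, 1.0, size=self.n_hidden)
        H = self._hidden(X)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        # ridge-regularized normal equations = regularized pseudoinverse
        A = H.T @ H + self.ridge * np.eye(self.n_hidden)
        self.beta_ = np.linalg.solve(A, H.T @ T)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._hidden(np.asarray(X, dtype=float)) @ self.beta_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def train_elm(
    scores_train: np.ndarray, y_train: np.ndarray, n_hidden: int, seed: int
) -> ELMClassifier:
    """Fit an :class:`ELMClassifier` (functional surface)."""
    return ELMClassifier(n_hidden=n_hidden, seed=seed).fit(scores_train, y_train)


# ---------------------------------------------------------------------------
# Baseline pipeline


#: feature-input names accepted by :class:`BaselineSpec`, mapped to the keys
#: produced by :func:`lvdlnet.models.featurize_dataset`
_FEATURE_KEYS = {
    "libs_peaks": "libs_peaks",
    "libs_intervals": "libs_intervals",
    "vnir_intervals": "vnir_slopes",
    "vnir_full": "vnir_full",
}

_CLASSIFIERS = ("lda", "knn", "svm", "elm")


@dataclass
class BaselineSpec:
    """One conventional-chemometrics run: input -> PCA -> classifier."""

    feature_input: str
    classifier: str
    n_components: int | float = 0.99
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_input not in _FEATURE_KEYS:
            raise ValueError(
                f"feature_input must be one of {sorted(_FEATURE_KEYS)}"
            )
        if self.classifier not in _CLASSIFIERS:
            raise ValueError(f"classifier must be one of {_CLASSIFIERS}")

    @property
    def name(self) -> str:
        return f"PCA-{self.classifier.upper()}[{self.feature_input}]"


def _make_classifier(spec: BaselineSpec):
    hp = spec.hyperparams
    if spec.classifier == "lda":
        return LinearDiscriminantAnalysis()
    if spec.classifier == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("k", 5))
    if spec.classifier == "svm":
        return SVC(kernel=hp.get("kernel", "rbf"), C=hp.get("C", 10.0),
                   gamma=hp.get("gamma", "scale"), random_state=spec.seed)
    return ELMClassifier(n_hidden=hp.get("n_hidden", 200), seed=spec.seed)


def run_baseline(
    spec: BaselineSpec,
    features: dict[str, np.ndarray],
    labels: np.ndarray,
    split: SplitIndices,
    n_classes: int = 6,
) -> MetricsReport:
    """Fit one baseline on the training rows, score it on the test rows.

    All fitting (z-score, PCA, classifier) sees training rows only.
    """
    X = np.asarray(features[_FEATURE_KEYS[spec.feature_input]], dtype=float)
    X = X.reshape(X.shape[0], -1)
    y = np.asarray(labels, dtype=int)

    scaler = ZScorer().fit(X[split.train])
    X_train = scaler.transform(X[split.train])
    X_test = scaler.transform(X[split.test])

    n_comp = spec.n_components
    if isinstance(n_comp, (int, np.integer)):
        n_comp = min(n_comp, X_train.shape[0] - 1, X_train.shape[1])
    scores_train, scores_test, _ = pca_reduce(X_train, X_test, n_comp)

    clf = _make_classifier(spec)
    clf.fit(scores_train, y[split.train])
    y_pred = clf.predict(scores_test)
    return macro_metrics(confusion(y[split.test], y_pred, n_classes))


def comparison_table(
    baseline_specs: list[BaselineSpec],
    deep_reports: dict[str, MetricsReport],
    features: dict[str, np.ndarray],
    labels: np.ndarray,
    split: SplitIndices,
    n_classes: int = 6,
) -> pd.DataFrame:
    """One row per method with Acc / Mac_F / Mac_P / Mac_R.

    ``deep_reports`` maps a model name (e.g. ``"DL-LIBS"``) to its
    already-computed test metrics so deep models and baselines share the
    same dataset and split.
    """
    rows = []
    for spec in baseline_specs:
        report = run_baseline(spec, features, labels, split, n_classes)
        rows.append({"model": spec.name, **report.to_dict()})
    for name, report in deep_reports.items():
        rows.append({"model": name, **report.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Visualization


def embed_tsne(X: np.ndarray, seed: int, perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE embedding (thin wrapper, plotting use only)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("t-SNE embedding needs at least 10 samples")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    )
    return tsne.fit_transform(X)
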