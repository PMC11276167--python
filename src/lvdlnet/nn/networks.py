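"""The three classifier networks.

* :class:`LibsNet` — element branch: one shared width-14 convolution scores
  each standardized line interval, the 18 per-line values form a
  wavelength-ordered sequence fed to a bidirectional LSTM, and a dense head
  with batch normalization and dropout produces the class logits.
* :class:`VnirNet` — molecular branch: the 370 slope features go through a
  dense layer with batch normalization and dropout, then a linear head.
* :class:`FusionNet` — both branch extractors (without their heads) are
  projected to a common dimension ``d``, added elementwise, and classified;
  everything is trained jointly end to end.

Each network exposes ``forward(x, train) -> logits``, ``backward(dlogits)``,
``predict_proba`` (evaluation mode), flat parameter access for the
optimizer, and ``get_state``/``set_state`` for best-epoch checkpointing.
"""

from __future__ import annotations

import copy

import numpy as np

from .layers import (
    BatchNorm1d,
    BiLSTM,
    Dense,
    Dropout,
    Layer,
    LineConv,
    ReLU,
    Tanh,
    softmax,
)

__all__ = ["LibsNet", "VnirNet", "FusionNet"]


class _Network:
    """Shared plumbing: parameter flattening and state checkpointing."""

    n_classes: int

    def layers(self) -> list[Layer]:
        raise NotImplementedError

    def forward(self, x, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def param_layers(self) -> list[Layer]:
        return self.layers()

    def get_state(self) -> list[dict]:
        return [
            {
                "params": copy.deepcopy(l.params),
                "state": copy.deepcopy(l.state),
            }
            for l in self.param_layers()
        ]

    def set_state(self, state: list[dict]) -> None:
        for l, s in zip(self.param_layers(), state, strict=True):
            for k in l.params:
                l.params[k][...] = s["params"][k]
            for k in l.state:
                l.state[k][...] = s["state"][k]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = softmax(self.forward(x, train=False))
        return p

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=-1)


class _DenseHead:
    """Dense -> ReLU -> BatchNorm -> Dropout -> Dense classifier head.

    Normalization sits after the activation: placed before it, the
    batch-mean subtraction erases the absolute activation level within each
    batch, which carries most of the class signal when the classes are
    ordered along a single direction in feature space (the adulteration
    fraction), and its scale-invariance also defeats the L2 penalty.
    """

    def __init__(self, n_in, n_hidden, n_out, dropout, rng):
        self.fc1 = Dense(n_in, n_hidden, rng)
        self.act = ReLU()
        self.bn = BatchNorm1d(n_hidden)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Dense(n_hidden, n_out, rng)
        self.chain = [self.fc1, self.act, self.bn, self.drop, self.fc2]

    def forward(self, x, train):
        for l in self.chain:
            x = l.forward(x, train)
        return x

    def backward(self, d):
        for l in reversed(self.chain):
            d = l.backward(d)
        return d


class LibsNet(_Network):
    """DL-LIBS: shared line convolution -> Bi-LSTM -> dense head."""

    def __init__(
        self,
        n_lines: int = 18,
        kernel: int = 14,
        lstm_hidden: int = 32,
        dense: int = 64,
        n_classes: int = 6,
        dropout: float = 0.3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.n_lines = n_lines
        self.kernel = kernel
        self.n_classes = n_classes
        self.conv = LineConv(kernel, rng)
        self.conv_act = Tanh()
        self.rnn = BiLSTM(1, lstm_hidden, rng)
        self.head = _DenseHead(2 * lstm_hidden, dense, n_classes, dropout, rng)

    def layers(self):
        return [self.conv, self.conv_act, self.rnn] + self.head.chain

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, :, :]
        if x.ndim != 3 or x.shape[1] != self.n_lines or x.shape[2] != self.kernel:
            raise ValueError(
                f"expected line-feature input (B, {self.n_lines}, {self.kernel}),"
                f" got {x.shape}"
            )
        return x

    def extract(self, x, train=False):
        """Branch features before the head, shape (B, 2*lstm_hidden)."""
        x = self._check(x)
        u = self.conv_act.forward(self.conv.forward(x, train), train)
        return self.rnn.forward(u[:, :, None], train)

    def forward(self, x, train=False):
        return self.head.forward(self.extract(x, train), train)

    def backward_extract(self, dfeat):
        du = self.rnn.backward(dfeat)[:, :, 0]
        self.conv.backward(self.conv_act.backward(du))

    def backward(self, dlogits):
        self.backward_extract(self.head.backward(dlogits))


class VnirNet(_Network):
    """DL-VNIR: slope vector -> dense layer (BN, ReLU, dropout) -> linear head."""

    def __init__(
        self,
        n_features: int = 370,
        dense: int = 64,
        n_classes: int = 6,
        dropout: float = 0.3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.n_features = n_features
        self.n_classes = n_classes
        self.fc = Dense(n_features, dense, rng)
        self.act = ReLU()
        self.bn = BatchNorm1d(dense)  # after the activation; see _DenseHead
        self.drop = Dropout(dropout, rng)
        self.out = Dense(dense, n_classes, rng)
        self._extract_chain = [self.fc, self.act, self.bn, self.drop]

    def layers(self):
        return self._extract_chain + [self.out]

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError(
                f"expected slope-feature input (B, {self.n_features}), got {x.shape}"
            )
        return x

    def extract(self, x, train=False):
        x = self._check(x)
        for l in self._extract_chain:
            x = l.forward(x, train)
        return x

    def forward(self, x, train=False):
        return self.out.forward(self.extract(x, train), train)

    def backward_extract(self, dfeat):
        d = dfeat
        for l in reversed(self._extract_chain):
            d = l.backward(d)

    def backward(self, dlogits):
        self.backward_extract(self.out.backward(dlogits))


class FusionNet(_Network):
    """LVDLNet: Add-fusion of the two branch extractors.

    Branch outputs of different widths are mapped by learned linear
    projections to a common dimension ``d`` and added elementwise; the sum
    passes through ReLU and dropout into the classification layer.
    """

    def __init__(
        self,
        n_lines: int = 18,
        kernel: int = 14,
        n_vnir_features: int = 370,
        lstm_hidden: int = 32,
        dense: int = 64,
        fusion_dim: int = 64,
        n_classes: int = 6,
        dropout: float = 0.3,
        seed: int = 0,
    ):
        ss = np.random.SeedSequence(seed).spawn(3)
        self.n_classes = n_classes
        self.fusion_dim = fusion_dim
        self.libs = LibsNet(
            n_lines, kernel, lstm_hidden, dense, n_classes, dropout,
            seed=int(ss[0].generate_state(1)[0] % (2**31)),
        )
        self.vnir = VnirNet(
            n_vnir_features, dense, n_classes, dropout,
            seed=int(ss[1].generate_state(1)[0] % (2**31)),
        )
        rng = np.random.default_rng(ss[2])
        self.proj_libs = Dense(2 * lstm_hidden, fusion_dim, rng)
        self.proj_vnir = Dense(dense, fusion_dim, rng)
        self.act = ReLU()
        self.drop = Dropout(dropout, rng)
        self.out = Dense(fusion_dim, n_classes, rng)

    def layers(self):
        # branch extractors only: the single-modality heads are not part of
        # the fused graph
        return (
            [self.libs.conv, self.libs.conv_act, self.libs.rnn]
            + self.vnir._extract_chain
            + [self.proj_libs, self.proj_vnir, self.act, self.drop, self.out]
        )

    def forward(self, x, train=False):
        x_libs, x_vnir = x
        z = self.proj_libs.forward(
            self.libs.extract(x_libs, train), train
        ) + self.proj_vnir.forward(self.vnir.extract(x_vnir, train), train)
        z = self.drop.forward(self.act.forward(z, train), train)
        return self.out.forward(z, train)

    def backward(self, dlogits):
        d = self.act.backward(self.drop.backward(self.out.backward(dlogits)))
        self.libs.backward_extract(self.proj_libs.backward(d))
        self.vnir.backward_extract(self.proj_vnir.backward(d))

    def predict_proba(self, x):
        x_libs, x_vnir = x
        x_libs = self.libs._check(x_libs)
        x_vnir = self.vnir._check(x_vnir)
        return softmax(self.forward((x_libs, x_vnir), train=False))
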