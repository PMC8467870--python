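"""The four base classifiers of the stacking ensemble.

* waveform 1-D CNN: four conv blocks on the raw 6000-sample segment
  (kernel lengths 50, 30, 10, 2; widths 20/20, 20/24, 12/12, 12/12), each
  block two valid convolutions with ReLU then max-pool 2, global average
  pooling to a 12-vector, dense softmax to 2;
* band-power RNN: bidirectional LSTM (20 per direction) over the 29x8
  band-power matrix, uni-directional LSTM (10, last state), dense 32 with
  ReLU, dense softmax to 2;
* random forest on the 1x42 expert features;
* pre-merged CNN+RNN: the CNN's 12-vector and the RNN's 32-vector
  concatenated into a 44-vector feeding a dense softmax head.

Inputs are standardized before the neural models: per-segment z-scoring for
the raw waveform, per-column log-then-z-scoring for the band powers (powers
span decades).  Standardization statistics are learned on the training set
and recorded in the model manifest.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .config import ForestConfig, TrainConfig

__all__ = [
    "build_cnn",
    "build_rnn",
    "build_premerge",
    "build_forest",
    "CnnClassifier",
    "RnnClassifier",
    "PreMergeClassifier",
    "ForestClassifier",
    "train_submodel",
]

SEGMENT_LEN = 6000
BAND_SHAPE = (29, 8)
CNN_EMBED = 12
RNN_EMBED = 32
MERGED_EMBED = CNN_EMBED + RNN_EMBED  # 44

# (kernel, c_in, c_out) per conv layer; a max-pool follows every second conv.
_CNN_LAYOUT = [
    (50, 1, 20), (50, 20, 20),
    (30, 20, 20), (30, 20, 24),
    (10, 24, 12), (10, 12, 12),
    (2, 12, 12), (2, 12, 12),
]


@dataclass
class LayerCensus:
    name: str
    n_params: int
    out_shape: tuple


def _census(model: nn.Sequential, in_shape: tuple) -> list[LayerCensus]:
    rows = []
    shape = in_shape
    for layer in model.layers:
        shape = layer.out_shape(shape)
        rows.append(LayerCensus(layer.name, layer.n_params, shape))
    return rows


def build_cnn(rng: np.random.Generator | int = 0):
    """Build the waveform CNN trunk + head; returns (trunk, head, census).

    The trunk ends at the global-average-pooled 12-vector (the embedding tap
    point used by the pre-merge model); the head is the dense softmax layer.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    layers: list[nn.Layer] = []
    conv_i = 0
    for block in range(4):
        for _ in range(2):
            k, ci, co = _CNN_LAYOUT[conv_i]
            conv_i += 1
            layers.append(nn.Conv1D(k, ci, co, rng, name=f"conv1d{conv_i}"))
            layers.append(nn.ReLU())
        pool = nn.MaxPool2()
        pool.name = f"maxpool{block + 1}"
        layers.append(pool)
    gap = nn.GlobalAvgPool()
    layers.append(gap)
    trunk = nn.Sequential(layers)
    head = nn.Dense(CNN_EMBED, 2, rng, name="dense_out")
    full = nn.Sequential(trunk.layers + [head])
    return trunk, head, _census(full, (SEGMENT_LEN, 1))


def build_rnn(rng: np.random.Generator | int = 0):
    """Build the band-power RNN trunk + head; returns (trunk, head, census).

    The trunk ends at the 32-vector after the ReLU dense layer (the pre-merge
    tap point); the head is the dense softmax layer.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    layers: list[nn.Layer] = [
        nn.Bidirectional(8, 20, rng, name="bilstm"),
        nn.LSTM(40, 10, rng, return_sequences=False, name="lstm"),
        nn.Dense(10, 32, rng, name="dense32"),
        nn.ReLU(),
    ]
    trunk = nn.Sequential(layers)
    head = nn.Dense(RNN_EMBED, 2, rng, name="dense_out")
    full = nn.Sequential(trunk.layers + [head])
    return trunk, head, _census(full, BAND_SHAPE)


def cnn_shape_trace() -> list[int]:
    """Time-axis lengths through the CNN, input to embedding to logits."""
    trunk, head, _ = build_cnn(0)
    shapes = nn.Sequential(trunk.layers + [head]).shape_trace((SEGMENT_LEN, 1))
    return [s[0] for s in shapes]


def _standardize_wave(X: np.ndarray) -> np.ndarray:
    """Per-segment z-score of raw waveforms (B, 6000) -> (B, 6000, 1)."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ((X - mu) / sd)[:, :, None].astype(nn.DTYPE)


@dataclass
class BandScaler:
    """log10(x + eps) then per-column z-score, fitted on training data."""

    eps: float = 1e-12
    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "BandScaler":
        z = np.log10(X + self.eps)
        self.mean = z.mean(axis=(0, 1))
        self.std = z.std(axis=(0, 1))
        self.std[self.std == 0] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        z = np.log10(X + self.eps)
        return ((z - self.mean) / self.std).astype(nn.DTYPE)


class _NetBase:
    """Shared training loop: Adam, mini-batches, early stopping on val loss."""

    trunk: nn.Sequential
    head: nn.Dense

    def _full(self) -> nn.Sequential:
        return nn.Sequential(self.trunk.layers + [self.head])

    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        return self._full().forward(X, train)

    def _backward(self, dlogits: np.ndarray) -> None:
        self._full().backward(dlogits)

    def _prepare(self, X: np.ndarray, fit_scaler: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None):
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)
        Xp = self._prepare(X, fit_scaler=True)
        y = np.asarray(y, dtype=np.int64)
        n = len(y)
        n_val = max(1, int(round(config.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = Xp[tr_idx], y[tr_idx]
        Xval, yval = Xp[val_idx], y[val_idx]

        params = self._full().params()
        opt = nn.Adam(params, lr=config.learning_rate)
        best_val = np.inf
        best_state = None
        bad_epochs = 0
        self.history: list[dict[str, float]] = []
        for epoch in range(config.max_epochs):
            order = rng.permutation(len(ytr))
            total, count = 0.0, 0
            for i0 in range(0, len(order), config.batch_size):
                idx = order[i0 : i0 + config.batch_size]
                logits = self._forward(Xtr[idx], train=True)
                loss, dlogits = nn.softmax_xent(logits, ytr[idx])
                opt.zero_grad()
                self._backward(dlogits)
                opt.step()
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf training loss at epoch {epoch}, batch {i0 // config.batch_size}"
                    )
                total += loss * len(idx)
                count += len(idx)
            val_loss = self._eval_loss(Xval, yval, config.batch_size)
            self.history.append({"epoch": epoch, "train_loss": total / count,
                                 "val_loss": val_loss})
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = [p.value.copy() for _, p in params]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    break
        if best_state is not None:
            for (_, p), v in zip(params, best_state):
                p.value[...] = v
        self.fitted = True
        return self

    def _eval_loss(self, X: np.ndarray, y: np.ndarray, batch: int) -> float:
        total, count = 0.0, 0
        for i0 in range(0, len(y), batch):
            logits = self._forward(X[i0 : i0 + batch], train=False)
            loss, _ = nn.softmax_xent(logits, y[i0 : i0 + batch])
            total += loss * len(y[i0 : i0 + batch])
            count += len(y[i0 : i0 + batch])
        return total / count

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """(n, 2) array of (p_normal, p_arousal) rows summing to 1."""
        if not getattr(self, "fitted", False):
            raise RuntimeError("model is not trained")
        Xp = self._prepare(X, fit_scaler=False)
        out = []
        for i0 in range(0, len(Xp), batch):
            logits = self._forward(Xp[i0 : i0 + batch], train=False)
            out.append(nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def embed(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """The trunk output (embedding tap point) for each input."""
        Xp = self._prepare(X, fit_scaler=False)
        out = []
        for i0 in range(0, len(Xp), batch):
            out.append(self.trunk.forward(Xp[i0 : i0 + batch], train=False))
        return np.concatenate(out, axis=0)

    def manifest(self) -> dict[str, Any]:
        census = [(c.name, c.n_params) for c in self.census]
        return {
            "architecture": type(self).__name__,
            "parameter_census": census,
            "n_params_total": int(sum(n for _, n in census)),
        }


class CnnClassifier(_NetBase):
    """Waveform 1-D CNN sub-model (input: raw 6000-sample segments)."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.trunk, self.head, self.census = build_cnn(rng)
        self.fitted = False

    def _prepare(self, X, fit_scaler):
        return _standardize_wave(np.asarray(X))


class RnnClassifier(_NetBase):
    """Band-power LSTM sub-model (input: 29x8 band matrices)."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.trunk, self.head, self.census = build_rnn(rng)
        self.scaler = BandScaler()
        self.fitted = False

    def _prepare(self, X, fit_scaler):
        X = np.asarray(X)
        if fit_scaler:
            self.scaler.fit(X)
        return self.scaler.transform(X)


class PreMergeClassifier:
    """Merged CNN+RNN: concatenated 44-vector embedding, dense softmax head.

    Trunks are initialized from already-trained CNN and RNN sub-models and
    fine-tuned end-to-end by default (``freeze_trunks=True`` trains only the
    merged head).
    """

    def __init__(self, cnn: CnnClassifier, rnn: RnnClassifier, seed: int = 0,
                 freeze_trunks: bool = False):
        if not (cnn.fitted and rnn.fitted):
            raise RuntimeError("pre-merge requires trained CNN and RNN sub-models")
        self.cnn = copy.deepcopy(cnn)
        self.rnn = copy.deepcopy(rnn)
        rng = np.random.default_rng(seed)
        self.head = nn.Dense(MERGED_EMBED, 2, rng, name="merge_dense_out")
        self.freeze_trunks = freeze_trunks
        self.fitted = False

    def _forward(self, Xw, Xb, train):
        e1 = self.cnn.trunk.forward(Xw, train and not self.freeze_trunks)
        e2 = self.rnn.trunk.forward(Xb, train and not self.freeze_trunks)
        self._e_shapes = (e1.shape[1], e2.shape[1])
        merged = np.concatenate([e1, e2], axis=1)
        return self.head.forward(merged, train)

    def _backward(self, dlogits):
        dmerged = self.head.backward(dlogits)
        if not self.freeze_trunks:
            d1, d2 = self._e_shapes
            self.cnn.trunk.backward(dmerged[:, :d1])
            self.rnn.trunk.backward(dmerged[:, d1:])

    def _params(self):
        ps = self.head.params()
        if not self.freeze_trunks:
            ps = self.cnn.trunk.params() + self.rnn.trunk.params() + ps
        return ps

    def fit(self, Xw: np.ndarray, Xb: np.ndarray, y: np.ndarray,
            config: TrainConfig | None = None):
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)
        Xwp = self.cnn._prepare(Xw, fit_scaler=False)
        Xbp = self.rnn._prepare(Xb, fit_scaler=False)
        y = np.asarray(y, dtype=np.int64)
        n = len(y)
        n_val = max(1, int(round(config.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        params = self._params()
        opt = nn.Adam(params, lr=config.learning_rate)
        best_val, best_state, bad = np.inf, None, 0
        self.history = []
        for epoch in range(config.max_epochs):
            order = rng.permutation(len(tr_idx))
            total, count = 0.0, 0
            for i0 in range(0, len(order), config.batch_size):
                idx = tr_idx[order[i0 : i0 + config.batch_size]]
                logits = self._forward(Xwp[idx], Xbp[idx], train=True)
                loss, dlogits = nn.softmax_xent(logits, y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(f"NaN/inf training loss at epoch {epoch}")
                opt.zero_grad()
                self._backward(dlogits)
                opt.step()
                total += loss * len(idx)
                count += len(idx)
            val_loss = self._val_loss(Xwp[val_idx], Xbp[val_idx], y[val_idx],
                                      config.batch_size)
            self.history.append({"epoch": epoch, "train_loss": total / count,
                                 "val_loss": val_loss})
            if val_loss < best_val - 1e-6:
                best_val, bad = val_loss, 0
                best_state = [p.value.copy() for _, p in params]
            else:
                bad += 1
                if bad >= config.patience:
                    break
        if best_state is not None:
            for (_, p), v in zip(params, best_state):
                p.value[...] = v
        self.fitted = True
        return self

    def _val_loss(self, Xw, Xb, y, batch):
        total, count = 0.0, 0
        for i0 in range(0, len(y), batch):
            logits = self._forward(Xw[i0 : i0 + batch], Xb[i0 : i0 + batch], train=False)
            loss, _ = nn.softmax_xent(logits, y[i0 : i0 + batch])
            total += loss * len(y[i0 : i0 + batch])
            count += len(y[i0 : i0 + batch])
        return total / count

    def predict_proba(self, Xw: np.ndarray, Xb: np.ndarray, batch: int = 256) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not trained")
        Xwp = self.cnn._prepare(Xw, fit_scaler=False)
        Xbp = self.rnn._prepare(Xb, fit_scaler=False)
        out = []
        for i0 in range(0, len(Xwp), batch):
            logits = self._forward(Xwp[i0 : i0 + batch], Xbp[i0 : i0 + batch], train=False)
            out.append(nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def embedding_dim(self) -> int:
        return MERGED_EMBED


def build_premerge(cnn: CnnClassifier, rnn: RnnClassifier, seed: int = 0,
                   freeze_trunks: bool = False) -> PreMergeClassifier:
    return PreMergeClassifier(cnn, rnn, seed=seed, freeze_trunks=freeze_trunks)


class ForestClassifier:
    """Random forest on the 42 expert features (scikit-learn backend)."""

    N_FEATURES = 42

    def __init__(self, config: ForestConfig | None = None):
        self.config = config or ForestConfig()
        self.model = RandomForestClassifier(
            n_estimators=self.config.n_trees,
            max_depth=self.config.max_depth,
            max_features="sqrt",
            class_weight=self.config.class_weight,
            random_state=self.config.seed,
            n_jobs=1,
        )
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray, config=None):
        X = np.asarray(X)
        if X.shape[1] != self.N_FEATURES:
            raise ValueError(f"expected {self.N_FEATURES} features, got {X.shape[1]}")
        self.model.fit(X, np.asarray(y, dtype=np.int64))
        self.fitted = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not trained")
        p = self.model.predict_proba(np.asarray(X))
        if p.shape[1] == 1:  # degenerate single-class training set
            p = np.column_stack([1.0 - p[:, 0], p[:, 0]])
        return p


def build_forest(config: ForestConfig | None = None) -> ForestClassifier:
    return ForestClassifier(config)


def train_submodel(model, X, y, config: TrainConfig | None = None):
    """Uniform trainer entry point for any sub-model."""
    return model.fit(X, y, config)
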