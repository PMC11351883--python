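"""The end-to-end hemodynamic regression network and its estimator wrapper.

Architecture: six residual 1-D convolutional blocks followed by a
bidirectional GRU and a 4-cell dense head.  Each block's main branch is
[BN -> ReLU (omitted at the very start of block 1)] -> Conv1D -> BN -> ReLU
-> Dropout -> Conv1D(stride s); the shortcut branch is a max-pool whose
size matches the stride (2 in blocks 1, 3 and 5, else 1), with a 1x1
projection convolution when the channel count changes (block 5, 32 -> 64).
Every convolution uses kernel length 16; kernel numbers are
(32, 32, 32, 32, 64, 64).  Three stride-2 blocks downsample the 1000-sample
input to a 125-step feature sequence; the Bi-GRU (32 units per direction)
summarizes it into a 64-dimensional feature (concatenated final hidden
states by default, temporal mean pooling selectable) which, after BN and
LeakyReLU, feeds the dense layer producing the four scaled outputs.

Training minimizes mean squared error on the scaled targets (SBP/50,
DBP/10, MRR/2000, MRD/1000) with Adam at learning rate 0.001 (plain SGD
selectable); the checkpoint kept is the epoch with the smallest validation
loss.

:class:`HemodynamicRegressor` wraps all of this in the scikit-learn
estimator protocol (``fit``/``predict``/``get_params``/``set_params``,
fitted attributes with trailing underscores) so it composes with sklearn
model selection; :func:`build_model`, :func:`train`, :func:`forward` and
:func:`predict` are thin functional wrappers.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .labels import SCALE_DIVISORS, HemodynamicLabel, inverse_scale, scale_targets

__all__ = [
    "HemodynamicNet",
    "HemodynamicRegressor",
    "ModelConfig",
    "ResidualBlock",
    "ResidualBlockSpec",
    "build_model",
    "forward",
    "predict",
    "train",
]


@dataclass(frozen=True)
class ResidualBlockSpec:
    """Per-block hyper-parameters (two convolutions sharing kernel length)."""

    kernel_length: int
    kernel_number: int
    second_conv_stride: int
    pooling_size: int
    first_block: bool = False

    def __post_init__(self) -> None:
        if self.second_conv_stride != self.pooling_size:
            raise ValueError(
                "second-conv stride must equal the shortcut pooling size "
                f"({self.second_conv_stride} != {self.pooling_size}): "
                "branches would disagree in length"
            )


@dataclass
class ModelConfig:
    """Hyper-parameters of the regression network.

    Defaults reproduce the published topology: 1000-sample two-channel
    input, kernel length 16 everywhere, kernel numbers
    (32, 32, 32, 32, 64, 64), stride/pool 2 in blocks 1, 3, 5 (net temporal
    downsampling 8x), 32 GRU units per direction, a 4-cell dense head,
    batch size 64, learning rate 0.001, MSE loss, 200 epochs.
    """

    input_length: int = 1000
    input_channels: int = 2
    kernel_length: int = 16
    kernel_numbers: tuple[int, ...] = (32, 32, 32, 32, 64, 64)
    downsample_blocks: tuple[int, ...] = (1, 3, 5)  # 1-based block positions
    dropout_rate: float = 0.2
    gru_units: int = 32
    dense_cells: int = 4
    batch_size: int = 64
    learning_rate: float = 0.001
    epochs: int = 200
    optimizer: str = "adam"
    aggregation: str = "final"  # or "mean"
    leaky_alpha: float = 0.01
    seed: int = 0

    def block_specs(self) -> list[ResidualBlockSpec]:
        specs = []
        for i, kn in enumerate(self.kernel_numbers, start=1):
            s = 2 if i in self.downsample_blocks else 1
            specs.append(
                ResidualBlockSpec(self.kernel_length, kn, s, s, first_block=(i == 1))
            )
        return specs

    @property
    def downsampling_factor(self) -> int:
        return int(np.prod([2 for i in self.downsample_blocks]))

    def to_dict(self) -> dict:
        return asdict(self)


class ResidualBlock:
    """One residual unit: pre-activated conv main branch + pooled shortcut."""

    def __init__(self, in_channels: int, spec: ResidualBlockSpec,
                 dropout_rate: float, rng: np.random.Generator, dtype=np.float32) -> None:
        self.spec = spec
        k, c = spec.kernel_length, spec.kernel_number
        self.pre: list[nn.Layer] = []
        if not spec.first_block:
            self.pre = [nn.BatchNorm(in_channels, dtype=dtype), nn.ReLU()]
        self.main: list[nn.Layer] = [
            nn.Conv1D(in_channels, c, k, stride=1, rng=rng, dtype=dtype),
            nn.BatchNorm(c, dtype=dtype),
            nn.ReLU(),
            nn.Dropout(dropout_rate, rng),
            nn.Conv1D(c, c, k, stride=spec.second_conv_stride, rng=rng, dtype=dtype),
        ]
        self.pool = nn.MaxPool1D(spec.pooling_size)
        # 1x1 projection keeps the identity shortcut when channels change.
        self.proj = (
            nn.Conv1D(in_channels, c, 1, stride=1, rng=rng, dtype=dtype)
            if in_channels != c
            else None
        )

    @property
    def layers(self) -> list[nn.Layer]:
        out = self.pre + self.main + [self.pool]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.pre:
            x = layer.forward(x, training)
        main = x
        for layer in self.main:
            main = layer.forward(main, training)
        short = self.pool.forward(x, training)
        if self.proj is not None:
            short = self.proj.forward(short, training)
        if main.shape != short.shape:
            raise ValueError(f"branch shape mismatch {main.shape} vs {short.shape}")
        return main + short

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dmain = dy
        for layer in reversed(self.main):
            dmain = layer.backward(dmain)
        dshort = dy
        if self.proj is not None:
            dshort = self.proj.backward(dshort)
        dshort = self.pool.backward(dshort)
        dx = dmain + dshort
        for layer in reversed(self.pre):
            dx = layer.backward(dx)
        return dx


class HemodynamicNet:
    """The full residual-CNN + Bi-GRU regression network."""

    def __init__(self, config: ModelConfig, dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        self.rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        cin = config.input_channels
        self.blocks: list[ResidualBlock] = []
        for spec in config.block_specs():
            self.blocks.append(ResidualBlock(cin, spec, config.dropout_rate, self.rng, dtype))
            cin = spec.kernel_number
        self.bigru = nn.BiGRU(cin, config.gru_units, self.rng, dtype)
        feat = 2 * config.gru_units
        self.head_bn = nn.BatchNorm(feat, dtype=dtype)
        self.head_act = nn.LeakyReLU(config.leaky_alpha)
        self.dense = nn.Dense(feat, config.dense_cells, self.rng, dtype)
        self._layers = (
            [lay for blk in self.blocks for lay in blk.layers]
            + [self.bigru, self.head_bn, self.dense]
        )

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for lay in self._layers for p in lay.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lay in self._layers for g in lay.grads]

    def get_weights(self) -> list[np.ndarray]:
        bn_state = [
            (b.running_mean.copy(), b.running_var.copy())
            for b in self._bn_layers()
        ]
        return [copy.deepcopy([p.copy() for p in self.params]), bn_state]

    def set_weights(self, state) -> None:
        saved, bn_state = state
        for p, s in zip(self.params, saved):
            p[...] = s
        for b, (m, v) in zip(self._bn_layers(), bn_state):
            b.running_mean[...] = m
            b.running_var[...] = v

    def _bn_layers(self) -> list[nn.BatchNorm]:
        return [lay for lay in self._layers if isinstance(lay, nn.BatchNorm)]

    # -- forward / backward -------------------------------------------------
    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Feature sequence after the residual stack: ``(B, 125, 64)``."""
        for blk in self.blocks:
            x = blk.forward(x, training)
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1:] != (self.config.input_length, self.config.input_channels):
            raise ValueError(
                f"expected input (n, {self.config.input_length}, "
                f"{self.config.input_channels}), got {x.shape}"
            )
        seq = self.features(x, training)
        gru_out = self.bigru.forward(seq, training)  # (B, T, 2H)
        self._gru_T = gru_out.shape[1]
        h = self.config.gru_units
        if self.config.aggregation == "final":
            feat = np.concatenate([gru_out[:, -1, :h], gru_out[:, 0, h:]], axis=1)
        elif self.config.aggregation == "mean":
            feat = gru_out.mean(axis=1)
        else:
            raise ValueError(f"unknown aggregation {self.config.aggregation!r}")
        z = self.head_bn.forward(feat, training)
        z = self.head_act.forward(z, training)
        return self.dense.forward(z, training)

    def backward(self, dy: np.ndarray) -> None:
        dz = self.dense.backward(dy)
        dz = self.head_act.backward(dz)
        dfeat = self.head_bn.backward(dz)
        b = dfeat.shape[0]
        h = self.config.gru_units
        t = self._gru_T
        dgru = np.zeros((b, t, 2 * h), dtype=self.dtype)
        if self.config.aggregation == "final":
            dgru[:, -1, :h] = dfeat[:, :h]
            dgru[:, 0, h:] = dfeat[:, h:]
        else:
            dgru += (dfeat / t)[:, None, :]
        dseq = self.bigru.backward(dgru)
        for blk in reversed(self.blocks):
            dseq = blk.backward(dseq)


def build_model(config: ModelConfig | None = None, dtype=np.float32) -> HemodynamicNet:
    """Construct the untrained network for a configuration."""
    return HemodynamicNet(config or ModelConfig(), dtype)


class HemodynamicRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for beat-wise hemodynamic regression.

    ``fit`` takes per-beat input windows ``X`` of shape ``(n, 1000, 2)``
    (or flattened ``(n, 2000)``) and targets ``y`` of shape ``(n, 4)`` in
    physical units (SBP mmHg, DBP mmHg, MRR mmHg/s, MRD mmHg/s); targets are
    scaled internally and predictions are returned in physical units.  A
    validation set may be passed explicitly (record-level splits should be
    built upstream to avoid leakage between nearby beats); otherwise a
    trailing fraction of the training beats is held out.  The retained
    weights are those of the epoch with minimum validation loss.

    Fitted attributes: ``net_``, ``history_`` (per-epoch train/val MSE on
    scaled targets), ``best_epoch_``, ``n_features_in_``.
    """

    def __init__(
        self,
        epochs: int = 200,
        batch_size: int = 64,
        learning_rate: float = 0.001,
        dropout_rate: float = 0.2,
        gru_units: int = 32,
        optimizer: str = "adam",
        aggregation: str = "final",
        validation_fraction: float = 0.25,
        input_length: int = 1000,
        input_channels: int = 2,
        seed: int = 0,
    ) -> None:
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.gru_units = gru_units
        self.optimizer = optimizer
        self.aggregation = aggregation
        self.validation_fraction = validation_fraction
        self.input_length = input_length
        self.input_channels = input_channels
        self.seed = seed

    # -- helpers ------------------------------------------------------------
    def _as_windows(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X.reshape(len(X), self.input_length, self.input_channels)
        if X.ndim != 3 or X.shape[1:] != (self.input_length, self.input_channels):
            raise ValueError(f"bad input shape {X.shape}")
        return X

    def _config(self) -> ModelConfig:
        return ModelConfig(
            input_length=self.input_length,
            input_channels=self.input_channels,
            dropout_rate=self.dropout_rate,
            gru_units=self.gru_units,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            optimizer=self.optimizer,
            aggregation=self.aggregation,
            seed=self.seed,
        )

    def _batched_loss(self, net: HemodynamicNet, X: np.ndarray, y: np.ndarray) -> float:
        total, n = 0.0, 0
        for lo in range(0, len(X), self.batch_size):
            xb, yb = X[lo : lo + self.batch_size], y[lo : lo + self.batch_size]
            pred = net.forward(xb, training=False)
            total += float(np.sum((pred - yb) ** 2))
            n += yb.size
        return total / n

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X = self._as_windows(X)
        y = np.asarray(y, dtype=np.float32)
        if y.ndim != 2 or y.shape[1] != 4:
            raise ValueError(f"targets must be (n, 4), got {y.shape}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training set")
        ys = scale_targets(y).astype(np.float32)
        if X_val is not None:
            Xv = self._as_windows(X_val)
            yv = scale_targets(np.asarray(y_val, dtype=np.float32)).astype(np.float32)
        else:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            if n_val >= len(X):
                raise ValueError("not enough beats to hold out a validation set")
            Xv, yv = X[-n_val:], ys[-n_val:]
            X, ys = X[:-n_val], ys[:-n_val]
        if len(Xv) == 0:
            raise ValueError("empty validation set")

        config = self._config()
        net = build_model(config)
        if self.optimizer == "adam":
            opt = nn.Adam(net.params, net.grads, lr=self.learning_rate)
        elif self.optimizer == "sgd":
            opt = nn.SGD(net.params, net.grads, lr=self.learning_rate)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        shuffle_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        history = {"train_loss": [], "val_loss": []}
        best_loss, best_state, best_epoch = np.inf, None, -1
        n = len(X)
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            running, seen = 0.0, 0
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                if len(idx) < 2:
                    continue  # batch statistics need >= 2 samples
                xb, yb = X[idx], ys[idx]
                pred = net.forward(xb, training=True)
                loss, dpred = nn.mse_loss(pred, yb)
                net.backward(dpred)
                opt.step()
                running += loss * yb.size
                seen += yb.size
            val_loss = self._batched_loss(net, Xv, yv)
            history["train_loss"].append(running / max(seen, 1))
            history["val_loss"].append(val_loss)
            if val_loss < best_loss:
                best_loss, best_epoch = val_loss, epoch
                best_state = net.get_weights()
        if best_state is not None:
            net.set_weights(best_state)
        self.net_ = net
        self.config_ = config
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_features_in_ = self.input_length * self.input_channels
        return self

    def decision_function(self, X) -> np.ndarray:
        """Scaled (dimensionless) network outputs, one 4-vector per beat."""
        check_is_fitted(self, "net_")
        X = self._as_windows(X)
        outs = []
        for lo in range(0, len(X), self.batch_size):
            outs.append(self.net_.forward(X[lo : lo + self.batch_size], training=False))
        return np.concatenate(outs, axis=0) if outs else np.empty((0, 4))

    def predict(self, X) -> np.ndarray:
        """Per-beat (SBP, DBP, MRR, MRD) predictions in physical units."""
        return inverse_scale(self.decision_function(X))


# ---------------------------------------------------------------------------
# Functional wrappers


def forward(net: HemodynamicNet | HemodynamicRegressor, windows: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass returning scaled 4-vectors."""
    if isinstance(net, HemodynamicRegressor):
        return net.decision_function(windows)
    return net.forward(np.asarray(windows, dtype=np.float32), training=False)


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig | None = None,
    **overrides,
) -> HemodynamicRegressor:
    """Train a regressor on explicit train/validation beat sets."""
    config = config or ModelConfig()
    est = HemodynamicRegressor(
        epochs=overrides.get("epochs", config.epochs),
        batch_size=overrides.get("batch_size", config.batch_size),
        learning_rate=overrides.get("learning_rate", config.learning_rate),
        dropout_rate=overrides.get("dropout_rate", config.dropout_rate),
        gru_units=overrides.get("gru_units", config.gru_units),
        optimizer=overrides.get("optimizer", config.optimizer),
        aggregation=overrides.get("aggregation", config.aggregation),
        input_length=config.input_length,
        input_channels=config.input_channels,
        seed=overrides.get("seed", config.seed),
    )
    return est.fit(X_train, y_train, X_val=X_val, y_val=y_val)


def predict(trained: HemodynamicRegressor, windows: np.ndarray) -> list[HemodynamicLabel]:
    """Predict beat labels in physical units, preserving input order."""
    values = trained.predict(windows)
    out = []
    for i, (sbp, dbp, mrr, mrd) in enumerate(values):
        sbp, dbp = max(sbp, dbp), min(sbp, dbp)  # enforce label invariants
        mrr, mrd = max(mrr, mrd), min(mrr, mrd)
        out.append(HemodynamicLabel(float(sbp), float(dbp), float(mrr), float(mrd), cycle_index=i))
    return out


# re-export for convenience: targets scale used by the estimator
TARGET_DIVISORS = SCALE_DIVISORS
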