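"""Compact convolutional network for raw-epoch EEG classification.

Architecture (fixed by design, for 60-channel x 200-sample epochs):

====================  ==========  ============  ==========
operation             activation  output shape  parameters
====================  ==========  ============  ==========
temporal conv 1x4     none        60 x 197 x12          60
spatio-temporal 60x4  ELU          1 x 194 x12      34,572
max-pool 1x4          -            1 x 48 x12            -
flatten + dropout .3  -           576                    -
dense 32              ELU          32              18,464
dense 1               sigmoid       1                  33
====================  ==========  ============  ==========

53,129 trainable parameters in total. Convolutions are valid (no padding),
stride 1; the pool uses width = stride = 4 with floor on the remainder.
Training is mini-batch Adam on class-weighted binary cross-entropy, fully
seeded (initialisation, shuffling, dropout). The implementation is plain
numpy: forward pass, analytic backprop and the optimiser are all written
out explicitly, which keeps the model dependency-light and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .containers import labels_to_int
from .metrics import auc


@dataclass(frozen=True)
class CNNSpec:
    """Architecture description; the defaults are the reference network."""

    n_channels: int = 60
    n_samples: int = 200
    n_filters: int = 12
    kernel: int = 4
    pool: int = 4
    dense_units: int = 32
    dropout: float = 0.30

    @property
    def shape_chain(self) -> list:
        """Output shapes layer by layer, as (channels, time) or flat sizes."""
        t1 = self.n_samples - self.kernel + 1
        t2 = t1 - self.kernel + 1
        tp = t2 // self.pool
        flat = tp * self.n_filters
        return [
            (self.n_channels, self.n_samples),
            (self.n_channels, t1),
            (1, t2),
            (1, tp),
            flat,
            self.dense_units,
            1,
        ]

    @property
    def parameter_counts(self) -> dict:
        """Closed-form per-layer trainable parameter counts."""
        f, k = self.n_filters, self.kernel
        flat = self.shape_chain[4]
        counts = {
            "conv_temporal": f * k + f,
            "conv_spatiotemporal": f * (self.n_channels * k * f) + f,
            "dense": self.dense_units * flat + self.dense_units,
            "output": self.dense_units + 1,
        }
        counts["total"] = sum(counts.values())
        return counts


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters (defaults are the reference protocol)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    batch_size: int = 32
    n_epochs: int = 25
    early_stopping: bool = False
    patience: int = 6
    validation_fraction: float = 0.2
    class_weighting: bool = True
    seed: int = 0


def _elu(z):
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z, a):
    # a = elu(z); derivative is 1 for z>0 else a+1
    return np.where(z > 0, 1.0, a + 1.0)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def class_weights(labels) -> dict:
    """Balanced per-class loss weights: N_total / (2 * N_class)."""
    y = labels_to_int(np.asarray(labels))
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to compute class weights")
    n = counts.sum()
    return {int(c): n / (2.0 * cnt) for c, cnt in zip(classes, counts)}


class MinMaxSymmetric:
    """Affine map of a whole epoch dataset onto [-1, 1].

    The global min/max are computed over every value of the fitted (training)
    dataset and frozen, so test epochs are transformed with the training map
    and inter-epoch amplitude relations are preserved. Constant data map to 0.
    """

    def __init__(self):
        self.lo = None
        self.hi = None

    def fit(self, X: np.ndarray) -> "MinMaxSymmetric":
        X = np.asarray(X)
        if X.size == 0:
            raise ValueError("cannot fit normaliser on empty data")
        self.lo = float(X.min())
        self.hi = float(X.max())
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise ValueError("normaliser not fitted")
        if self.hi == self.lo:
            return np.zeros_like(np.asarray(X, dtype=np.float64))
        return 2.0 * (np.asarray(X, dtype=np.float64) - self.lo) / (self.hi - self.lo) - 1.0

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def normalize_minmax(epochs: np.ndarray) -> np.ndarray:
    """Scale an epoch dataset to [-1, 1] using its global min/max."""
    return MinMaxSymmetric().fit_transform(epochs)


class ConvNet:
    """The two-stage convolutional classifier, with explicit backprop."""

    def __init__(self, spec: CNNSpec | None = None, seed: int = 0, dtype=np.float32):
        self.spec = spec or CNNSpec()
        self.dtype = dtype
        s = self.spec
        self.T1 = s.n_samples - s.kernel + 1
        self.T2 = self.T1 - s.kernel + 1
        self.Tp = self.T2 // s.pool
        self.flat = self.Tp * s.n_filters
        rng = np.random.default_rng(seed)

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape).astype(dtype)

        f, k, c = s.n_filters, s.kernel, s.n_channels
        self.W1 = glorot((f, k), k, k * f)
        self.b1 = np.zeros(f, dtype)
        # W2[k] maps the (channel, map) feature vector at lag k to the filters
        self.W2 = glorot((k, c * f, f), c * k * f, c * k * f)
        self.b2 = np.zeros(f, dtype)
        self.Wd1 = glorot((self.flat, s.dense_units), self.flat, s.dense_units)
        self.bd1 = np.zeros(s.dense_units, dtype)
        self.Wd2 = glorot((s.dense_units, 1), s.dense_units, 1)
        self.bd2 = np.zeros(1, dtype)
        self._adam_state = None

    # -- bookkeeping ------------------------------------------------------

    @property
    def params(self) -> dict:
        return {
            "W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
            "Wd1": self.Wd1, "bd1": self.bd1, "Wd2": self.Wd2, "bd2": self.bd2,
        }

    def set_params(self, values: dict):
        for k, v in values.items():
            getattr(self, k)[...] = v

    def parameter_counts(self) -> dict:
        """Counts of the actually allocated weights (cross-checks the spec)."""
        counts = {
            "conv_temporal": self.W1.size + self.b1.size,
            "conv_spatiotemporal": self.W2.size + self.b2.size,
            "dense": self.Wd1.size + self.bd1.size,
            "output": self.Wd2.size + self.bd2.size,
        }
        counts["total"] = sum(counts.values())
        return counts

    def shape_chain(self, batch: int = 1) -> list:
        return self.spec.shape_chain

    # -- forward / backward ----------------------------------------------

    def _check_input(self, X):
        s = self.spec
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[1] != s.n_channels or X.shape[2] != s.n_samples:
            raise ValueError(
                f"expected input (batch, {s.n_channels}, {s.n_samples}), got {X.shape}"
            )
        return X

    def _forward(self, X, train=False, drop_rng=None):
        s = self.spec
        f, k, c = s.n_filters, s.kernel, s.n_channels
        B = X.shape[0]
        Xw = sliding_window_view(X, k, axis=2)  # (B, c, T1, k) view
        A1 = (Xw.reshape(-1, k) @ self.W1.T).reshape(B, c, self.T1, f) + self.b1
        A1t = np.ascontiguousarray(A1.transpose(0, 2, 1, 3)).reshape(B, self.T1, c * f)
        Z2 = np.broadcast_to(self.b2, (B, self.T2, f)).copy()
        for j in range(k):
            Z2 += A1t[:, j : j + self.T2, :] @ self.W2[j]
        A2 = _elu(Z2)
        P = A2[:, : self.Tp * s.pool, :].reshape(B, self.Tp, s.pool, f)
        arg = P.argmax(axis=2)
        pooled = np.take_along_axis(P, arg[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(B, self.flat)
        if train and s.dropout > 0:
            mask = (drop_rng.random(flat.shape) >= s.dropout).astype(self.dtype) / (
                1.0 - s.dropout
            )
            flat = flat * mask
        else:
            mask = None
        Z3 = flat @ self.Wd1 + self.bd1
        A3 = _elu(Z3)
        z = (A3 @ self.Wd2 + self.bd2)[:, 0]
        p = _sigmoid(z)
        cache = dict(X=X, Xw=Xw, A1t=A1t, Z2=Z2, A2=A2, arg=arg, flat=flat,
                     mask=mask, Z3=Z3, A3=A3, z=z, p=p)
        return cache

    def _backward(self, cache, dz):
        """Gradients of the scalar loss w.r.t. all parameters; dz = dL/dz."""
        s = self.spec
        f, k, c = s.n_filters, s.kernel, s.n_channels
        B = dz.shape[0]
        g = {}
        A3, Z3, flat = cache["A3"], cache["Z3"], cache["flat"]
        dz = dz.astype(self.dtype)
        g["Wd2"] = A3.T @ dz[:, None]
        g["bd2"] = np.array([dz.sum()], dtype=self.dtype)
        dA3 = dz[:, None] @ self.Wd2.T
        dZ3 = dA3 * _elu_grad(Z3, A3)
        g["Wd1"] = flat.T @ dZ3
        g["bd1"] = dZ3.sum(axis=0)
        dflat = dZ3 @ self.Wd1.T
        if cache["mask"] is not None:
            dflat = dflat * cache["mask"]
        dpooled = dflat.reshape(B, self.Tp, f)
        dP = np.zeros((B, self.Tp, s.pool, f), dtype=self.dtype)
        np.put_along_axis(dP, cache["arg"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        dA2 = np.zeros((B, self.T2, f), dtype=self.dtype)
        dA2[:, : self.Tp * s.pool, :] = dP.reshape(B, self.Tp * s.pool, f)
        dZ2 = dA2 * _elu_grad(cache["Z2"], cache["A2"])
        g["b2"] = dZ2.sum(axis=(0, 1))
        A1t = cache["A1t"]
        dA1t = np.zeros_like(A1t)
        gW2 = np.empty_like(self.W2)
        for j in range(k):
            dA1t[:, j : j + self.T2, :] += dZ2 @ self.W2[j].T
            gW2[j] = np.tensordot(dZ2, A1t[:, j : j + self.T2, :], axes=([0, 1], [0, 1])).T
        g["W2"] = gW2
        dA1 = dA1t.reshape(B, self.T1, c, f).transpose(0, 2, 1, 3)
        g["b1"] = dA1.sum(axis=(0, 1, 2))
        g["W1"] = np.ascontiguousarray(dA1.reshape(-1, f)).T @ cache["Xw"].reshape(-1, k)
        return g

    def loss_and_grad(self, X, y, sample_weight=None, train=True, drop_rng=None):
        X = self._check_input(X)
        y = np.asarray(y, dtype=self.dtype)
        B = len(y)
        w = np.ones(B, self.dtype) if sample_weight is None else np.asarray(
            sample_weight, self.dtype
        )
        cache = self._forward(X, train=train, drop_rng=drop_rng)
        p = np.clip(cache["p"].astype(np.float64), 1e-12, 1 - 1e-12)
        loss = -np.mean(w * (y * np.log(p) + (1 - y) * np.log1p(-p)))
        dz = (w * (cache["p"] - y) / B).astype(self.dtype)
        grads = self._backward(cache, dz)
        return float(loss), grads

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        """Per-epoch probability of the positive class ("syllable")."""
        X = self._check_input(X)
        out = np.empty(len(X), dtype=np.float64)
        for i in range(0, len(X), batch_size):
            out[i : i + batch_size] = self._forward(X[i : i + batch_size])["p"]
        return out

    # -- optimiser ---------------------------------------------------------

    def _adam_step(self, grads, cfg: TrainConfig):
        if self._adam_state is None:
            self._adam_state = {
                k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()
            }
            self._adam_t = 0
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            m, v = self._adam_state[k]
            gk = grads[k]
            m *= cfg.beta1
            m += (1 - cfg.beta1) * gk
            v *= cfg.beta2
            v += (1 - cfg.beta2) * gk**2
            mhat = m / (1 - cfg.beta1**t)
            vhat = v / (1 - cfg.beta2**t)
            p -= (cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.eps)).astype(self.dtype)


def build_cnn(spec: CNNSpec | None = None, seed: int = 0, dtype=np.float32) -> ConvNet:
    """Construct the (optionally re-dimensioned) network with seeded weights."""
    return ConvNet(spec=spec, seed=seed, dtype=dtype)


def train_cnn(
    train_epochs: np.ndarray,
    train_labels,
    config: TrainConfig | None = None,
    validation_split: float | None = None,
    model: ConvNet | None = None,
) -> tuple[ConvNet, pd.DataFrame]:
    """Train the network on normalised epochs; returns (model, history).

    The protocol is a fixed number of passes through the data (default 25);
    with ``config.early_stopping`` the run instead monitors validation AUC
    with the configured patience and restores the best weights. History has
    one row per pass: loss and, when a validation split exists, val_loss and
    val_auc.
    """
    cfg = config or TrainConfig()
    y = labels_to_int(np.asarray(train_labels))
    X = np.asarray(train_epochs)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    ss = np.random.SeedSequence(cfg.seed)
    k_init, k_shuffle, k_drop, k_split = ss.spawn(4)
    model = model or ConvNet(seed=int(k_init.generate_state(1)[0] % (2**31)))
    shuffle_rng = np.random.default_rng(k_shuffle)
    drop_rng = np.random.default_rng(k_drop)

    frac = cfg.validation_fraction if validation_split is None else validation_split
    if cfg.early_stopping and not frac:
        raise ValueError("early stopping requires a validation split")
    if frac:
        split_rng = np.random.default_rng(k_split)
        order = split_rng.permutation(len(y))
        n_val = max(1, int(round(frac * len(y))))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
            # rotate until both splits hold both classes (small-data guard)
            for shift in range(1, len(y)):
                order = np.roll(order, 1)
                val_idx, tr_idx = order[:n_val], order[n_val:]
                if len(np.unique(y[tr_idx])) == 2 and len(np.unique(y[val_idx])) == 2:
                    break
        Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    else:
        Xtr, ytr, Xval, yval = X, y, None, None

    weights = class_weights(ytr) if cfg.class_weighting else {0: 1.0, 1: 1.0}
    w_tr = np.array([weights[int(c)] for c in ytr])

    history = []
    best = (-np.inf, None, 0)
    for ep in range(cfg.n_epochs):
        perm = shuffle_rng.permutation(len(ytr))
        losses = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            loss, grads = model.loss_and_grad(
                Xtr[idx], ytr[idx], sample_weight=w_tr[idx], train=True, drop_rng=drop_rng
            )
            model._adam_step(grads, cfg)
            losses.append(loss)
        row = {"epoch": ep + 1, "loss": float(np.mean(losses))}
        if Xval is not None:
            pval = model.predict_proba(Xval)
            pv = np.clip(pval, 1e-12, 1 - 1e-12)
            row["val_loss"] = float(-np.mean(yval * np.log(pv) + (1 - yval) * np.log1p(-pv)))
            row["val_auc"] = auc(yval, pval) if len(np.unique(yval)) == 2 else np.nan
        history.append(row)
        if cfg.early_stopping:
            score = row["val_auc"]
            if score > best[0]:
                best = (score, {k: v.copy() for k, v in model.params.items()}, ep)
            elif ep - best[2] >= cfg.patience:
                break
    if cfg.early_stopping and best[1] is not None:
        model.set_params(best[1])
    return model, pd.DataFrame(history)


def predict_proba(model: ConvNet, epochs: np.ndarray) -> np.ndarray:
    """Per-epoch probability that the stimulus was the syllable."""
    return model.predict_proba(epochs)
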