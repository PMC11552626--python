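"""Embedding + CNN site classifier.

Architecture: learned word embedding -> 2D convolution over the
(position, embedding-dim) plane with a full-width kernel (ReLU,
L2-regularized kernel) -> max pooling over positions -> dense (ReLU) ->
dropout -> dense(1, sigmoid).  Trained with Adam on binary cross-entropy
and early stopping on validation loss, restoring the best-epoch weights.

Implemented directly on NumPy (forward + manual backprop) so that the
exact gradient of the output with respect to the embedded input is
available for attribution methods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .alphabet import ModAlphabet
from .datasets import DatasetSplit, SiteRecord

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    k: int = 53
    vocab_size: int = 22
    embedding_dim: int = 21
    conv_filters: int = 64
    conv_kernel: tuple[int, int] = (7, 21)  # (positions, embedding dims)
    pool: int = 4
    dense_units: tuple[int, int] = (128, 1)
    dropout: float = 0.1
    l2_weight: float = 1e-6
    lr: float = 0.001
    batch_size: int = 100
    max_epochs: int = 400
    patience: int = 15
    train_padding_embedding: bool = True

    def validate(self) -> None:
        if self.k % 2 == 0 or self.k < 1:
            raise ModelError(f"k must be odd and positive, got {self.k}")
        if not 0.0 <= self.dropout < 1.0:
            raise ModelError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.conv_kernel[1] != self.embedding_dim:
            raise ModelError(
                "convolution kernel must span the full embedding width: "
                f"kernel width {self.conv_kernel[1]} != embedding_dim "
                f"{self.embedding_dim}"
            )
        if self.conv_kernel[0] > self.k:
            raise ModelError(
                f"kernel height {self.conv_kernel[0]} exceeds window length {self.k}"
            )
        if self.dense_units[1] != 1:
            raise ModelError("output layer must have a single unit")
        for name in ("vocab_size", "conv_filters", "pool", "batch_size",
                     "max_epochs", "patience"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be positive")
        n_pooled = ((self.k - self.conv_kernel[0] + 1) // self.pool)
        if n_pooled < 1:
            raise ModelError("pool size leaves no pooled positions")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_kernel"] = list(self.conv_kernel)
        d["dense_units"] = list(self.dense_units)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_kernel"] = tuple(d["conv_kernel"])
        d["dense_units"] = tuple(d["dense_units"])
        return cls(**d)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


PARAM_NAMES = ("E", "Wc", "bc", "W1", "b1", "W2", "b2")


@dataclass
class TrainedModel:
    """Network weights plus the alphabet and window size they assume."""

    config: ModelConfig
    alphabet: ModAlphabet
    params: dict[str, np.ndarray]
    training_log: list[dict] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    # ---- forward ---------------------------------------------------------

    def embed(self, codes: np.ndarray) -> np.ndarray:
        """Integer codes (..., k) -> embedded tensor (..., k, d)."""
        codes = np.asarray(codes)
        if codes.max(initial=0) >= self.config.vocab_size or codes.min(initial=0) < 0:
            bad = int(codes.max())
            raise ModelError(
                f"code {bad} outside vocabulary of size {self.config.vocab_size} "
                "(alphabet mismatch?)"
            )
        return self.params["E"][codes]

    def _forward(self, X: np.ndarray, *, dropout_rng=None) -> tuple[np.ndarray, dict]:
        """Embedded input (B, k, d) -> probabilities (B,), with cache."""
        cfg = self.config
        p = self.params
        B = X.shape[0]
        h = cfg.conv_kernel[0]
        P = cfg.k - h + 1

        # im2col: (B, P, h*d)
        cols = np.lib.stride_tricks.sliding_window_view(X, h, axis=1)
        # sliding_window_view gives (B, P, d, h); reorder to (B, P, h, d)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, P, -1)
        Z1 = cols @ p["Wc"] + p["bc"]          # (B, P, F)
        A1 = _relu(Z1)

        P2 = P // cfg.pool
        A1t = A1[:, : P2 * cfg.pool].reshape(B, P2, cfg.pool, -1)
        pool_arg = A1t.argmax(axis=2)           # (B, P2, F)
        M = np.take_along_axis(A1t, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]
        flat = M.reshape(B, -1)

        Z2 = flat @ p["W1"] + p["b1"]
        A2 = _relu(Z2)
        if dropout_rng is not None and cfg.dropout > 0.0:
            mask = (dropout_rng.random(A2.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
        else:
            mask = None
        A2d = A2 * mask if mask is not None else A2
        Z3 = A2d @ p["W2"] + p["b2"]
        y = _sigmoid(Z3[:, 0])

        cache = dict(X=X, cols=cols, Z1=Z1, A1=A1, pool_arg=pool_arg, flat=flat,
                     Z2=Z2, A2=A2, mask=mask, A2d=A2d, y=y, B=B, P=P, P2=P2)
        return y, cache

    def _backward(self, cache: dict, dZ3: np.ndarray,
                  *, need_param_grads: bool = True,
                  need_input_grad: bool = False) -> dict[str, np.ndarray]:
        """Backprop from dL/dZ3 (pre-sigmoid logit gradient, shape (B,))."""
        cfg = self.config
        p = self.params
        B, P, P2 = cache["B"], cache["P"], cache["P2"]
        h = cfg.conv_kernel[0]
        d = cfg.embedding_dim
        F = cfg.conv_filters
        grads: dict[str, np.ndarray] = {}

        dZ3 = dZ3[:, None]                         # (B, 1)
        if need_param_grads:
            grads["W2"] = cache["A2d"].T @ dZ3
            grads["b2"] = dZ3.sum(axis=0)
        dA2d = dZ3 @ p["W2"].T
        dA2 = dA2d * cache["mask"] if cache["mask"] is not None else dA2d
        dZ2 = dA2 * (cache["Z2"] > 0)
        if need_param_grads:
            grads["W1"] = cache["flat"].T @ dZ2
            grads["b1"] = dZ2.sum(axis=0)
        dflat = dZ2 @ p["W1"].T
        dM = dflat.reshape(B, P2, F)

        dA1 = np.zeros((B, P2, cfg.pool, F))
        np.put_along_axis(dA1, cache["pool_arg"][:, :, None, :], dM[:, :, None, :],
                          axis=2)
        dA1_full = np.zeros((B, P, F))
        dA1_full[:, : P2 * cfg.pool] = dA1.reshape(B, P2 * cfg.pool, F)
        dZ1 = dA1_full * (cache["Z1"] > 0)

        if need_param_grads:
            grads["Wc"] = (
                cache["cols"].reshape(B * P, -1).T @ dZ1.reshape(B * P, F)
                + 2.0 * cfg.l2_weight * p["Wc"]
            )
            grads["bc"] = dZ1.sum(axis=(0, 1))

        if need_param_grads or need_input_grad:
            dcols = dZ1 @ p["Wc"].T                # (B, P, h*d)
            dcols = dcols.reshape(B, P, h, d)
            dX = np.zeros_like(cache["X"])
            for off in range(h):                   # fold overlapping windows
                dX[:, off : off + P] += dcols[:, :, off, :]
            if need_input_grad:
                grads["X"] = dX
            if need_param_grads:
                dE = np.zeros_like(p["E"])
                np.add.at(dE, cache["codes"], dX)
                if not cfg.train_padding_embedding:
                    dE[0] = 0.0
                grads["E"] = dE
        return grads

    # ---- public inference ------------------------------------------------

    def predict_codes(self, codes: np.ndarray) -> np.ndarray:
        """Probabilities for a (B, k) integer code matrix (dropout off)."""
        codes = np.atleast_2d(np.asarray(codes))
        if codes.shape[1] != self.config.k:
            raise ModelError(
                f"window length {codes.shape[1]} != model k {self.config.k}"
            )
        y, _ = self._forward(self.embed(codes))
        return y

    def predict(self, windows: list) -> np.ndarray:
        """One probability per encoded window, order preserved."""
        if not windows:
            return np.empty(0)
        codes = np.stack([w.codes for w in windows])
        return self.predict_codes(codes)

    def value_and_grad_embedding(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Output probability and its gradient w.r.t. the embedded input.

        ``X`` has shape (B, k, d).  Returns (probabilities (B,), dF/dX
        (B, k, d)); dropout disabled.
        """
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 2
        if single:
            X = X[None]
        y, cache = self._forward(X)
        dZ3 = y * (1.0 - y)  # dF/dZ3 for F = sigmoid(Z3)
        grads = self._backward(cache, dZ3, need_param_grads=False,
                               need_input_grad=True)
        if single:
            return y[0], grads["X"][0]
        return y, grads["X"]

    # ---- serialization ---------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "format": "ptmtok-model-v1",
            "config": self.config.to_dict(),
            "alphabet": self.alphabet.to_dict(),
            "training_log": self.training_log,
            "stopped_epoch": self.stopped_epoch,
            "best_epoch": self.best_epoch,
        }
        with open(path, "wb") as fh:
            np.savez(fh, meta=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as npz:
            if "meta" not in npz:
                raise ModelError(f"{path} is not a model archive")
            meta = json.loads(str(npz["meta"]))
            if meta.get("format") != "ptmtok-model-v1":
                raise ModelError(f"unsupported model format {meta.get('format')!r}")
            params = {name: npz[name] for name in PARAM_NAMES}
        return cls(
            config=ModelConfig.from_dict(meta["config"]),
            alphabet=ModAlphabet.from_dict(meta["alphabet"]),
            params=params,
            training_log=meta["training_log"],
            stopped_epoch=meta["stopped_epoch"],
            best_epoch=meta["best_epoch"],
        )

    @property
    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.params.values())


def build_model(config: ModelConfig, alphabet: ModAlphabet, seed: int = 0) -> TrainedModel:
    """Initialize an untrained model (Glorot-uniform weights, fixed seed)."""
    config.validate()
    if config.vocab_size != alphabet.vocab_size:
        raise ModelError(
            f"config vocab_size {config.vocab_size} != alphabet size "
            f"{alphabet.vocab_size}"
        )
    rng = np.random.default_rng(seed)
    h = config.conv_kernel[0]
    d = config.embedding_dim
    F = config.conv_filters
    P2 = (config.k - h + 1) // config.pool
    u = config.dense_units[0]

    def glorot(shape):
        fan_in, fan_out = shape[0], shape[-1]
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    params = {
        "E": rng.uniform(-0.05, 0.05, size=(config.vocab_size, d)),
        "Wc": glorot((h * d, F)),
        "bc": np.zeros(F),
        "W1": glorot((P2 * F, u)),
        "b1": np.zeros(u),
        "W2": glorot((u, 1)),
        "b2": np.zeros(1),
    }
    return TrainedModel(config=config, alphabet=alphabet, params=params)


def _bce(y: np.ndarray, t: np.ndarray, eps: float = 1e-12) -> float:
    y = np.clip(y, eps, 1.0 - eps)
    return float(-np.mean(t * np.log(y) + (1.0 - t) * np.log(1.0 - y)))


def _records_to_arrays(records: list[SiteRecord]) -> tuple[np.ndarray, np.ndarray]:
    codes = np.stack([r.window.codes for r in records])
    labels = np.array([r.label for r in records], dtype=np.float64)
    return codes, labels


def train(model: TrainedModel, split: DatasetSplit, seed: int = 0) -> TrainedModel:
    """Adam + binary cross-entropy with early stopping on validation loss.

    Stops when validation loss fails to improve for ``patience`` consecutive
    epochs (or at ``max_epochs``) and restores the best-epoch weights.
    """
    cfg = model.config
    if not split.train:
        raise ModelError("training set is empty")
    if not split.validation:
        raise ModelError("validation set is empty: early stopping undefined")
    Xc, yt = _records_to_arrays(split.train)
    Xv, yv = _records_to_arrays(split.validation)
    if Xc.shape[1] != cfg.k:
        raise ModelError(f"window length {Xc.shape[1]} != config k {cfg.k}")
    if yt.min() == yt.max():
        raise ModelError("training labels are constant; need both classes")

    rng = np.random.default_rng(seed)
    p = model.params
    m_t = {k: np.zeros_like(v) for k, v in p.items()}
    v_t = {k: np.zeros_like(v) for k, v in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_loss = np.inf
    best_params = {k: v.copy() for k, v in p.items()}
    best_epoch = 0
    wait = 0
    log: list[dict] = []

    n = Xc.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            codes = Xc[idx]
            t = yt[idx]
            X = model.embed(codes)
            y, cache = model._forward(X, dropout_rng=rng)
            cache["codes"] = codes
            epoch_loss += _bce(y, t) * len(idx)
            # d(BCE)/dZ3 for sigmoid output
            dZ3 = (y - t) / len(idx)
            grads = model._backward(cache, dZ3)
            step += 1
            for name in p:
                g = grads[name]
                m_t[name] = beta1 * m_t[name] + (1 - beta1) * g
                v_t[name] = beta2 * v_t[name] + (1 - beta2) * g * g
                m_hat = m_t[name] / (1 - beta1**step)
                v_hat = v_t[name] / (1 - beta2**step)
                p[name] -= cfg.lr * m_hat / (np.sqrt(v_hat) + eps)

        train_loss = epoch_loss / n
        val_pred, _ = model._forward(model.embed(Xv))
        val_loss = _bce(val_pred, yv)
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})

        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in p.items()}
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                model.stopped_epoch = epoch
                break
    else:
        model.stopped_epoch = cfg.max_epochs

    model.params = best_params
    model.best_epoch = best_epoch
    model.training_log = log
    return model
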