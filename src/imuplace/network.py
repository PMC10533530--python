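"""A small 1D causal-convolution classifier for walk patterns.

Architecture: two blocks of [1D convolution (kernel 3, causal padding) ->
ReLU -> layer normalization over the channel dimension at each time step],
with 32 then 64 filters, followed by global average pooling over time, a
fully connected layer with seven outputs, and a softmax with cross-entropy
loss.  Causal padding (k-1 zeros on the past side) preserves the temporal
length and makes every activation depend only on current and earlier
samples.

The network and its Adam training loop are implemented directly on NumPy
(float32, im2col GEMMs).  Training is deterministic for a fixed seed; exact
bit-reproducibility across BLAS builds is not guaranteed, which is the
usual floating-point caveat.

Parameter count for C input channels:
  conv1: 3*C*32 + 32, ln1: 2*32, conv2: 3*32*64 + 64, ln2: 2*64,
  dense: 64*7 + 7  =>  96*C + 6887.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "VALID_INPUT_CHANNELS",
    "CausalConvNet",
    "TrainingConfig",
    "TEST_PROFILE",
    "TrainedModel",
    "build_network",
    "train",
    "predict",
    "clip_gradients",
]

VALID_INPUT_CHANNELS = (6, 12, 18, 24, 30, 36)
_LN_EPS = 1e-5


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class CausalConvNet:
    """conv(32x3, causal) -> relu -> LN -> conv(64x3, causal) -> relu -> LN
    -> global average pool -> dense(7) -> softmax."""

    KERNEL = 3
    FILTERS = (32, 64)
    N_CLASSES = 7

    def __init__(self, input_channels: int, seed: int = 0):
        if input_channels not in VALID_INPUT_CHANNELS:
            raise ValueError(
                f"input_channels must be one of {VALID_INPUT_CHANNELS}, "
                f"got {input_channels}"
            )
        self.input_channels = input_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        k, (f1, f2), nc = self.KERNEL, self.FILTERS, self.N_CLASSES
        c = input_channels
        self.params: dict[str, np.ndarray] = {
            "W1": _glorot(rng, k * c, k * f1, (k * c, f1)),
            "b1": np.zeros(f1, dtype=np.float32),
            "g1": np.ones(f1, dtype=np.float32),
            "be1": np.zeros(f1, dtype=np.float32),
            "W2": _glorot(rng, k * f1, k * f2, (k * f1, f2)),
            "b2": np.zeros(f2, dtype=np.float32),
            "g2": np.ones(f2, dtype=np.float32),
            "be2": np.zeros(f2, dtype=np.float32),
            "W3": _glorot(rng, f2, nc, (f2, nc)),
            "b3": np.zeros(nc, dtype=np.float32),
        }

    # ---- building blocks -------------------------------------------------

    @staticmethod
    def _im2col_causal(x: np.ndarray, k: int) -> np.ndarray:
        """x (N, T, C) -> (N, T, k*C); window at t covers samples t-k+1..t."""
        N, T, C = x.shape
        xp = np.pad(x, ((0, 0), (k - 1, 0), (0, 0)))
        return np.concatenate([xp[:, i : i + T, :] for i in range(k)], axis=2)

    @staticmethod
    def _ln_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + _LN_EPS)
        xhat = xc * inv
        return xhat * g + b, (xhat, inv)

    @staticmethod
    def _ln_backward(dy: np.ndarray, g: np.ndarray, cache):
        xhat, inv = cache
        dg = (dy * xhat).sum(axis=(0, 1))
        db = dy.sum(axis=(0, 1))
        dxhat = dy * g
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        return dx, dg, db

    # ---- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, return_cache: bool = False):
        """x (N, C, T) -> logits (N, 7); optionally the backprop cache."""
        if x.ndim != 3 or x.shape[1] != self.input_channels:
            raise ValueError(
                f"expected input (N, {self.input_channels}, T), got {x.shape}"
            )
        p, k = self.params, self.KERNEL
        xt = np.ascontiguousarray(x.transpose(0, 2, 1), dtype=np.float32)  # (N,T,C)
        N, T, _ = xt.shape

        X1 = self._im2col_causal(xt, k)
        a1 = X1.reshape(N * T, -1) @ p["W1"] + p["b1"]
        a1 = a1.reshape(N, T, -1)
        r1 = np.maximum(a1, 0.0)
        h1, ln1 = self._ln_forward(r1, p["g1"], p["be1"])

        X2 = self._im2col_causal(h1, k)
        a2 = X2.reshape(N * T, -1) @ p["W2"] + p["b2"]
        a2 = a2.reshape(N, T, -1)
        r2 = np.maximum(a2, 0.0)
        h2, ln2 = self._ln_forward(r2, p["g2"], p["be2"])

        pooled = h2.mean(axis=1)  # (N, F2)
        logits = pooled @ p["W3"] + p["b3"]
        if not return_cache:
            return logits
        cache = (X1, a1, ln1, X2, a2, ln2, h2, pooled, T)
        return logits, cache

    def activations(self, x: np.ndarray) -> np.ndarray:
        """Pre-pooling activations (N, T, 64) after the second block."""
        _, cache = self.forward(x, return_cache=True)
        return cache[6]

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean softmax cross-entropy and gradients for one batch."""
        logits, cache = self.forward(x, return_cache=True)
        X1, a1, ln1, X2, a2, ln2, _h2, pooled, T = cache
        p, k = self.params, self.KERNEL
        N = logits.shape[0]

        probs = softmax(logits)
        loss = float(-np.mean(np.log(probs[np.arange(N), y] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N

        grads: dict[str, np.ndarray] = {}
        grads["W3"] = pooled.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dpooled = dlogits @ p["W3"].T
        dh2 = np.broadcast_to(dpooled[:, None, :] / T, (N, T, dpooled.shape[1]))

        dr2, grads["g2"], grads["be2"] = self._ln_backward(dh2, p["g2"], ln2)
        da2 = dr2 * (a2 > 0)
        da2f = da2.reshape(N * T, -1)
        grads["W2"] = X2.reshape(N * T, -1).T @ da2f
        grads["b2"] = da2f.sum(axis=0)
        dX2 = (da2f @ p["W2"].T).reshape(N, T, -1)
        dh1 = self._col2im_causal(dX2, k)

        dr1, grads["g1"], grads["be1"] = self._ln_backward(dh1, p["g1"], ln1)
        da1 = dr1 * (a1 > 0)
        da1f = da1.reshape(N * T, -1)
        grads["W1"] = X1.reshape(N * T, -1).T @ da1f
        grads["b1"] = da1f.sum(axis=0)
        # input gradient is not needed for training

        return loss, {k_: v.astype(np.float32) for k_, v in grads.items()}

    @staticmethod
    def _col2im_causal(dcols: np.ndarray, k: int) -> np.ndarray:
        """Adjoint of _im2col_causal: (N, T, k*C) -> (N, T, C)."""
        N, T, kc = dcols.shape
        C = kc // k
        dxp = np.zeros((N, T + k - 1, C), dtype=dcols.dtype)
        for i in range(k):
            dxp[:, i : i + T, :] += dcols[:, :, i * C : (i + 1) * C]
        return dxp[:, k - 1 :, :]

    # ---- inference / persistence -----------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def save(self, path) -> None:
        meta = json.dumps({"input_channels": self.input_channels, "seed": self.seed})
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "CausalConvNet":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        model = cls(meta["input_channels"], seed=meta["seed"])
        for k in model.params:
            model.params[k] = data[k].astype(np.float32)
        return model


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_network(input_channels: int, seed: int = 0) -> CausalConvNet:
    """Construct the untrained classifier for a given walk-pattern width."""
    return CausalConvNet(input_channels, seed=seed)


@dataclass(frozen=True)
class TrainingConfig:
    """Adam training recipe.

    Only the squared-gradient decay (0.99), learning rate, global-L2
    gradient clipping threshold (0.9), epochs (500), batch size (64) and
    shuffle=never are prescribed by the study protocol; the first-moment
    decay and epsilon use the common defaults 0.9 and 1e-8.
    """

    learning_rate: float = 0.001
    beta1: float = 0.9
    squared_gradient_decay: float = 0.99
    epsilon: float = 1e-8
    gradient_clip: float = 0.9
    epochs: int = 500
    batch_size: int = 64
    shuffle: Literal["never", "each_epoch"] = "never"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


#: reduced-epoch profile used by the test suite and scaled-down evaluations
TEST_PROFILE = TrainingConfig(epochs=50)


def clip_gradients(
    grads: dict[str, np.ndarray], threshold: float
) -> tuple[dict[str, np.ndarray], float]:
    """Global L2-norm clipping: if ||g|| > threshold, rescale all gradients
    by threshold/||g||.  Returns (clipped gradients, pre-clip norm)."""
    norm = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values())))
    if threshold > 0 and norm > threshold:
        scale = threshold / norm
        grads = {k: g * np.float32(scale) for k, g in grads.items()}
    return grads, norm


@dataclass
class TrainedModel:
    model: CausalConvNet
    config: TrainingConfig
    log: list = field(default_factory=list)

    def save(self, model_path, log_path=None) -> None:
        self.model.save(model_path)
        if log_path is not None:
            with open(log_path, "w") as fh:
                json.dump({"config": asdict(self.config), "log": self.log}, fh, indent=2)


def train(
    model: CausalConvNet,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
    config: TrainingConfig = TrainingConfig(),
) -> TrainedModel:
    """Optimize the network with Adam under the stated recipe.

    Batch order follows the dataset order when ``shuffle='never'`` (the
    caller canonicalizes the order); validation metrics are logged per
    epoch and never influence the optimization (no early stopping).
    """
    if train_x.shape[0] == 0:
        raise ValueError("empty training set")
    if train_x.shape[1] != model.input_channels:
        raise ValueError(
            f"data has {train_x.shape[1]} channels, model expects "
            f"{model.input_channels}"
        )
    x = np.ascontiguousarray(train_x, dtype=np.float32)
    y = np.asarray(train_y, dtype=np.int64)
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)

    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2 = config.beta1, config.squared_gradient_decay
    step = 0
    log: list[dict] = []

    for epoch in range(1, config.epochs + 1):
        order = np.arange(n)
        if config.shuffle == "each_epoch":
            rng.shuffle(order)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = model.loss_and_grads(x[idx], y[idx])
            grads, _ = clip_gradients(grads, config.gradient_clip)
            step += 1
            bc1 = 1.0 - b1**step
            bc2 = 1.0 - b2**step
            for key, g in grads.items():
                m_state[key] = b1 * m_state[key] + (1 - b1) * g
                v_state[key] = b2 * v_state[key] + (1 - b2) * g * g
                mhat = m_state[key] / bc1
                vhat = v_state[key] / bc2
                model.params[key] -= (
                    config.learning_rate * mhat / (np.sqrt(vhat) + config.epsilon)
                ).astype(np.float32)
            epoch_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(1, n_batches)}
        if val_x is not None and val_y is not None and len(val_x) > 0:
            pred = predict(model, val_x)[0]
            entry["val_accuracy"] = float(np.mean(pred == np.asarray(val_y)))
        log.append(entry)

    return TrainedModel(model=model, config=config, log=log)


def predict(model: CausalConvNet, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax; ties -> lowest index) and probabilities."""
    probs = model.predict_proba(np.asarray(x, dtype=np.float32))
    return probs.argmax(axis=1), probs
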