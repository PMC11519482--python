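"""1D-convolutional autoencoder mapping observed-value windows to latent emotions.

The emotional encoder compresses a normalized W-step x V-variable window
into a d-dimensional latent vector Psi_t -- the synthetic emotional state
at step t.  The architecture is a small convolutional stack (two strided
conv layers, then a dense projection to the latent); the decoder mirrors
it (dense expansion, two transposed-conv layers).  It is trained
unsupervised to minimize mean squared reconstruction error, so the latent
captures the high-level trends and magnitudes of the recent experience
rather than exact sample values.

Implemented directly on numpy: forward passes, analytic gradients, Adam,
and early stopping.  All randomness flows from a single integer seed, so
training is reproducible bit-for-bit on fixed thread settings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import HomeostatNorms, SequenceDataset, SequenceWindow


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    batch_size: int = 10
    validation_split: float = 0.1
    max_epochs: int = 200
    patience: int = 5
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class EncoderConfig:
    """Architecture of the convolutional encoder (decoder is its mirror)."""

    W: int = 20
    n_variables: int = 2
    encoding_dim: int = 5
    l1_filters: int = 32
    l1_kernel_size: int = 5
    l1_strides: int = 2
    l2_filters: int = 16
    l2_kernel_size: int = 5
    l2_strides: int = 2
    padding: str = "same"
    activation: str = "relu"
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if self.encoding_dim < 1:
            raise ValueError("encoding_dim must be >= 1")
        if self.W < 1 or self.n_variables < 1:
            raise ValueError("W and n_variables must be positive")
        if self.l1_kernel_size > self.W:
            raise ValueError("kernel size cannot exceed the window length")
        if self.padding != "same":
            raise ValueError("only 'same' padding is supported")
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")

    # temporal lengths under 'same' padding: ceil(L / stride)
    @property
    def l1_out(self) -> int:
        return math.ceil(self.W / self.l1_strides)

    @property
    def l2_out(self) -> int:
        return math.ceil(self.l1_out / self.l2_strides)

    @property
    def flat_dim(self) -> int:
        return self.l2_out * self.l2_filters

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        if isinstance(d.get("training"), dict):
            d["training"] = TrainingConfig(**d["training"])
        return cls(**d)


def count_parameters(config: EncoderConfig, part: str = "encoder") -> int:
    """Exact trainable-parameter count from the architecture arithmetic.

    Conv layer: kernel x in_channels x filters + filters (bias); dense:
    in x out + out; temporal lengths via ceil division under 'same'
    padding.  ``part`` is ``"encoder"``, ``"decoder"`` or ``"both"``.
    """
    c = config
    conv1 = c.l1_kernel_size * c.n_variables * c.l1_filters + c.l1_filters
    conv2 = c.l2_kernel_size * c.l1_filters * c.l2_filters + c.l2_filters
    dense = c.flat_dim * c.encoding_dim + c.encoding_dim
    encoder = conv1 + conv2 + dense
    d_dense = c.encoding_dim * c.flat_dim + c.flat_dim
    d_conv1 = c.l2_kernel_size * c.l2_filters * c.l1_filters + c.l1_filters
    d_conv2 = c.l1_kernel_size * c.l1_filters * c.n_variables + c.n_variables
    decoder = d_dense + d_conv1 + d_conv2
    if part == "encoder":
        return encoder
    if part == "decoder":
        return decoder
    if part == "both":
        return encoder + decoder
    raise ValueError(f"unknown part {part!r}; use encoder|decoder|both")


# ---------------------------------------------------------------------------
# layer primitives (forward + analytic backward)
# ---------------------------------------------------------------------------

def _same_pad(L: int, k: int, s: int) -> tuple[int, int, int]:
    out = math.ceil(L / s)
    total = max((out - 1) * s + k - L, 0)
    left = total // 2
    return out, left, total - left


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, s: int):
    """x: (n, L, C); W: (k, C, F).  Returns y (n, out, F) and cache."""
    n, L, C = x.shape
    k = W.shape[0]
    out, pl, pr = _same_pad(L, k, s)
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    view = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)[:, ::s]
    # view: (n, out, C, k)
    y = np.einsum("ntck,kcf->ntf", view, W, optimize=True) + b
    return y, (view, xp.shape[1], pl, L, s)


def _conv1d_backward(dy: np.ndarray, x_shape, W: np.ndarray, cache):
    view, Lp, pl, L, s = cache
    k = W.shape[0]
    dW = np.einsum("ntck,ntf->kcf", view, dy, optimize=True)
    db = dy.sum(axis=(0, 1))
    n, out, F = dy.shape
    dxp = np.zeros((n, Lp, x_shape[2]))
    pos = s * np.arange(out)
    for i in range(k):
        dxp[:, pos + i, :] += np.einsum("ntf,cf->ntc", dy, W[i], optimize=True)
    dx = dxp[:, pl:pl + L, :]
    return dx, dW, db


def _convT1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, s: int):
    """Transposed conv; x: (n, L, C); W: (k, C, F).  Output length L*s."""
    n, L, C = x.shape
    k, _, F = W.shape
    out = L * s
    full = (L - 1) * s + k
    total = full - out
    pl = total // 2
    yf = np.zeros((n, full, F))
    pos = s * np.arange(L)
    for i in range(k):
        yf[:, pos + i, :] += np.einsum("ntc,cf->ntf", x, W[i], optimize=True)
    y = yf[:, pl:pl + out, :] + b
    return y, (full, pl, out, s)


def _convT1d_backward(dy: np.ndarray, x: np.ndarray, W: np.ndarray, cache):
    full, pl, out, s = cache
    n, L, C = x.shape
    k, _, F = W.shape
    dyf = np.zeros((n, full, F))
    dyf[:, pl:pl + out, :] = dy
    pos = s * np.arange(L)
    dx = np.zeros_like(x)
    dW = np.zeros_like(W)
    for i in range(k):
        sl = dyf[:, pos + i, :]           # (n, L, F)
        dx += np.einsum("ntf,cf->ntc", sl, W[i], optimize=True)
        dW[i] = np.einsum("ntc,ntf->cf", x, sl, optimize=True)
    db = dy.sum(axis=(0, 1))
    return dx, dW, db


# ---------------------------------------------------------------------------
# latent container and trained model
# ---------------------------------------------------------------------------

@dataclass
class LatentEmotion:
    """Psi_t: the d-dimensional latent emotional state for one window."""

    psi: np.ndarray
    source: tuple[str, int]

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        if not np.all(np.isfinite(self.psi)):
            raise ValueError(f"non-finite latent for window {self.source}")

    @property
    def t(self) -> int:
        return self.source[1]


class TrainedEncoder:
    """Weights + config of a trained autoencoder; pure encode/decode."""

    _WEIGHT_KEYS = ("Wc1", "bc1", "Wc2", "bc2", "Wd", "bd",
                    "Wdd", "bdd", "Wt1", "bt1", "Wt2", "bt2")

    def __init__(self, config: EncoderConfig, weights: dict[str, np.ndarray],
                 history: dict[str, list[float]] | None = None,
                 norms: HomeostatNorms | None = None):
        self.config = config
        self.weights = weights
        self.history = history or {"loss": [], "val_loss": []}
        self.norms = norms

    # -- forward passes ----------------------------------------------------

    def _encode_forward(self, X: np.ndarray, want_cache: bool = False):
        c, w = self.config, self.weights
        z1, cache1 = _conv1d_forward(X, w["Wc1"], w["bc1"], c.l1_strides)
        a1 = np.maximum(z1, 0.0)
        z2, cache2 = _conv1d_forward(a1, w["Wc2"], w["bc2"], c.l2_strides)
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(X.shape[0], -1)
        psi = flat @ w["Wd"] + w["bd"]
        if want_cache:
            return psi, (X, z1, a1, cache1, z2, a2, cache2, flat)
        return psi

    def _decode_forward(self, psi: np.ndarray, want_cache: bool = False):
        c, w = self.config, self.weights
        zd = psi @ w["Wdd"] + w["bdd"]
        ad = np.maximum(zd, 0.0)
        h = ad.reshape(psi.shape[0], c.l2_out, c.l2_filters)
        zt1, cacheT1 = _convT1d_forward(h, w["Wt1"], w["bt1"], c.l2_strides)
        at1 = np.maximum(zt1, 0.0)
        Xhat, cacheT2 = _convT1d_forward(at1, w["Wt2"], w["bt2"], c.l1_strides)
        if want_cache:
            return Xhat, (psi, zd, ad, h, zt1, at1, cacheT1, cacheT2)
        return Xhat

    def encode_batch(self, X: np.ndarray) -> np.ndarray:
        """(n, W, V) normalized windows -> (n, d) latents, order preserving."""
        X = np.asarray(X, dtype=float)
        c = self.config
        if X.ndim != 3 or X.shape[1:] != (c.W, c.n_variables):
            raise ValueError(
                f"expected (n, {c.W}, {c.n_variables}) input, got {X.shape}"
            )
        return self._encode_forward(X)

    def encode(self, window: SequenceWindow) -> LatentEmotion:
        if not window.normalized:
            raise ValueError("encode expects a normalized window")
        psi = self.encode_batch(window.values[None])[0]
        return LatentEmotion(psi, window.source)

    def decode(self, latent: LatentEmotion | np.ndarray) -> np.ndarray:
        psi = latent.psi if isinstance(latent, LatentEmotion) else np.asarray(latent)
        if psi.ndim == 1:
            return self._decode_forward(psi[None])[0]
        return self._decode_forward(psi)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._decode_forward(self._encode_forward(np.asarray(X, dtype=float)))

    # -- loss and gradients ------------------------------------------------

    def _loss_and_grads(self, X: np.ndarray):
        w = self.config, self.weights
        c, w = self.config, self.weights
        psi, ec = self._encode_forward(X, want_cache=True)
        Xhat, dc = self._decode_forward(psi, want_cache=True)
        n = X.shape[0]
        diff = Xhat - X
        loss = float(np.mean(diff ** 2))
        dXhat = 2.0 * diff / diff.size

        grads: dict[str, np.ndarray] = {}
        psi_c, zd, ad, h, zt1, at1, cacheT1, cacheT2 = dc
        dat1, grads["Wt2"], grads["bt2"] = _convT1d_backward(dXhat, at1, w["Wt2"], cacheT2)
        dzt1 = dat1 * (zt1 > 0)
        dh, grads["Wt1"], grads["bt1"] = _convT1d_backward(dzt1, h, w["Wt1"], cacheT1)
        dad = dh.reshape(n, -1)
        dzd = dad * (zd > 0)
        grads["Wdd"] = psi_c.T @ dzd
        grads["bdd"] = dzd.sum(axis=0)
        dpsi = dzd @ w["Wdd"].T

        Xin, z1, a1, cache1, z2, a2, cache2, flat = ec
        grads["Wd"] = flat.T @ dpsi
        grads["bd"] = dpsi.sum(axis=0)
        dflat = dpsi @ w["Wd"].T
        da2 = dflat.reshape(a2.shape)
        dz2 = da2 * (z2 > 0)
        da1, grads["Wc2"], grads["bc2"] = _conv1d_backward(dz2, a1.shape, w["Wc2"], cache2)
        dz1 = da1 * (z1 > 0)
        _, grads["Wc1"], grads["bc1"] = _conv1d_backward(dz1, Xin.shape, w["Wc1"], cache1)
        return loss, grads

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        np.savez(path / "weights.npz", **self.weights)
        pd.DataFrame(self.history).to_csv(path / "history.csv", index=False)
        if self.norms is not None:
            (path / "norms.json").write_text(json.dumps(self.norms.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEncoder":
        path = Path(path)
        config = EncoderConfig.from_dict(json.loads((path / "config.json").read_text()))
        with np.load(path / "weights.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        history = pd.read_csv(path / "history.csv").to_dict("list") \
            if (path / "history.csv").exists() else None
        norms = None
        if (path / "norms.json").exists():
            norms = HomeostatNorms.from_dict(json.loads((path / "norms.json").read_text()))
        return cls(config, weights, history, norms)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_weights(config: EncoderConfig, seed: int) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, from one integer seed."""
    c = config
    rng = np.random.default_rng(seed)
    w = {
        "Wc1": _glorot(rng, (c.l1_kernel_size, c.n_variables, c.l1_filters),
                       c.l1_kernel_size * c.n_variables, c.l1_kernel_size * c.l1_filters),
        "bc1": np.zeros(c.l1_filters),
        "Wc2": _glorot(rng, (c.l2_kernel_size, c.l1_filters, c.l2_filters),
                       c.l2_kernel_size * c.l1_filters, c.l2_kernel_size * c.l2_filters),
        "bc2": np.zeros(c.l2_filters),
        "Wd": _glorot(rng, (c.flat_dim, c.encoding_dim), c.flat_dim, c.encoding_dim),
        "bd": np.zeros(c.encoding_dim),
        "Wdd": _glorot(rng, (c.encoding_dim, c.flat_dim), c.encoding_dim, c.flat_dim),
        "bdd": np.zeros(c.flat_dim),
        "Wt1": _glorot(rng, (c.l2_kernel_size, c.l2_filters, c.l1_filters),
                       c.l2_kernel_size * c.l2_filters, c.l2_kernel_size * c.l1_filters),
        "bt1": np.zeros(c.l1_filters),
        "Wt2": _glorot(rng, (c.l1_kernel_size, c.l1_filters, c.n_variables),
                       c.l1_kernel_size * c.l1_filters, c.l1_kernel_size * c.n_variables),
        "bt2": np.zeros(c.n_variables),
    }
    return w


def train(dataset: SequenceDataset, config: EncoderConfig | None = None,
          ) -> TrainedEncoder:
    """Train the autoencoder on the dataset's normalized train windows.

    Minimizes mean squared reconstruction error with Adam, early-stopping
    on validation loss (best weights restored).  Deterministic given the
    config seed.
    """
    config = config or EncoderConfig()
    tc = config.training
    train_windows = dataset.subset("train")
    if any(not w.normalized for w in train_windows):
        raise ValueError("train() expects normalized windows; call normalize_dataset first")
    X = dataset.matrix("train")
    if X.shape[0] < tc.batch_size:
        raise ValueError(
            f"need at least batch_size={tc.batch_size} train windows, got {X.shape[0]}"
        )
    rng = np.random.default_rng(tc.seed)
    model = TrainedEncoder(config, init_weights(config, tc.seed), norms=dataset.norms)

    perm = rng.permutation(X.shape[0])
    n_val = max(1, int(round(tc.validation_split * X.shape[0])))
    X_val, X_tr = X[perm[:n_val]], X[perm[n_val:]]
    if X_tr.shape[0] < tc.batch_size:
        raise ValueError("too few windows left for training after validation split")

    m = {k: np.zeros_like(v) for k, v in model.weights.items()}
    v = {k: np.zeros_like(w) for k, w in model.weights.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val, best_weights, wait = np.inf, None, 0

    for epoch in range(tc.max_epochs):
        order = rng.permutation(X_tr.shape[0])
        losses = []
        for start in range(0, X_tr.shape[0], tc.batch_size):
            batch = X_tr[order[start:start + tc.batch_size]]
            loss, grads = model._loss_and_grads(batch)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            losses.append(loss)
            step += 1
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** step)
                vhat = v[k] / (1 - b2 ** step)
                model.weights[k] -= tc.learning_rate * mhat / (np.sqrt(vhat) + eps)
        val_loss = float(np.mean((model.reconstruct(X_val) - X_val) ** 2))
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        model.history["loss"].append(float(np.mean(losses)))
        model.history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val, wait = val_loss, 0
            best_weights = {k: w.copy() for k, w in model.weights.items()}
        else:
            wait += 1
            if wait >= tc.patience:
                break
    if best_weights is not None:
        model.weights = best_weights
    return model


def reconstruction_rmse(model: TrainedEncoder, dataset: SequenceDataset,
                        scale: str = "raw", part: str | None = None,
                        ) -> dict[str, float]:
    """Per-variable RMSE of reconstruction over all window entries.

    ``scale='raw'`` denormalizes predictions and targets with the dataset
    norms (equivalently, normalized RMSE times sigma_v); ``'normalized'``
    stays in z-score units.
    """
    if scale not in ("raw", "normalized"):
        raise ValueError("scale must be 'raw' or 'normalized'")
    norms = dataset.norms or model.norms
    if scale == "raw" and norms is None:
        raise ValueError("raw-scale RMSE requires fitted norms")
    X = dataset.matrix(part)
    if X.shape[0] == 0:
        raise ValueError("no windows to evaluate")
    Xhat = model.reconstruct(X)
    mse = np.mean((Xhat - X) ** 2, axis=(0, 1))
    rmse = np.sqrt(mse)
    if scale == "raw":
        rmse = rmse * norms.sd
    return {name: float(r) for name, r in zip(dataset.variables, rmse)}
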