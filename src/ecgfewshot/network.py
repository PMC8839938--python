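"""The QRS set-encoder network, implemented in numpy.

Architecture (one QRS complex, 12 x 100, to a 24-D feature vector):

====================  ===========  ============  ======  =======  ======
Layer                 Channels in  Channels out  Kernel  Padding  Stride
====================  ===========  ============  ======  =======  ======
Conv1d + LeakyReLU    12           24            3       1        1
MaxPool1d             24           24            2       0        2
Conv1d + LeakyReLU    24           48            3       0        1
MaxPool1d             48           48            2       0        2
Conv1d + LeakyReLU    48           96            3       1        1
MaxPool1d             96           96            2       0        2
Conv1d + LeakyReLU    96           2             1       0        1
====================  ===========  ============  ======  =======  ======

The final 1-kernel convolution is a GoogLeNet-style channel reduction: it
needs only 96 x 2 = 192 weights to collapse 96 channels to 2. Sequence
lengths run 100 -> 50 -> 48 -> 24 -> 24 -> 12, so the flattened output has
2 x 12 = 24 values (channel-major). The third convolution is padded so the
per-QRS feature vector is exactly 24-dimensional.

A record's variable-cardinality set of per-QRS features is pooled
symmetrically — elementwise maximum and mean over the set, concatenated to
48 values — and mapped by a fully connected layer to the 20-D record
embedding. An optional extra fully connected layer plus softmax turns the
embedding into class probabilities for the cross-entropy baseline.

All layers implement explicit ``forward``/``backward`` passes in float64;
gradients are exact (verified against finite differences in the tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import N_LEADS
from .segmentation import QRS_SAMPLES, QRSSet

__all__ = [
    "EncoderConfig",
    "RecordEmbedding",
    "FewShotEncoder",
    "aggregate",
    "softmax",
    "softmax_head",
    "count_parameters",
    "load_checkpoint",
]

# (kind, in_channels, out_channels, kernel, padding, stride)
_TABLE = (
    ("conv", 12, 24, 3, 1, 1),
    ("maxpool", 24, 24, 2, 0, 2),
    ("conv", 24, 48, 3, 0, 1),
    ("maxpool", 48, 48, 2, 0, 2),
    ("conv", 48, 96, 3, 1, 1),
    ("maxpool", 96, 96, 2, 0, 2),
    ("conv", 96, 2, 1, 0, 1),
)


@dataclass
class EncoderConfig:
    """Layer plan and dimensions of the set encoder."""

    layers: tuple = _TABLE
    leaky_slope: float = 0.01
    feature_dim: int = 24     # per-QRS vector
    pooled_dim: int = 48      # [max, avg] concatenation
    embedding_dim: int = 20   # record embedding
    n_classes: int | None = None  # softmax head size, None = no head

    def __post_init__(self) -> None:
        convs = [l for l in self.layers if l[0] == "conv"]
        if convs[0][1] != N_LEADS:
            raise ValueError("first conv must take 12 input channels")
        if convs[-1][3] != 1 or convs[-1][2] != 2:
            raise ValueError("last conv must be a kernel-1 reduction to 2 channels")
        if self.pooled_dim != 2 * self.feature_dim:
            raise ValueError("pooled_dim must be twice feature_dim")


def count_parameters(config: EncoderConfig, layer: int) -> int:
    """Multiplicative weights (excluding biases) of one table row.

    Convolutions contribute ``in_channels * out_channels * kernel``;
    pooling layers have no weights.
    """
    if not 0 <= layer < len(config.layers):
        raise IndexError(f"layer index {layer} out of range")
    kind, cin, cout, k, _, _ = config.layers[layer]
    return cin * cout * k if kind == "conv" else 0


# --- layers ---------------------------------------------------------------

class _Conv1d:
    def __init__(self, cin: int, cout: int, k: int, pad: int, stride: int,
                 rng: np.random.Generator):
        bound = 1.0 / np.sqrt(cin * k)
        self.W = rng.uniform(-bound, bound, size=(cout, cin, k))
        self.b = rng.uniform(-bound, bound, size=cout)
        self.pad, self.stride = pad, stride
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        k = self.W.shape[2]
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        win = win[:, :, :: self.stride, :]
        self._win, self._xlen = win, x.shape[2]
        return np.einsum("nclk,ock->nol", win, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += np.einsum("nclk,nol->ock", self._win, dy, optimize=True)
        self.db += dy.sum(axis=(0, 2))
        n, _, lout = dy.shape
        k = self.W.shape[2]
        dxp = np.zeros((n, self.W.shape[1], self._xlen))
        for kk in range(k):
            dxp[:, :, kk : kk + self.stride * lout : self.stride] += np.einsum(
                "oc,nol->ncl", self.W[:, :, kk], dy, optimize=True
            )
        return dxp[:, :, self.pad : self._xlen - self.pad] if self.pad else dxp

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _MaxPool1d:
    def __init__(self, k: int, stride: int):
        assert k == stride, "only non-overlapping pooling is used"
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        lout = L // self.k
        view = x[:, :, : lout * self.k].reshape(n, c, lout, self.k)
        self._argmax = view.argmax(axis=3)
        self._shape = x.shape
        return view.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, lout = dy.shape
        dx = np.zeros(self._shape)
        view = dx[:, :, : lout * self.k].reshape(n, c, lout, self.k)
        ni, ci, li = np.ogrid[:n, :c, :lout]
        view[ni, ci, li, self._argmax] = dy
        return dx

    def params(self):
        return []


class _LeakyReLU:
    def __init__(self, slope: float):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)

    def params(self):
        return []


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_out, n_in))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


# --- set pooling ----------------------------------------------------------

def aggregate(zs: np.ndarray) -> np.ndarray:
    """Pool a non-empty set of 24-D vectors into one 48-D vector.

    The first 24 entries are the per-dimension maximum over the set, the
    last 24 the per-dimension mean; both are symmetric in set order.
    """
    zs = np.atleast_2d(np.asarray(zs, dtype=float))
    if zs.shape[0] == 0:
        raise ValueError("cannot aggregate an empty set")
    return np.concatenate([zs.max(axis=0), zs.mean(axis=0)])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class RecordEmbedding:
    """A record's embedding with all intermediates of the encoding chain."""

    z_per_qrs: np.ndarray  # (n, 24)
    z_max: np.ndarray      # (24,)
    z_avg: np.ndarray      # (24,)
    pooled: np.ndarray     # (48,) = [z_max, z_avg]
    f: np.ndarray          # (20,)


class FewShotEncoder:
    """The set-encoder network with optional softmax head.

    Parameters are initialized uniformly within fan-in bounds from an
    explicit seed, so two encoders built with the same seed are identical.
    """

    def __init__(self, config: EncoderConfig | None = None, seed: int = 0):
        self.config = config or EncoderConfig()
        rng = np.random.default_rng(seed)
        self.layers: list = []
        for kind, cin, cout, k, pad, stride in self.config.layers:
            if kind == "conv":
                self.layers.append(_Conv1d(cin, cout, k, pad, stride, rng))
                self.layers.append(_LeakyReLU(self.config.leaky_slope))
            elif kind == "maxpool":
                self.layers.append(_MaxPool1d(k, stride))
            else:
                raise ValueError(f"unknown layer kind {kind!r}")
        self.fc = _Linear(self.config.pooled_dim, self.config.embedding_dim, rng)
        self.head = (
            _Linear(self.config.embedding_dim, self.config.n_classes, rng)
            if self.config.n_classes
            else None
        )

    # -- parameter plumbing ------------------------------------------------

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend(self.fc.params())
        if self.head is not None:
            out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    # -- forward passes ----------------------------------------------------

    def encode_qrs(self, q: np.ndarray) -> np.ndarray:
        """Encode one 12 x 100 QRS complex (or a batch) into 24-D features.

        The final 2-channel map is flattened channel-major: channel 0's 12
        values then channel 1's.
        """
        q = np.asarray(q, dtype=float)
        single = q.ndim == 2
        x = q[None] if single else q
        if x.shape[1:] != (N_LEADS, QRS_SAMPLES):
            raise ValueError(f"expected (*, {N_LEADS}, {QRS_SAMPLES}), got {q.shape}")
        for layer in self.layers:
            x = layer.forward(x)
        z = x.reshape(x.shape[0], -1)
        if z.shape[1] != self.config.feature_dim:
            raise ValueError(
                f"encoder produced {z.shape[1]} features, config says {self.config.feature_dim}"
            )
        return z[0] if single else z

    def embed_record(self, x: QRSSet | np.ndarray) -> RecordEmbedding:
        """Embed one record's QRS set into the 20-D space, with intermediates."""
        qs = x.stacked() if isinstance(x, QRSSet) else np.asarray(x, dtype=float)
        zs = self.encode_qrs(qs)
        z_max, z_avg = zs.max(axis=0), zs.mean(axis=0)
        pooled = np.concatenate([z_max, z_avg])
        f = self.fc.forward(pooled[None])[0]
        return RecordEmbedding(zs, z_max, z_avg, pooled, f)

    def softmax_head(self, f: np.ndarray) -> np.ndarray:
        """Class probabilities from a 20-D embedding (baseline head)."""
        if self.head is None:
            raise ValueError("encoder was built without a softmax head")
        return softmax(self.head.forward(np.atleast_2d(f)))[0] if f.ndim == 1 \
            else softmax(self.head.forward(f))

    # -- batched training path --------------------------------------------

    def forward_records(self, batch: np.ndarray) -> np.ndarray:
        """Embed a batch of records with homogeneous QRS counts.

        ``batch`` has shape (B, n, 12, 100); returns (B, embedding_dim) and
        caches everything needed by :meth:`backward_records`.
        """
        B, n = batch.shape[:2]
        zs = self.encode_qrs(batch.reshape(B * n, N_LEADS, QRS_SAMPLES))
        zs = zs.reshape(B, n, -1)
        self._set_argmax = zs.argmax(axis=1)          # (B, 24)
        self._set_n = n
        pooled = np.concatenate([zs.max(axis=1), zs.mean(axis=1)], axis=1)
        return self.fc.forward(pooled)

    def backward_records(self, dF: np.ndarray) -> None:
        """Backpropagate through pooling and the conv stack; accumulates grads."""
        dA = self.fc.backward(dF)                     # (B, 48)
        B, n = dA.shape[0], self._set_n
        d = self.config.feature_dim
        dZ = np.repeat(dA[:, d:, None], n, axis=2).transpose(0, 2, 1) / n
        bi, di = np.ogrid[:B, :d]
        dZ[bi, self._set_argmax, di] += dA[:, :d]
        dz = dZ.reshape(B * n, d)
        dx = dz.reshape(B * n, 2, -1)                 # undo channel-major flatten
        for layer in reversed(self.layers):
            dx = layer.backward(dx)

    def forward_logits(self, batch: np.ndarray) -> np.ndarray:
        if self.head is None:
            raise ValueError("encoder was built without a softmax head")
        return self.head.forward(self.forward_records(batch))

    def backward_logits(self, dlogits: np.ndarray) -> None:
        self.backward_records(self.head.backward(dlogits))

    # -- checkpointing -----------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint tensor count mismatch")
        for (p, _), a in zip(params, arrays):
            if p.shape != a.shape:
                raise ValueError(f"checkpoint shape mismatch: {p.shape} vs {a.shape}")
            p[...] = a

    def save_checkpoint(self, path: str | Path) -> None:
        """Versioned checkpoint: config echo plus all parameter tensors."""
        meta = {
            "version": 1,
            "layers": self.config.layers,
            "leaky_slope": self.config.leaky_slope,
            "feature_dim": self.config.feature_dim,
            "pooled_dim": self.config.pooled_dim,
            "embedding_dim": self.config.embedding_dim,
            "n_classes": self.config.n_classes,
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.state_arrays())}
        np.savez(path, config=json.dumps(meta), **arrays)


def softmax_head(f: np.ndarray, head_weights: tuple[np.ndarray, np.ndarray],
                 n_classes: int) -> np.ndarray:
    """Functional softmax head: linear map then softmax over ``n_classes``."""
    W, b = head_weights
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if W.shape[0] != n_classes or W.shape[1] != np.asarray(f).shape[-1]:
        raise ValueError("head weight shape mismatch")
    return softmax(np.asarray(f) @ W.T + b)


def load_checkpoint(path: str | Path) -> FewShotEncoder:
    """Load a checkpoint, validating tensor shapes against the config echo."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["config"]))
        config = EncoderConfig(
            layers=tuple(tuple(l) for l in meta["layers"]),
            leaky_slope=meta["leaky_slope"],
            feature_dim=meta["feature_dim"],
            pooled_dim=meta["pooled_dim"],
            embedding_dim=meta["embedding_dim"],
            n_classes=meta["n_classes"],
        )
        model = FewShotEncoder(config)
        n = len(model.parameters())
        model.set_state([data[f"param_{i}"] for i in range(n)])
    return model
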