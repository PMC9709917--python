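"""A compact numpy implementation of the spherical graph CNN.

The trunk is four blocks of [graph convolution -> batch normalization -> ReLU
-> 4:1 max pooling] with channel widths 32/64/128/256, followed by global
average pooling over the 12 base pixels and a fully connected head: a 3-way
softmax classifier, or a 256-d embedding for metric learning.

Graph convolution is the monomial Laplacian polynomial

    y = sum_{k=0..K} L^k x a_k      (K = 3, so four terms),

evaluated by K recursive sparse applications of L (L^k is never
materialized).  All layers carry hand-written gradients; optimization is Adam.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .graph import SphereGraph, build_graph_hierarchy

__all__ = [
    "GraphConv", "BatchNorm", "ReLU", "MaxPool4", "GlobalAvgPool", "Dense",
    "pool", "softmax", "cross_entropy", "contrastive_loss", "SphereCNN",
    "NetworkConfig", "Adam", "save_weights", "load_weights",
]


def _check_finite(x: np.ndarray, where: str) -> np.ndarray:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(f"non-finite activations in {where}")
    return x


class GraphConv:
    """Polynomial graph convolution y = sum_k L^k x a_k (no bias; BN follows).

    The monomial basis is numerically reparameterized as
    ``a_k = a_hat_k / lmax^k`` so that every Laplacian power contributes at
    comparable magnitude and per-parameter Adam steps act on comparable
    scales; the model class is unchanged and :attr:`coeffs` exposes the
    effective a_k.
    """

    def __init__(self, graph: SphereGraph, c_in: int, c_out: int, K: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.graph = graph
        self.K = K
        self.scales = np.array([max(graph.lmax, 1e-12)**k for k in range(K + 1)])
        scale = np.sqrt(2.0 / (c_in * (K + 1)))
        self.a = rng.normal(0.0, scale, size=(K + 1, c_in, c_out))
        self.grad_a = np.zeros_like(self.a)
        self._xs = None

    @property
    def coeffs(self) -> np.ndarray:
        """Effective polynomial coefficients a_k of y = sum_k L^k x a_k."""
        return self.a / self.scales[:, None, None]

    @coeffs.setter
    def coeffs(self, value: np.ndarray) -> None:
        self.a = np.asarray(value) * self.scales[:, None, None]

    def _apply_L(self, x: np.ndarray) -> np.ndarray:
        # x: (B, P, C) -> L x along the pixel axis
        B, P, C = x.shape
        xt = x.transpose(1, 0, 2).reshape(P, B * C)
        yt = self.graph.laplacian @ xt
        return yt.reshape(P, B, C).transpose(1, 0, 2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        powers = [x]
        for _ in range(self.K):
            powers.append(self._apply_L(powers[-1]))
        xs = np.stack([powers[k] / self.scales[k] for k in range(self.K + 1)])
        self._xs = xs if train else None
        return _check_finite(np.einsum("kbpi,kio->bpo", xs, self.a), "GraphConv")

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xs = self._xs
        self.grad_a += np.einsum("kbpi,bpo->kio", xs, gy)
        gx = np.zeros_like(xs[0])
        for k in range(self.K, -1, -1):
            g = np.einsum("bpo,io->bpi", gy, self.a[k]) / self.scales[k]
            for _ in range(k):
                g = self._apply_L(g)   # L symmetric
            gx += g
        return gx

    def params(self):
        return [(self, "a", "grad_a")]


class BatchNorm:
    """Per-channel normalization over batch and pixels; running averages with
    momentum 0.9 are used in eval mode."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.grad_gamma = np.zeros(channels)
        self.grad_beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, axes)
        return _check_finite(xhat * self.gamma + self.beta, "BatchNorm")

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._cache
        n = gy.size // gy.shape[-1]
        self.grad_gamma += (gy * xhat).sum(axis=axes)
        self.grad_beta += gy.sum(axis=axes)
        gxhat = gy * self.gamma
        gx = (gxhat - gxhat.mean(axis=axes)
              - xhat * (gxhat * xhat).sum(axis=axes) / n) * inv
        return gx

    def params(self):
        return [(self, "gamma", "grad_gamma"), (self, "beta", "grad_beta")]


class ReLU:
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return gy * self._mask

    def params(self):
        return []


def pool(x: np.ndarray, mode: str = "max", ordering: str = "nested") -> np.ndarray:
    """4:1 hierarchical pooling: output pixel p aggregates input pixels
    4p..4p+3 (nested-ordering children)."""
    if ordering != "nested":
        raise ValueError("hierarchical pooling requires nested ordering")
    P = x.shape[-2]
    if P % 4:
        raise ValueError(f"n_pix={P} not divisible by 4")
    blocks = x.reshape(*x.shape[:-2], P // 4, 4, x.shape[-1])
    if mode == "max":
        return blocks.max(axis=-2)
    if mode == "average":
        return blocks.mean(axis=-2)
    raise ValueError(f"unknown pooling mode {mode!r}")


class MaxPool4:
    def forward(self, x, train=False):
        B, P, C = x.shape
        blocks = x.reshape(B, P // 4, 4, C)
        self._arg = blocks.argmax(axis=2)
        self._shape = x.shape
        return blocks.max(axis=2)

    def backward(self, gy):
        B, Q, C = gy.shape
        gx = np.zeros((B, Q, 4, C))
        bi, qi, ci = np.ogrid[:B, :Q, :C]
        gx[bi, qi, self._arg, ci] = gy
        return gx.reshape(self._shape)

    def params(self):
        return []


class GlobalAvgPool:
    def forward(self, x, train=False):
        self._P = x.shape[1]
        return x.mean(axis=1)

    def backward(self, gy):
        return np.repeat(gy[:, None, :], self._P, axis=1) / self._P

    def params(self):
        return []


class Dense:
    def __init__(self, c_in: int, c_out: int, rng=None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.b = np.zeros(c_out)
        self.grad_W = np.zeros_like(self.W)
        self.grad_b = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x if train else None
        return _check_finite(x @ self.W + self.b, "Dense")

    def backward(self, gy):
        self.grad_W += self._x.T @ gy
        self.grad_b += gy.sum(axis=0)
        return gy @ self.W.T

    def params(self):
        return [(self, "W", "grad_W"), (self, "b", "grad_b")]


def softmax(z: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax along the last axis."""
    z = np.asarray(z, float)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, y_onehot: np.ndarray) -> float:
    """Mean negative log-likelihood, -sum_i y_i log p_i (natural log).

    Zero probability at the true class is clamped at 1e-12 with a warning.
    """
    p = np.asarray(p, float)
    y = np.asarray(y_onehot, float)
    at_true = (p * y).sum(axis=-1)
    if np.any(at_true <= 0):
        import warnings
        warnings.warn("zero predicted probability at the true class; clamped",
                      stacklevel=2)
    return float(-np.log(np.clip(at_true, 1e-12, None)).mean())


def contrastive_loss(f1: np.ndarray, f2: np.ndarray, y, m: float = 1.0):
    """Margin (contrastive) pair loss L = y d^2 + (1-y) max(0, m-d)^2 with
    d = ||f1 - f2||_2; returns (mean loss, grad wrt f1, grad wrt f2)."""
    f1 = np.atleast_2d(np.asarray(f1, float))
    f2 = np.atleast_2d(np.asarray(f2, float))
    y = np.atleast_1d(np.asarray(y, float))
    diff = f1 - f2
    d = np.linalg.norm(diff, axis=1)
    hinge = np.maximum(0.0, m - d)
    loss = float((y * d**2 + (1 - y) * hinge**2).mean())
    n = len(y)
    d_safe = np.where(d == 0, 1.0, d)
    # dL/dd = 2 y d - 2 (1-y) hinge ; dd/df1 = diff / d
    coef = (2 * y * d - 2 * (1 - y) * hinge) / d_safe / n
    g1 = coef[:, None] * diff
    return loss, g1, -g1


@dataclass
class NetworkConfig:
    n_side: int = 16
    in_channels: int = 9
    channels: tuple = (32, 64, 128, 256)
    K: int = 3
    k_neighbors: int = 20
    head: str = "classifier"     # or "embedder"
    n_classes: int = 3
    embed_dim: int = 256

    def __post_init__(self):
        if self.head not in ("classifier", "embedder"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.n_side // 2 ** len(self.channels) < 1:
            raise ValueError("too many pooling stages for this n_side")


class SphereCNN:
    """Spherical graph CNN over nested HEALPix maps.

    Input signal: (batch, n_pix, in_channels) or a 9 x n_pix map array.
    Classifier head returns class probabilities; embedder head returns raw
    256-d descriptors.
    """

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0,
                 graphs: list[SphereGraph] | None = None):
        self.cfg = cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(seed)
        depth = len(cfg.channels)
        self.graphs = graphs or build_graph_hierarchy(
            cfg.n_side, depth, k=cfg.k_neighbors)
        self.layers = []
        c_prev = cfg.in_channels
        for graph, c in zip(self.graphs, cfg.channels):
            self.layers += [GraphConv(graph, c_prev, c, K=cfg.K, rng=rng),
                            BatchNorm(c), ReLU(), MaxPool4()]
            c_prev = c
        self.layers.append(GlobalAvgPool())
        out_dim = cfg.n_classes if cfg.head == "classifier" else cfg.embed_dim
        self.fc = Dense(c_prev, out_dim, rng=rng)
        if cfg.head == "embedder":
            # start pair distances at margin scale so both contrastive terms
            # are active from the first step
            self.fc.W *= 0.1
        self.layers.append(self.fc)

    def _as_batch(self, maps) -> np.ndarray:
        x = np.asarray(maps, float)
        if x.ndim == 2 and x.shape[0] == self.cfg.in_channels:
            x = x.T[None]            # single (9, n_pix) map
        elif x.ndim == 3 and x.shape[1] == self.cfg.in_channels:
            x = x.transpose(0, 2, 1)  # (B, 9, n_pix) stack
        return x

    def forward(self, maps, train: bool = False) -> np.ndarray:
        x = self._as_batch(maps)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        if self.cfg.head == "classifier":
            return softmax(x)
        return x

    def forward_logits(self, maps, train: bool = False) -> np.ndarray:
        x = self._as_batch(maps)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> None:
        g = grad_out
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def zero_grad(self):
        for obj, _, gname in self.parameters():
            getattr(obj, gname)[...] = 0.0

    def embed(self, maps) -> np.ndarray:
        """Descriptors for one map or a stack of maps (eval mode)."""
        return self.forward(maps, train=False)

    def state_arrays(self) -> dict:
        arrays = {}
        for li, layer in enumerate(self.layers):
            for obj, name, _ in layer.params():
                arrays[f"layer{li}.{name}"] = getattr(obj, name)
            if isinstance(layer, BatchNorm):
                arrays[f"layer{li}.running_mean"] = layer.running_mean
                arrays[f"layer{li}.running_var"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays: dict) -> None:
        for li, layer in enumerate(self.layers):
            for obj, name, _ in layer.params():
                setattr(obj, name, np.array(arrays[f"layer{li}.{name}"]))
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.array(arrays[f"layer{li}.running_mean"])
                layer.running_var = np.array(arrays[f"layer{li}.running_var"])


class Adam:
    """Adam optimizer over a model's (object, value, grad) parameter triples."""

    def __init__(self, model: SphereCNN, lr: float = 0.05, betas=(0.9, 0.999),
                 weight_decay: float = 0.0, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for o, n, _ in model.parameters()]
        self.v = [np.zeros_like(getattr(o, n)) for o, n, _ in model.parameters()]

    def step(self):
        self.t += 1
        for i, (obj, name, gname) in enumerate(self.model.parameters()):
            g = getattr(obj, gname)
            if self.weight_decay:
                g = g + self.weight_decay * getattr(obj, name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            getattr(obj, name)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_weights(model: SphereCNN, path) -> None:
    """Single-archive serialization: npz arrays + JSON manifest."""
    arrays = model.state_arrays()
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(model.cfg).items()},
        "n_side_schedule": [g.n_side for g in model.graphs],
        "arrays": sorted(arrays),
    }
    with zipfile.ZipFile(str(path), "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        zf.writestr("weights.npz", buf.getvalue())


def load_weights(path) -> SphereCNN:
    with zipfile.ZipFile(str(path)) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        with zf.open("weights.npz") as fh:
            data = np.load(io.BytesIO(fh.read()))
            arrays = {k: data[k] for k in data.files}
    cfg_d = dict(manifest["config"])
    cfg_d["channels"] = tuple(cfg_d["channels"])
    model = SphereCNN(NetworkConfig(**cfg_d))
    model.load_state_arrays(arrays)
    return model
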