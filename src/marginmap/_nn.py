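"""Neural-network layers on the autodiff engine: a small convolutional
patch classifier and single-head graph-attention layers, with Adam and
cosine-annealed learning rates.  Deterministic given the seed."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, logsumexp_rows, segment_softmax

__all__ = [
    "Linear",
    "Conv2d",
    "SmallConvNet",
    "GATConv",
    "GATNet",
    "Adam",
    "cosine_lr",
    "cross_entropy",
    "dropout",
    "drop_edges",
]


def _glorot(rng, shape):
    fan_in = shape[0] if len(shape) == 2 else int(np.prod(shape[1:]))
    fan_out = shape[-1] if len(shape) == 2 else shape[0]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, shape), requires_grad=True)


class Module:
    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        params.extend(u.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        for p, s in zip(self.parameters(), state):
            p.data = np.asarray(s, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, in_dim, out_dim, rng):
        self.W = _glorot(rng, (in_dim, out_dim))
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv2d(Module):
    """3x3-style convolution via im2col gather + matmul (no padding)."""

    def __init__(self, in_ch, out_ch, rng, kernel=3, stride=2):
        self.kernel, self.stride = kernel, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = _glorot(rng, (out_ch, in_ch * kernel * kernel))
        self.b = Tensor(np.zeros((out_ch, 1)), requires_grad=True)
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def _indices(self, shape):
        if shape in self._idx_cache:
            return self._idx_cache[shape]
        n, c, h, w = shape
        k, s = self.kernel, self.stride
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        ci, di, dj = np.meshgrid(np.arange(c), np.arange(k), np.arange(k), indexing="ij")
        win = (ci * h * w + di * w + dj).ravel()  # (c*k*k,)
        oi, oj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        origin = (oi * s * w + oj * s).ravel()  # (oh*ow,)
        base = (np.arange(n) * c * h * w)[:, None, None]
        idx = base + win[None, :, None] + origin[None, None, :]
        self._idx_cache[shape] = (idx, oh, ow)
        return self._idx_cache[shape]

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        idx, oh, ow = self._indices((n, c, h, w))
        cols = x.reshape(-1).gather(idx)  # (n, c*k*k, oh*ow)
        out = self.W @ cols + self.b  # (n, out_ch, oh*ow)
        return out.reshape(n, self.out_ch, oh, ow)


class SmallConvNet(Module):
    """Four stride-2 conv blocks -> global average pool -> linear head.

    The pooled activation is the patch embedding (penultimate layer);
    ``input_size`` must reduce to 1x1 through the four blocks (32 works:
    32 -> 15 -> 7 -> 3 -> 1 with 3x3/stride-2 kernels, no padding).
    """

    def __init__(self, n_classes, rng, in_ch=3, channels=(16, 32, 48, 64),
                 input_size=32):
        self.input_size = input_size
        chans = [in_ch, *channels]
        self.convs = [Conv2d(chans[i], chans[i + 1], rng) for i in range(4)]
        self.embed_dim = channels[-1]
        self.head = Linear(self.embed_dim, n_classes, rng)

    def embed(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).relu()
        n = x.shape[0]
        return x.reshape(n, self.embed_dim, -1).mean(axis=2)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.embed(x))


class GATConv(Module):
    """Single-head graph attention layer.

    Per directed edge (u -> v): score = LeakyReLU(a_src . Wh_u + a_dst . Wh_v),
    attention = softmax over the in-neighborhood of v, output_v = sum of
    attention-weighted Wh_u plus bias.
    """

    def __init__(self, in_dim, out_dim, rng):
        self.W = _glorot(rng, (in_dim, out_dim))
        self.a_src = _glorot(rng, (out_dim, 1))
        self.a_dst = _glorot(rng, (out_dim, 1))
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, h: Tensor, edge_index: np.ndarray) -> Tensor:
        src, dst = edge_index
        n = h.shape[0]
        wh = h @ self.W  # (N, out)
        s_src = (wh @ self.a_src).reshape(-1)  # (N,)
        s_dst = (wh @ self.a_dst).reshape(-1)
        e = (s_src.gather(src) + s_dst.gather(dst)).leaky_relu(0.2)
        alpha = segment_softmax(e, dst, n)  # (E,)
        msg = wh.gather(src) * alpha.reshape(-1, 1)
        return msg.scatter_add(dst, n) + self.b


class GATNet(Module):
    """Graph attention network for per-node classification: attention layers
    of the configured dims (default 32, 32, 64) with ELU in between,
    followed by a linear prediction layer."""

    def __init__(self, in_dim, n_classes, rng, dims=(32, 32, 64)):
        sizes = [in_dim, *dims]
        self.layers = [GATConv(sizes[i], sizes[i + 1], rng) for i in range(len(dims))]
        self.head = Linear(dims[-1], n_classes, rng)

    def __call__(self, h: Tensor, edge_index: np.ndarray,
                 dropout_p: float = 0.0, rng=None) -> Tensor:
        for layer in self.layers:
            h = layer(h, edge_index).elu()
            if dropout_p > 0.0:
                h = dropout(h, dropout_p, rng)
        return self.head(h)


# ---------------------------------------------------------------------------
# training utilities


def dropout(x: Tensor, p: float, rng) -> Tensor:
    """Inverted dropout (training only)."""
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def drop_edges(edge_index: np.ndarray, p: float, rng, keep_self_loops=True) -> np.ndarray:
    """DropEdge: remove each undirected edge pair with probability ``p``."""
    src, dst = edge_index
    loop = src == dst
    key = np.minimum(src, dst) * (edge_index.max() + 1) + np.maximum(src, dst)
    uniq, inv = np.unique(key, return_inverse=True)
    keep_pair = rng.random(len(uniq)) >= p
    keep = keep_pair[inv]
    if keep_self_loops:
        keep |= loop
    return edge_index[:, keep]


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    n, c = logits.shape
    lse = logsumexp_rows(logits)  # (n, 1)
    picked = logits.reshape(-1).gather(np.arange(n) * c + np.asarray(labels))
    return (lse.reshape(-1) - picked).mean()


def cosine_lr(step: int, total: int, lr0: float, lr_min: float = 0.0) -> float:
    t = min(step, total) / max(total, 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * t))


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
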