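"""Numpy execution engine for :class:`~ftirnet.graph.LayerGraph`.

Materializes a layer graph into trainable numpy layers and provides the
forward pass, reverse-mode gradients and an Adam optimizer.  Conventions:

- activations are ``(batch, channels, length)`` float32 tensors; flatten
  and dense layers switch to ``(batch, features)``;
- convolutions use odd kernels with 'same' zero padding and stride 1,
  implemented as a sliding-window view contracted with the kernel tensor
  (a BLAS matmul under the hood);
- batch normalization is per channel over (batch, length), with running
  statistics (momentum 0.1) used at evaluation time;
- dropout is inverted (scaling at train time, identity at eval);
- the softmax and the categorical cross-entropy are fused in
  :class:`SoftmaxCrossEntropy`, so the network output node produces logits
  and ``predict_proba`` applies the softmax explicitly.

Every source of randomness (weight init, dropout masks) comes from a
single ``numpy.random.Generator``, so training is bit-reproducible.

Gradient correctness for each layer type is verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigError, NumericError
from .graph import LayerGraph

_DT = np.float32


# ---------------------------------------------------------------------------
# layers


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, *xs, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Input(Layer):
    def forward(self, x, train):
        return x

    def backward(self, dout):
        return (dout,)


class Conv1d(Layer):
    """'same'-padded stride-1 1D convolution with bias; odd kernels only."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ConfigError("Conv1d requires an odd kernel size")
        self.k = kernel
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.W = (scale * rng.standard_normal((c_out, c_in, kernel))).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        patches = sliding_window_view(xp, self.k, axis=2)  # (B, Cin, L, k)
        self._patches = patches
        out = np.tensordot(patches, self.W, axes=([1, 3], [1, 2]))  # (B, L, Cout)
        out = np.ascontiguousarray(out.transpose(0, 2, 1)) + self.b[None, :, None]
        return out.astype(_DT, copy=False)

    def backward(self, dout):
        p = self.k // 2
        self.grads[0][...] = np.tensordot(dout, self._patches, axes=([0, 2], [0, 2]))
        self.grads[1][...] = dout.sum(axis=(0, 2))
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p)))
        dpatches = sliding_window_view(dp, self.k, axis=2)  # (B, Cout, L, k)
        Wflip = self.W[:, :, ::-1]
        dx = np.tensordot(dpatches, Wflip, axes=([1, 3], [0, 2]))  # (B, L, Cin)
        return (np.ascontiguousarray(dx.transpose(0, 2, 1)).astype(_DT, copy=False),)


class BatchNorm1d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=_DT)
        self.beta = np.zeros(channels, dtype=_DT)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._cache = (xhat.astype(_DT, copy=False), invstd.astype(_DT), train)
        return (self.gamma[None, :, None] * self._cache[0] + self.beta[None, :, None])

    def backward(self, dout):
        xhat, invstd, train = self._cache
        dgamma = (dout * xhat).sum(axis=(0, 2))
        dbeta = dout.sum(axis=(0, 2))
        self.grads[0][...] = dgamma
        self.grads[1][...] = dbeta
        g = (self.gamma * invstd)[None, :, None]
        if train:
            n = dout.shape[0] * dout.shape[2]
            dx = g * (dout - (dbeta[None, :, None] + xhat * dgamma[None, :, None]) / n)
        else:
            dx = g * dout
        return (dx.astype(_DT, copy=False),)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return (dout * self._mask,)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the
    pool window is dropped (floor semantics)."""

    def __init__(self, pool: int):
        super().__init__()
        self.p = pool

    def forward(self, x, train):
        B, C, L = x.shape
        n = L // self.p
        xt = x[:, :, : n * self.p].reshape(B, C, n, self.p)
        self._arg = xt.argmax(axis=3)
        self._shape = x.shape
        return xt.max(axis=3)

    def backward(self, dout):
        B, C, L = self._shape
        n = L // self.p
        dx = np.zeros((B, C, n, self.p), dtype=_DT)
        bi, ci, ni = np.ogrid[:B, :C, :n]
        dx[bi, ci, ni, self._arg] = dout
        full = np.zeros(self._shape, dtype=_DT)
        full[:, :, : n * self.p] = dx.reshape(B, C, n * self.p)
        return (full,)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2, keepdims=True)

    def backward(self, dout):
        return (np.repeat(dout / self._L, self._L, axis=2).astype(_DT, copy=False),)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return (dout.reshape(self._shape),)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ConfigError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(_DT, copy=False)

    def backward(self, dout):
        if self._mask is None:
            return (dout,)
        return ((dout * self._mask).astype(_DT, copy=False),)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = (scale * rng.standard_normal((n_in, n_out))).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return (dout @ self.W.T,)


class Add(Layer):
    def forward(self, *xs, train):
        self._n = len(xs)
        out = xs[0].copy()
        for x in xs[1:]:
            out += x
        return out

    def backward(self, dout):
        return tuple(dout for _ in range(self._n))


class Concat(Layer):
    """Concatenation along the channel axis."""

    def forward(self, *xs, train):
        self._splits = np.cumsum([x.shape[1] for x in xs])[:-1]
        return np.concatenate(xs, axis=1)

    def backward(self, dout):
        return tuple(np.ascontiguousarray(p) for p in np.split(dout, self._splits, axis=1))


# ---------------------------------------------------------------------------
# loss


class SoftmaxCrossEntropy:
    """Fused softmax + categorical cross-entropy on logits."""

    @staticmethod
    def probabilities(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def forward(self, logits: np.ndarray, y: np.ndarray) -> float:
        probs = self.probabilities(logits.astype(np.float64))
        self._probs, self._y = probs, y
        return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())

    def backward(self) -> np.ndarray:
        d = self._probs.copy()
        d[np.arange(len(self._y)), self._y] -= 1.0
        return (d / len(self._y)).astype(_DT)


# ---------------------------------------------------------------------------
# network


class Network:
    """A :class:`LayerGraph` materialized with trainable numpy layers."""

    def __init__(self, graph: LayerGraph, rng: np.random.Generator):
        graph.validate()
        self.graph = graph
        self.order = graph.topological_order()
        shapes = graph.propagate_shapes()
        self.layers: dict[str, Layer] = {}
        for nid in self.order:
            node = graph.node(nid)
            ins = [shapes[p] for p in graph.predecessors(nid)]
            if node.kind == "input":
                self.layers[nid] = Input()
            elif node.kind == "conv":
                self.layers[nid] = Conv1d(ins[0][0], node.params["n_filters"],
                                          node.params["kernel_size"], rng)
            elif node.kind == "bn":
                self.layers[nid] = BatchNorm1d(ins[0][0])
            elif node.kind == "relu":
                self.layers[nid] = ReLU()
            elif node.kind == "maxpool":
                self.layers[nid] = MaxPool1d(node.params["pool_size"])
            elif node.kind == "gap":
                self.layers[nid] = GlobalAvgPool()
            elif node.kind == "flatten":
                self.layers[nid] = Flatten()
            elif node.kind == "dropout":
                self.layers[nid] = Dropout(node.params["rate"], rng)
            elif node.kind == "dense":
                self.layers[nid] = Dense(ins[0][0], node.params["units"], rng)
            elif node.kind == "add":
                self.layers[nid] = Add()
            elif node.kind == "concat":
                self.layers[nid] = Concat()
            else:  # pragma: no cover - graph.validate rejects these
                raise ConfigError(f"unsupported layer kind {node.kind}")
        self.output_id = self.order[-1]
        # order is topological, so the last node is the single sink

    # -- passes -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        values: dict[str, np.ndarray] = {}
        for nid in self.order:
            preds = self.graph.predecessors(nid)
            ins = [values[p] for p in preds] if preds else [x.astype(_DT, copy=False)]
            values[nid] = self.layers[nid].forward(*ins, train=train)
        self._values = values
        return values[self.output_id]

    def backward(self, dlogits: np.ndarray) -> None:
        douts: dict[str, np.ndarray] = {self.output_id: dlogits}
        for nid in reversed(self.order):
            layer = self.layers[nid]
            din = layer.backward(douts.pop(nid))
            for p, d in zip(self.graph.predecessors(nid), din):
                if p in douts:
                    douts[p] = douts[p] + d
                else:
                    douts[p] = d

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            outs.append(SoftmaxCrossEntropy.probabilities(logits.astype(np.float64)))
        return np.vstack(outs)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- parameters -------------------------------------------------------
    def parameters(self):
        out = []
        for nid in self.order:
            layer = self.layers[nid]
            out.extend(zip(layer.params, layer.grads))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())


class Adam:
    def __init__(self, network: Network, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = network.parameters()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float32) for p, _ in self.pairs]
        self.v = [np.zeros_like(p, dtype=np.float32) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            if not np.all(np.isfinite(g)):
                raise NumericError("non-finite gradient encountered during training")
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
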