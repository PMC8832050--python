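"""Minimal reverse-mode automatic differentiation for time-series CNNs.

The networks in this package need only a small set of primitives: time-axis
convolutions that never mix leads, batch normalization, dense layers, ReLU,
logistic gates, axis means (squeeze / global average pooling), broadcasting
multiplication (channel reweighting) and a softmax cross-entropy head.  This
module implements exactly those, define-by-run, on NumPy arrays.  Gradients
are accumulated on every node of the graph, so intermediate feature maps can
be inspected after a backward pass — which is what Grad-CAM requires.

Tensors carry float32 data by default; float64 is supported throughout (the
finite-difference gradient checks in the test suite run in float64).
"""

from __future__ import annotations

import numpy as np

try:  # optional single-pass gather/scatter kernels for the time convolution
    from numba import njit as _njit

    @_njit(fastmath=True, cache=False)
    def _conv_gather(y, out):
        # out[n,t,l,c] = sum_i y[n,t+i,l,i,c]; one pass over y
        N, T, L, cout = out.shape
        k = y.shape[3]
        for n in range(N):
            for t in range(T):
                for l in range(L):
                    for c in range(cout):
                        acc = y[n, t, l, 0, c]
                        for i in range(1, k):
                            acc += y[n, t + i, l, i, c]
                        out[n, t, l, c] = acc

    @_njit(fastmath=True, cache=False)
    def _bn_bwd_fused(x2, g2, mu, inv_std, scale, s1m, s2m, dx2):
        # dx = scale * (g - mean(g) - xhat * mean(g*xhat)), one pass
        m, c = x2.shape
        for i in range(m):
            for j in range(c):
                xhat = (x2[i, j] - mu[j]) * inv_std[j]
                dx2[i, j] = scale[j] * (g2[i, j] - s1m[j] - xhat * s2m[j])

    @_njit(fastmath=True, cache=False)
    def _conv_scatter(g, dy):
        # dy[n,t+i,l,i,c] = g[n,t,l,c]; dy pre-zeroed
        N, T, L, cout = g.shape
        k = dy.shape[3]
        for n in range(N):
            for t in range(T):
                for l in range(L):
                    for i in range(k):
                        for c in range(cout):
                            dy[n, t + i, l, i, c] = g[n, t, l, c]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "conv_time",
    "relu",
    "sigmoid",
    "mean",
    "reshape",
    "concat",
    "softmax_cross_entropy",
    "Layer",
    "Dense",
    "ConvTime",
    "BatchNorm",
    "SqueezeExcite",
    "Adam",
]


class Tensor:
    """A node in the computation graph: value, gradient, and backward rule."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def backward(self, seed=None):
        """Backpropagate from this node; ``seed`` defaults to ones."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs here can be a few hundred nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if seed is None:
            seed = np.ones_like(self.data)
        self.grad = np.asarray(seed, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype})"


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(out, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bwd(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return Tensor(out, (a, b), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def bwd(g):
        return g @ b.data.T, a.data.T @ g

    return Tensor(out, (a, b), bwd)


def conv_time(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Convolution along the time axis only (kernel k x 1, stride 1, "same").

    ``x`` is (N, T, L, C_in); ``w`` is (k, C_in, C_out); ``b`` is (C_out,).
    The lead axis L is untouched: one kernel is shared by every lead.
    Implemented as an im2col gather followed by a single GEMM.
    """
    N, T, L, cin = x.shape
    k, _, cout = w.shape
    pad_l = (k - 1) // 2
    pad_r = k - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0), (0, 0)))
    tp = T + k - 1
    # GEMM first on the contiguous padded input against all k taps at once,
    # then shift-accumulate: out[:, t] = sum_i (xp @ W[i])[:, t + i].
    # This keeps the big matmul fully contiguous instead of gathering an
    # im2col buffer with strided writes.
    wall = np.ascontiguousarray(w.data.transpose(1, 0, 2).reshape(cin, k * cout))
    out = np.empty((N, T, L, cout), dtype=x.dtype)
    # process one record at a time so the (tp, L, k, cout) tap buffer stays
    # cache-resident between the GEMM and the diagonal gather
    ybuf = np.empty((tp * L, k * cout), dtype=x.dtype)
    for n in range(N):
        np.matmul(xp[n].reshape(-1, cin), wall, out=ybuf)
        y = ybuf.reshape(tp, L, k, cout)
        if _HAVE_NUMBA and k > 1:
            _conv_gather(y[None], out[n : n + 1])
        else:
            np.copyto(out[n], y[0:T, :, 0])
            for i in range(1, k):
                out[n] += y[i : i + T, :, i]
    out += b.data

    def bwd(g):
        g = np.ascontiguousarray(g)
        db = g.sum(axis=(0, 1, 2))
        dw2 = np.zeros((cin, k * cout), dtype=x.dtype)
        dxp = np.empty_like(xp)
        dybuf = np.zeros((tp, L, k, cout), dtype=g.dtype)
        for n in range(N):
            if _HAVE_NUMBA and k > 1:
                _conv_scatter(g[n : n + 1], dybuf[None])
            else:
                dybuf[:] = 0.0
                for i in range(k):
                    dybuf[i : i + T, :, i] = g[n]
            dy2 = dybuf.reshape(-1, k * cout)
            xp2 = xp[n].reshape(-1, cin)
            dw2 += xp2.T @ dy2
            np.matmul(dy2, wall.T, out=dxp[n].reshape(-1, cin))
        dw = dw2.reshape(cin, k, cout).transpose(1, 0, 2)
        return dxp[:, pad_l : pad_l + T], dw, db

    return Tensor(out, (x, w, b), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def bwd(g):
        return (g * mask,)

    return Tensor(out, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    # overflow-safe logistic: exp() only ever sees non-positive arguments
    z = x.data
    s = np.empty_like(z)
    pos = z >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    s[~pos] = ez / (1.0 + ez)

    def bwd(g):
        return (g * s * (1.0 - s),)

    return Tensor(s, (x,), bwd)


def mean(x: Tensor, axes) -> Tensor:
    """Mean over ``axes`` (dropped from the output shape)."""
    axes = tuple(sorted(a % x.ndim for a in axes))
    out = x.data.mean(axis=axes)
    count = 1
    for a in axes:
        count *= x.shape[a]

    def bwd(g):
        ge = np.expand_dims(g, axes)
        return (np.broadcast_to(ge, x.shape) / count,)

    return Tensor(out, (x,), bwd)


def reshape(x: Tensor, shape) -> Tensor:
    out = x.data.reshape(shape)

    def bwd(g):
        return (g.reshape(x.shape),)

    return Tensor(out, (x,), bwd)


def concat(xs, axis=1) -> Tensor:
    out = np.concatenate([t.data for t in xs], axis=axis)
    sizes = [t.shape[axis] for t in xs]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(xs))
        )

    return Tensor(out, tuple(xs), bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, sample_weight=None):
    """(Weighted) mean categorical cross-entropy. Returns (loss, probabilities)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = np.finfo(logits.dtype).tiny
    logp = np.log(probs[np.arange(n), labels] + eps)
    if sample_weight is None:
        w = np.full(n, 1.0 / n)
    else:
        sw = np.asarray(sample_weight, dtype=np.float64)
        w = sw / sw.sum()
    loss = -(w * logp).sum()

    def bwd(g):
        dz = probs.copy()
        dz[np.arange(n), labels] -= 1.0
        return (g * dz * w[:, None],)

    return Tensor(np.asarray(loss, dtype=logits.dtype), (logits,), bwd), probs


class Layer:
    """Base class: a layer owns parameters and optional sub-layers."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor):
                params.append(value)
            elif isinstance(value, Layer):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / cin)
        self.w = Tensor((rng.standard_normal((cin, cout)) * scale).astype(dtype))
        self.b = Tensor(np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)


class ConvTime(Layer):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (k * cin))
        self.w = Tensor((rng.standard_normal((k, cin, cout)) * scale).astype(dtype))
        self.b = Tensor(np.zeros(cout, dtype=dtype))
        self.kernel = k

    def __call__(self, x: Tensor) -> Tensor:
        return conv_time(x, self.w, self.b)


class BatchNorm(Layer):
    """Batch normalization over all axes except the trailing channel axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype))
        self.beta = Tensor(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        gamma, beta = self.gamma, self.beta
        c = x.shape[-1]
        x2 = x.data.reshape(-1, c)
        m = x2.shape[0]
        if train:
            # single-pass moments via BLAS: column sums and sums of squares
            s = np.ones(m, dtype=x.dtype) @ x2
            ss = np.einsum("ij,ij->j", x2, x2)
            mu = s / m
            var = np.maximum(ss / m - mu * mu, 0.0)
            mom = self.momentum
            self.running_mean = mom * self.running_mean + (1 - mom) * mu.astype(self.running_mean.dtype)
            self.running_var = mom * self.running_var + (1 - mom) * var.astype(self.running_var.dtype)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        scale = gamma.data * inv_std
        out = x.data * scale + (beta.data - mu * scale)

        def bwd(g):
            g2 = g.reshape(-1, c)
            s1 = np.ones(m, dtype=g.dtype) @ g2           # per-channel sum(g)
            xhat2 = (x2 - mu) * inv_std
            s2 = np.einsum("ij,ij->j", g2, xhat2)         # = dgamma
            if not train:
                return g * scale, s2, s1
            # fused normalization backward:
            # dx = gamma*inv_std * (g - sum(g)/m - xhat*sum(g*xhat)/m)
            if _HAVE_NUMBA:
                dx2 = np.empty_like(g2)
                _bn_bwd_fused(x2, np.ascontiguousarray(g2), mu, inv_std,
                              scale, s1 / m, s2 / m, dx2)
            else:
                dx2 = scale * (g2 - s1 / m - xhat2 * (s2 / m))
            return dx2.reshape(x.shape), s2, s1

        return Tensor(out, (x, gamma, beta), bwd)


class SqueezeExcite(Layer):
    """Channel attention: global-average squeeze, bottleneck excitation, gate.

    ``channel_axis`` selects which axis is reweighted; the squeeze averages
    over every other non-batch axis.  Gates pass through a logistic, so they
    lie strictly in (0, 1).  Returns (reweighted tensor, gate tensor (N, C)).
    """

    def __init__(self, channels: int, reduction: int, channel_axis: int,
                 rng: np.random.Generator, dtype=np.float32):
        if channels % reduction != 0:
            raise ValueError(
                f"squeeze-excite reduction {reduction} does not divide {channels} channels"
            )
        self.channels = channels
        self.channel_axis = channel_axis
        self.fc1 = Dense(channels, channels // reduction, rng, dtype)
        self.fc2 = Dense(channels // reduction, channels, rng, dtype)

    def __call__(self, x: Tensor):
        c_axis = self.channel_axis % x.ndim
        if x.shape[c_axis] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels on axis {c_axis}, got {x.shape[c_axis]}"
            )
        squeeze_axes = tuple(a for a in range(1, x.ndim) if a != c_axis)
        s = mean(x, squeeze_axes)  # (N, C)
        gates = sigmoid(self.fc2(relu(self.fc1(s))))
        bshape = [x.shape[0]] + [1] * (x.ndim - 1)
        bshape[c_axis] = self.channels
        return mul(x, reshape(gates, tuple(bshape))), gates


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
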