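"""Minimal reverse-mode automatic differentiation over numpy.

A small tape-based engine carrying exactly the operations the network
needs: elementwise arithmetic, matmul, reductions, reshapes, ReLU/exp/
log/sin, 3x3 same-padded convolution, 2x2 max pooling, and the composite
layers built from them (dense, batch norm, layer norm, softmax,
multi-head attention pieces live in :mod:`lungsound.model`).

Gradients are stored on every node in the graph, which is what Grad-CAM
needs (gradients at intermediate convolutional activations). Everything
is deterministic given explicit ``numpy.random.Generator`` instances.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "Dense", "Conv2d", "MaxPool2d",
    "BatchNorm2d", "LayerNorm", "Dropout", "AdamW",
    "relu", "softmax", "log_softmax", "concatenate", "stack",
    "cross_entropy", "trunc_normal",
]

_Array = np.ndarray


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), grad_fns: tuple = ()):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(data, np.ndarray) \
            else data
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: Optional[_Array] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._grad_fns = grad_fns

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: Optional[_Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs are deep at long sequences)
        seen: set[int] = {id(self)}
        order: list[Tensor] = []
        state: dict[int, int] = {}
        work: list[Tensor] = [self]
        while work:
            node = work[-1]
            idx = state.get(id(node), 0)
            if idx < len(node._parents):
                state[id(node)] = idx + 1
                parent = node._parents[idx]
                if id(parent) not in seen and parent.requires_grad:
                    seen.add(id(parent))
                    work.append(parent)
            else:
                order.append(work.pop())
        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(order):
            if node.grad is None:
                continue
            for parent, fn in zip(node._parents, node._grad_fns):
                if not parent.requires_grad:
                    continue
                g = fn(node.grad)
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g

    def zero_grad_graph(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data + other.data, parents=(self, other),
                      grad_fns=(lambda g: _unbroadcast(g, self.shape),
                                lambda g: _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), grad_fns=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      grad_fns=(lambda g: _unbroadcast(g * other.data, self.shape),
                                lambda g: _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      grad_fns=(lambda g: _unbroadcast(g / other.data, self.shape),
                                lambda g: _unbroadcast(-g * self.data / other.data ** 2,
                                                       other.shape)))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = self.data ** exponent
        return Tensor(out, parents=(self,),
                      grad_fns=(lambda g: g * exponent * self.data ** (exponent - 1),))

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = self.data @ other.data
        return Tensor(out, parents=(self, other),
                      grad_fns=(lambda g: _matmul_grad_a(g, self.data, other.data),
                                lambda g: _matmul_grad_b(g, self.data, other.data)))

    def __getitem__(self, idx):
        basic = all(isinstance(i, (int, np.integer, slice)) for i in
                    (idx if isinstance(idx, tuple) else (idx,)))

        def grad_fn(g):
            out = np.zeros_like(self.data)
            if basic:
                out[idx] += g
            else:
                np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=(self,), grad_fns=(grad_fn,))

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis if isinstance(axis, int) else tuple(axis))
            return np.broadcast_to(g, self.shape).copy()

        return Tensor(out, parents=(self,), grad_fns=(grad_fn,))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(self.data.reshape(shape), parents=(self,),
                      grad_fns=(lambda g: g.reshape(self.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))
        return Tensor(self.data.transpose(axes), parents=(self,),
                      grad_fns=(lambda g: g.transpose(inverse),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), grad_fns=(lambda g: g * out,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,),
                      grad_fns=(lambda g: g / self.data,))

    def sin(self):
        return Tensor(np.sin(self.data), parents=(self,),
                      grad_fns=(lambda g: g * np.cos(self.data),))

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: _Array, shape: tuple) -> _Array:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _matmul_grad_a(g, a, b):
    if b.ndim == 1:
        g = np.expand_dims(g, -1)
        b = np.expand_dims(b, -1)
    grad = g @ np.swapaxes(b, -1, -2)
    return _unbroadcast(grad, a.shape) if grad.shape != a.shape else grad


def _matmul_grad_b(g, a, b):
    if a.ndim == 1:
        a = np.expand_dims(a, 0)
        g = np.expand_dims(g, 0)
    grad = np.swapaxes(a, -1, -2) @ g
    return _unbroadcast(grad, b.shape) if grad.shape != b.shape else grad


# ---------------------------------------------------------------------------
# nonlinearities and composites

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), grad_fns=(lambda g: g * mask,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        def fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return fn

    return Tensor(out, parents=tuple(tensors),
                  grad_fns=tuple(make_fn(i) for i in range(len(tensors))))


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=axis)

    def make_fn(i):
        return lambda g: np.take(g, i, axis=axis)

    return Tensor(out, parents=tuple(tensors),
                  grad_fns=tuple(make_fn(i) for i in range(len(tensors))))


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean soft-target cross entropy; ``targets`` rows are probability vectors."""
    targets = np.asarray(targets, dtype=np.float64)
    lsm = log_softmax(logits, axis=-1)
    return -(lsm * Tensor(targets)).sum() * (1.0 / logits.shape[0])


# ---------------------------------------------------------------------------
# convolution / pooling primitives

def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """Stride-1, same-padded 2-D convolution (cross-correlation), NCHW."""
    xd, wd = x.data, weight.data
    b_, c_in, h, w = xd.shape
    c_out, _, kh, kw = wd.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b_ * h * w, c_in * kh * kw)
    wmat = wd.reshape(c_out, c_in * kh * kw)
    out = (cols @ wmat.T).reshape(b_, h, w, c_out).transpose(0, 3, 1, 2)

    def grad_x(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(b_ * h * w, c_out)
        dcols = (gmat @ wmat).reshape(b_, h, w, c_in, kh, kw)
        dxp = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                dxp[:, :, u:u + h, v:v + w] += dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
        return dxp[:, :, ph:ph + h, pw:pw + w]

    def grad_w(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(b_ * h * w, c_out)
        return (gmat.T @ cols).reshape(c_out, c_in, kh, kw)

    parents, fns = (x, weight), (grad_x, grad_w)
    result = Tensor(out, parents=parents, grad_fns=fns)
    if bias is not None:
        result = result + bias.reshape(1, c_out, 1, 1)
    return result


def maxpool2d(x: Tensor, size: int = 2, stride: int = 2) -> Tensor:
    """Max pooling with floor-division output extents."""
    b_, c_, h, w = x.data.shape
    h2, w2 = h // stride, w // stride
    cropped = x.data[:, :, : h2 * stride, : w2 * stride]
    blocks = cropped.reshape(b_, c_, h2, stride, w2, stride)
    out = blocks.max(axis=(3, 5))
    mask = blocks == out[:, :, :, None, :, None]

    def grad_fn(g):
        expanded = mask * g[:, :, :, None, :, None]
        dx = np.zeros_like(x.data)
        dx[:, :, : h2 * stride, : w2 * stride] = expanded.reshape(
            b_, c_, h2 * stride, w2 * stride)
        return dx

    return Tensor(out, parents=(x,), grad_fns=(grad_fn,))


# ---------------------------------------------------------------------------
# module system

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            for m in _collect_modules(value):
                mods.extend(m.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, _Array]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, _Array]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.astype(p.data.dtype, copy=True)


def _collect(value) -> Iterable[Parameter]:
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _collect_modules(value) -> Iterable[Module]:
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect_modules(v)


def trunc_normal(shape, rng: np.random.Generator, std: float = 0.02,
                 dtype=np.float64) -> _Array:
    """Truncated normal initialization (clipped at +-2 std)."""
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std).astype(dtype)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 std: float = 0.02, dtype=np.float64):
        super().__init__()
        self.weight = Parameter(trunc_normal((d_in, d_out), rng, std, dtype))
        self.bias = Parameter(np.zeros(d_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        fan_in = c_in * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))  # He initialization for ReLU stacks
        self.weight = Parameter(
            rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, size: int = 2, stride: int = 2):
        super().__init__()
        self.size, self.stride = size, stride

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.size, self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        c = self.gamma.data.size
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6, dtype=np.float64):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * Tensor(mask)


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                         + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
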