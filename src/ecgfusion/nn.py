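"""Minimal reverse-mode autodiff engine and neural-network layers.

A small numpy tensor library sufficient for the architectures in
:mod:`ecgfusion.models`: 2-D convolution (im2col), max pooling, batch and
layer normalization, dropout, multi-head self-attention and the Adam
optimizer with per-group learning rates. Gradients are validated against
finite differences in the test suite.

Every intermediate :class:`Tensor` on a backward path keeps its gradient
after ``backward()``, which is what Grad-CAM needs to read activations'
gradients without a hook mechanism.
"""

from __future__ import annotations

import numpy as np

_DT = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DT)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data)
        out.requires_grad = requires_grad and _GRAD_ENABLED
        if out.requires_grad:
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.astype(_DT, copy=True)
        else:
            self.grad = self.grad + grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return Tensor._make(out_data, (self, other), backward,
                            self.requires_grad or other.requires_grad)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward,
                            self.requires_grad or other.requires_grad)

    __rmul__ = __mul__

    def __neg__(self):
        return self * Tensor(np.array(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    def pow(self, exponent: float):
        out_data = np.power(self.data, exponent)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * exponent * np.power(self.data, exponent - 1))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward, self.requires_grad)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def relu(self):
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return Tensor._make(self.data * mask, (self,), backward, self.requires_grad)

    def matmul(self, other: "Tensor"):
        out_data = np.matmul(self.data, other.data)

        def backward(out):
            if self.requires_grad:
                g = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                g = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward,
                            self.requires_grad or other.requires_grad)

    __matmul__ = matmul

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward,
                            self.requires_grad)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), backward,
                            self.requires_grad)

    def __getitem__(self, key):
        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accum(g)

        return Tensor._make(self.data[key], (self,), backward, self.requires_grad)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(out):
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(np.array(1.0 / n))

    # -- backprop ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=_DT)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward,
                        any(t.requires_grad for t in tensors))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(out):
        if x.requires_grad:
            g = out.grad * out_data
            g -= out_data * g.sum(axis=axis, keepdims=True)
            x._accum(g)

    return Tensor._make(out_data, (x,), backward, x.requires_grad)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    c = np.sqrt(2.0 / np.pi)
    inner = (x * Tensor(np.array(c))) * (Tensor(np.array(1.0)) + x * x * Tensor(np.array(0.044715)))
    return x * Tensor(np.array(0.5)) * (Tensor(np.array(1.0)) + inner.tanh())


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy between logits (N, C) and integer targets (N,)."""
    targets = np.asarray(targets, dtype=np.int64)
    n = logits.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    log_probs = shifted - log_z
    loss = -log_probs[np.arange(n), targets].mean()

    def backward(out):
        if logits.requires_grad:
            probs = np.exp(log_probs)
            probs[np.arange(n), targets] -= 1.0
            logits._accum(out.grad * probs / n)

    return Tensor._make(np.asarray(loss), (logits,), backward, logits.requires_grad)


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0) -> Tensor:
    """2-D convolution, NCHW input, (F, C, kh, kw) weights."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]                      # (n, c, ho, wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = w.data.reshape(f, -1)
    out_data = cols @ wmat.T
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

    def backward(out):
        gout = out.grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        if b is not None and b.requires_grad:
            b._accum(gout.sum(axis=0))
        if w.requires_grad:
            w._accum((gout.T @ cols).reshape(w.shape))
        if x.requires_grad:
            gcols = (gout @ wmat).reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += \
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            gxp = gxp[:, :, ph:ph + h, pw:pw + wd]
            x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    req = any(p.requires_grad for p in parents)
    return Tensor._make(out_data, parents, backward, req)


def max_pool2d(x: Tensor, k, stride=None, padding=0) -> Tensor:
    """Max pooling with arbitrary kernel/stride (padded with -inf)."""
    kh, kw = _pair(k)
    sh, sw = _pair(stride if stride is not None else k)
    ph, pw = _pair(padding)
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                constant_values=-np.inf)
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw].reshape(n, c, ho, wo, kh * kw)
    am = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, am[..., None], axis=-1)[..., 0]

    def backward(out):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            oh, ow = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
            ih = oh[None, None] * sh + am // kw       # (n, c, ho, wo) padded coords
            iw = ow[None, None] * sw + am % kw
            ni = np.arange(n)[:, None, None, None]
            ci = np.arange(c)[None, :, None, None]
            np.add.at(gxp, (np.broadcast_to(ni, am.shape),
                            np.broadcast_to(ci, am.shape), ih, iw), out.grad)
            x._accum(gxp[:, :, ph:ph + h, pw:pw + w])

    return Tensor._make(out_data, (x,), backward, x.requires_grad)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter registry, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self._named_buffers():
            state[name] = mod.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for name, _ in self._named_buffers():
            self._set_buffer(name, state[name].copy())

    # running statistics (batch norm) -----------------------------------
    def _named_buffers(self, prefix: str = ""):
        for attr in ("running_mean", "running_var"):
            if attr in self.__dict__ and isinstance(self.__dict__[attr], np.ndarray):
                yield prefix + attr, self.__dict__[attr]
        for name, mod in self._modules.items():
            yield from mod._named_buffers(prefix + name + ".")

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        target = self
        for p in parts[:-1]:
            target = target._modules[p]
        object.__setattr__(target, parts[-1], value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_DT)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming_uniform(rng, (in_dim, out_dim), in_dim),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=_DT), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k, rng: np.random.Generator,
                 stride=1, padding=0, bias: bool = True):
        super().__init__()
        kh, kw = _pair(k)
        fan_in = c_in * kh * kw
        self.weight = Tensor(_kaiming_uniform(rng, (c_out, c_in, kh, kw), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=_DT), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding
        self.retain_output = False
        self.last_output: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, self.stride, self.padding)
        if self.retain_output:
            self.last_output = out
        return out


class BatchNorm2d(Module):
    """Channel-wise batch normalization for NCHW tensors."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=_DT), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=_DT), requires_grad=True)
        self.eps, self.momentum = eps, momentum
        object.__setattr__(self, "running_mean", np.zeros(c, dtype=_DT))
        object.__setattr__(self, "running_var", np.ones(c, dtype=_DT))

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * (var + Tensor(np.array(self.eps))).pow(-0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=_DT), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=_DT), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * (var + Tensor(np.array(self.eps))).pow(-0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout: activations scaled by 1/(1-p) so the expected value
    is preserved; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(_DT))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return gelu(x)


class MaxPool2d(Module):
    def __init__(self, k, stride=None, padding=0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.k, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self.mods = mods

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        if d % heads:
            raise ValueError(f"model dim {d} not divisible by {heads} heads")
        self.heads, self.dk = heads, d // heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape

        def split(y: Tensor) -> Tensor:
            return y.reshape(n, t, self.heads, self.dk).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q @ k.transpose(0, 1, 3, 2) * Tensor(np.array(1.0 / np.sqrt(self.dk)))
        attn = self.drop(softmax(scores, axis=-1))
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder block with GELU feed-forward."""

    def __init__(self, d: int, heads: int, ff: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, heads, rng, dropout)
        self.drop1 = Dropout(dropout, rng)
        self.norm2 = LayerNorm(d)
        self.ff1 = Linear(d, ff, rng)
        self.act = GELU()
        self.ff2 = Linear(ff, d, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.norm1(x)))
        x = x + self.drop2(self.ff2(self.act(self.ff1(self.norm2(x)))))
        return x


class Adam:
    """Adam with L2 weight decay and per-group learning rates."""

    def __init__(self, param_groups, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        if param_groups and isinstance(param_groups[0], Tensor):
            param_groups = [{"params": param_groups, "lr": lr}]
        self.groups = [
            {"params": list(g["params"]), "lr": g.get("lr", lr)}
            for g in param_groups
        ]
        self.betas, self.eps, self.weight_decay = betas, eps, weight_decay
        self.t = 0
        self._m = {}
        self._v = {}

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for g in self.groups:
            for p in g["params"]:
                if p.grad is None or not p.requires_grad:
                    continue
                grad = p.grad.astype(np.float64)
                if self.weight_decay:
                    grad = grad + self.weight_decay * p.data
                key = id(p)
                m = self._m.get(key, 0.0)
                v = self._v.get(key, 0.0)
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad**2
                self._m[key], self._v[key] = m, v
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p.data = (p.data - g["lr"] * mhat / (np.sqrt(vhat) + self.eps)).astype(_DT)
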