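"""A compact reverse-mode automatic differentiation core on NumPy arrays.

Only the operations the reconstruction network needs are implemented: 2D
convolution (stride 1, 'same' padding, via im2col), elementwise arithmetic,
leaky ReLU, 2x average pooling / nearest upsampling, channel concatenation,
separable bilinear resizing and mean-squared error.  Tensors carry data of
shape ``(N, C, H, W)`` unless stated otherwise.  Everything is deterministic:
the only randomness is in parameter initialization, which takes an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv2d", "leaky_relu", "avg_pool2", "upsample2",
           "concat", "bilinear_resize", "mse", "add", "mul", "scale",
           "pad_to_multiple", "crop_to", "DTYPE"]

# Compute dtype of the network stack.  float32 doubles matmul throughput on
# CPU BLAS and is ample for training; gradient-checking tests switch to
# float64 via this module attribute.
DTYPE = np.float32


class Tensor:
    """Node in the backward graph; ``grad`` accumulates during backward()."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, iter(node.parents))]
            if id(node) in seen:
                return
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p.parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad += pgrad

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, parents=(), backward=None, requires_grad=True)

    def zero_grad(self):
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def back(g):
        return ((a, g), (b, g))

    return Tensor(a.data + b.data, (a, b), back)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target array."""
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - target
    n = diff.size

    def back(g):
        return ((pred, (2.0 / n) * diff * g),)

    return Tensor(np.mean(diff**2), (pred,), back)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise (broadcasting) product."""
    a, b = _as_tensor(a), _as_tensor(b)

    def back(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return Tensor(a.data * b.data, (a, b), back)


def scale(x: Tensor, c: float) -> Tensor:
    x = _as_tensor(x)

    def back(g):
        return ((x, c * g),)

    return Tensor(c * x.data, (x,), back)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)

    def back(g):
        return ((x, np.where(mask, g, slope * g)),)

    return Tensor(out, (x,), back)


def conv2d(x: Tensor, w: Parameter, b: Parameter | None = None) -> Tensor:
    """Stride-1 'same' 2D convolution: x (N,Cin,H,W), w (Cout,Cin,k,k)."""
    x = _as_tensor(x)
    n, cin, h, wd = x.data.shape
    cout, cin_w, k, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, cin * k * k)
    wm = w.data.reshape(cout, cin * k * k)
    y = cols @ wm.T
    if b is not None:
        y = y + b.data[None, :]
    out = y.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)

    def back(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(n * h * wd, cout)
        grads = []
        if w.requires_grad:
            gw = (gflat.T @ cols).reshape(cout, cin, k, k)
            grads.append((w, gw))
        if b is not None and b.requires_grad:
            grads.append((b, gflat.sum(axis=0)))
        if x.requires_grad:
            dcols = (gflat @ wm).reshape(n, h, wd, cin, k, k)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            grads.append((x, dxp[:, :, p : p + h, p : p + wd]))
        return tuple(grads)

    return Tensor(out, (x, w) + ((b,) if b is not None else ()), back)


def avg_pool2(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dims")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def back(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        return ((x, gx),)

    return Tensor(out, (x,), back)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x = _as_tensor(x)
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def back(g):
        n, c, h, w = x.data.shape
        gx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        return ((x, gx),)

    return Tensor(out, (x,), back)


def concat(tensors: list[Tensor]) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[1] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=1)
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=1)
        return tuple(zip(tensors, parts))

    return Tensor(out, tuple(tensors), back)


def _linear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Edge-clamped linear interpolation matrix mapping n_in -> n_out samples.
    Exactly the identity when n_out == n_in."""
    if n_out == n_in:
        return np.eye(n_in)
    mat = np.zeros((n_out, n_in))
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0.0, n_in - 1.0)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Separable bilinear resize to (H_out, W_out)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    ry = _linear_matrix(size[0], h).astype(x.data.dtype)
    rx = _linear_matrix(size[1], w).astype(x.data.dtype)
    out = ry @ x.data @ rx.T

    def back(g):
        return ((x, ry.T @ g @ rx),)

    return Tensor(out, (x,), back)


def pad_to_multiple(x: Tensor, m: int) -> tuple[Tensor, tuple[int, int]]:
    """Zero-pad spatial dims up to the next multiple of ``m``."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    ph = (-h) % m
    pw = (-w) % m
    if ph == 0 and pw == 0:
        return x, (h, w)
    out = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)))

    def back(g):
        return ((x, g[:, :, :h, :w]),)

    return Tensor(out, (x,), back), (h, w)


def crop_to(x: Tensor, hw: tuple[int, int]) -> Tensor:
    x = _as_tensor(x)
    h, w = hw
    if x.data.shape[2] == h and x.data.shape[3] == w:
        return x
    out = x.data[:, :, :h, :w]

    def back(g):
        gx = np.zeros_like(x.data)
        gx[:, :, :h, :w] = g
        return ((x, gx),)

    return Tensor(out, (x,), back)
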