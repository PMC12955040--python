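"""Modules built on the autodiff core: conv blocks, a 2D U-Net, Adam."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = ["Module", "ConvBlock", "UNet2D", "Adam"]


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state dict length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state dict shape mismatch")
            p.data = a.copy()


class ConvBlock(Module):
    """k x k convolution (+ optional leaky ReLU), He-initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, act: bool = True, zero_init: bool = False):
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            w = rng.normal(0.0, scale, size=(cout, cin, k, k))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(cout))
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.conv2d(x, self.w, self.b)
        return ag.leaky_relu(y) if self.act else y


class UNet2D(Module):
    """Encoder-decoder with skip connections; depth = number of poolings.

    Input (N, cin, H, W) -> output (N, cout, H, W); odd sizes are zero-padded
    to a multiple of ``2**depth`` internally and cropped back.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 base: int = 16, depth: int = 2):
        self.depth = depth
        self.enc: list[ConvBlock] = []
        widths = [base * (2**d) for d in range(depth + 1)]
        c = cin
        for w in widths[:-1]:
            self.enc.append(ConvBlock(c, w, rng))
            self.enc.append(ConvBlock(w, w, rng))
            c = w
        self.bottleneck = [
            ConvBlock(c, widths[-1], rng),
            ConvBlock(widths[-1], widths[-1], rng),
        ]
        self.dec: list[ConvBlock] = []
        c = widths[-1]
        for w in reversed(widths[:-1]):
            self.dec.append(ConvBlock(c + w, w, rng))
            self.dec.append(ConvBlock(w, w, rng))
            c = w
        self.head = ConvBlock(c, cout, rng, k=1, act=False)

    def __call__(self, x: Tensor) -> Tensor:
        x, orig = ag.pad_to_multiple(x, 2**self.depth)
        skips = []
        for d in range(self.depth):
            x = self.enc[2 * d](x)
            x = self.enc[2 * d + 1](x)
            skips.append(x)
            x = ag.avg_pool2(x)
        for blk in self.bottleneck:
            x = blk(x)
        for d in range(self.depth):
            x = ag.upsample2(x)
            x = ag.concat([x, skips[-1 - d]])
            x = self.dec[2 * d](x)
            x = self.dec[2 * d + 1](x)
        x = self.head(x)
        return ag.crop_to(x, orig)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
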