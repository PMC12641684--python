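"""Layers and parameter containers for the volumetric networks."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor, conv3d


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=DTYPE).reshape(p.data.shape)


class Conv3d(Module):
    """Same-padded stride-1 3D convolution with He-style init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / (cin * k ** 3))
        self.weight = Tensor(rng.normal(0.0, scale, (cout, cin, k, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation with learnable scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class ConvBlock(Module):
    """conv -> instance norm -> leaky ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        self.conv = Conv3d(cin, cout, k, rng)
        self.norm = InstanceNorm3d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).leaky_relu(0.01)
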