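"""Neural-network modules built on the autodiff engine.

Each module owns its parameter tensors, exposes ``forward`` for computation
and ``param_count``/``macs`` for the architecture fingerprint accounting.
MACs follow the usual convolution convention (kernel volume x Cin x Cout x
output voxels); parameter-free operations (pooling, activations, additions)
contribute none.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: recursive parameter collection and train/eval switching."""

    def __init__(self):
        self.training = True

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield m

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
        for c in self.children():
            out.extend(c.parameters())
        return out

    def train(self, mode=True):
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def param_count(self):
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *a, **k):
        return self.forward(*a, **k)

    def state_arrays(self):
        """Flat ordered list of (name, array) for checkpointing."""
        out = []
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((name, v.data))
            elif isinstance(v, np.ndarray):
                out.append((name, v))
        for i, c in enumerate(self.children()):
            for n, arr in c.state_arrays():
                out.append((f"{i}.{n}", arr))
        return out


def _kaiming(rng, shape, fan_in):
    std = math.sqrt(2.0 / fan_in)
    return Tensor((rng.standard_normal(shape) * std).astype(np.float32),
                  requires_grad=True)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel, rng, bias=True):
        super().__init__()
        kz, ky, kx = kernel
        self.kernel = kernel
        self.cin, self.cout = cin, cout
        fan = cin * kz * ky * kx
        self.w = _kaiming(rng, (cout, cin, kz, ky, kx), fan)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ad.conv3d(x, self.w, self.b)

    def macs(self, spatial):
        return self.cin * self.cout * int(np.prod(self.kernel)) * int(np.prod(spatial))


class DownConv(Module):
    """In-plane halving (1,2,2)-kernel strided convolution."""

    def __init__(self, cin, cout, rng, bias=True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.w = _kaiming(rng, (cout, cin, 1, 2, 2), cin * 4)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ad.down_conv2x2(x, self.w, self.b)

    def macs(self, out_spatial):
        return self.cin * self.cout * 4 * int(np.prod(out_spatial))


class UpConv(Module):
    """In-plane doubling (1,2,2)-kernel transposed convolution."""

    def __init__(self, cin, cout, rng, bias=True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.w = _kaiming(rng, (cin, cout, 2, 2), cin)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ad.up_conv2x2(x, self.w, self.b)

    def macs(self, out_spatial):
        return self.cin * self.cout * int(np.prod(out_spatial))


class BatchNorm3d(Module):
    def __init__(self, c):
        super().__init__()
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x):
        return ad.batch_norm(x, self.gamma, self.beta,
                             self.running_mean, self.running_var, self.training)

    def macs(self, spatial):
        return 0


class PReLU(Module):
    def __init__(self, c):
        super().__init__()
        self.alpha = Tensor(np.full(c, 0.25, np.float32), requires_grad=True)

    def forward(self, x):
        return ad.prelu(x, self.alpha)

    def macs(self, spatial):
        return 0


class Linear(Module):
    def __init__(self, cin, cout, rng, bias=True):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.w = _kaiming(rng, (cout, cin), cin)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ad.linear(x, self.w, self.b)

    def macs(self, _spatial=None):
        return self.cin * self.cout
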