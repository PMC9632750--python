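"""Layer modules built on the autodiff core.

Modules own :class:`~dermofuse.nn.autodiff.Param` leaves and are callable
on :class:`Var` nodes.  ``params()`` walks the module tree so optimizers
and freeze/unfreeze logic can address every weight; freezing a module
flips the ``trainable`` flag on its parameters without touching values.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Param, Var


class Module:
    """Base class: parameter discovery + freeze/unfreeze."""

    def params(self) -> list[Param]:
        found: list[Param] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            if isinstance(obj, Param):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    found.append(obj)
            elif isinstance(obj, Module):
                stack.extend(obj.__dict__.values())
            elif isinstance(obj, (list, tuple)):
                stack.extend(obj)
            elif isinstance(obj, dict):
                stack.extend(obj.values())
        return found

    def set_trainable(self, flag: bool) -> None:
        for p in self.params():
            p.trainable = flag

    def __call__(self, x: Var) -> Var:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2D(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int | tuple[int, int],
                 stride: int = 1, padding: str = "valid", *,
                 rng: np.random.Generator, name: str = "conv"):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = kh * kw * c_in
        self.w = Param(he_normal(rng, (kh, kw, c_in, c_out), fan_in), name=f"{name}.w")
        self.b = Param(np.zeros(c_out, dtype=np.float32), name=f"{name}.b")
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Var) -> Var:
        return ad.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator,
                 name: str = "dense"):
        self.w = Param(he_normal(rng, (d_in, d_out), d_in), name=f"{name}.w")
        self.b = Param(np.zeros(d_out, dtype=np.float32), name=f"{name}.b")

    def __call__(self, x: Var) -> Var:
        return ad.add(ad.matmul(x, self.w), self.b)


class GlobalAvgPool(Module):
    """Spatial mean: (N, H, W, C) -> (N, C)."""

    def __call__(self, x: Var) -> Var:
        pooled = ad.mean_reduce(x, (1, 2), keepdims=True)
        n, _, _, c = pooled.shape
        return ad.reshape(pooled, (n, c))


class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate.

    Channel attention squeezes the map with global average and max pooling,
    pushes both descriptors through a shared two-layer bottleneck MLP
    (reduction ``ratio``), sums them and applies a sigmoid; the map is
    rescaled channel-wise.  Spatial attention pools the gated map across
    channels (mean and max), convolves the two-plane descriptor with a 7x7
    kernel ('same' padding) and rescales with the sigmoid response.
    """

    def __init__(self, channels: int, reduction_ratio: int = 16, *,
                 rng: np.random.Generator, name: str = "cbam"):
        if channels % reduction_ratio != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by the reduction "
                f"ratio ({reduction_ratio})")
        hidden = channels // reduction_ratio
        self.fc1 = Dense(channels, hidden, rng=rng, name=f"{name}.fc1")
        self.fc2 = Dense(hidden, channels, rng=rng, name=f"{name}.fc2")
        self.spatial = Conv2D(2, 1, 7, padding="same", rng=rng, name=f"{name}.spatial")
        self.channels = channels

    def _mlp(self, v: Var) -> Var:
        return self.fc2(ad.relu(self.fc1(v)))

    def __call__(self, x: Var) -> Var:
        n, h, w, c = x.shape
        avg = ad.reshape(ad.mean_reduce(x, (1, 2)), (n, c))
        mx = ad.reshape(ad.max_reduce(x, (1, 2)), (n, c))
        gate_c = ad.sigmoid(ad.add(self._mlp(avg), self._mlp(mx)))
        x = ad.mul(x, ad.reshape(gate_c, (n, 1, 1, c)))
        s_avg = ad.mean_reduce(x, 3, keepdims=True)
        s_max = ad.max_reduce(x, 3, keepdims=True)
        gate_s = ad.sigmoid(self.spatial(ad.concat([s_avg, s_max], axis=-1)))
        return ad.mul(x, gate_s)


class Sequential(Module):
    def __init__(self, *steps):
        self.steps = list(steps)

    def __call__(self, x: Var) -> Var:
        for step in self.steps:
            x = step(x) if isinstance(step, Module) else step(x)
        return x


class ReLU(Module):
    def __call__(self, x: Var) -> Var:
        return ad.relu(x)
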