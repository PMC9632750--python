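"""Forward-only NumPy builds of the three standard CNN feature extractors
(Inception V3, InceptionResNet V2, Xception).

Each architecture is encoded layer by layer — kernel sizes, strides,
padding conventions ('valid' stems, 'same' mixed blocks) and filter
schedules follow the published designs — so the spatial/channel geometry
of the emitted feature map is *computed* by propagating an input through
the graph, never hard-coded.  Two execution modes share the same graph
code:

* shape mode — propagates ``(H, W, C)`` tuples through the exact output-
  size arithmetic of every layer (instant);
* array mode — a real forward pass with randomly initialized weights
  (He-normal), single image, float32.

Normalization layers are identity at initialization and do not affect
geometry, so they are omitted; only random-initialization passes are
exercised here.  For a 450 x 600 x 3 input the three extractors emit
(12, 17, 2048), (12, 17, 1536) and (14, 19, 2048) respectively.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from ..nn.autodiff import same_pad_amounts


class FeatureShape(NamedTuple):
    h: int
    w: int
    c: int


def _is_shape(x) -> bool:
    return isinstance(x, FeatureShape)


def _out_dim(size: int, k: int, s: int, padding: str) -> int:
    if padding == "same":
        return -(-size // s)
    out = (size - k) // s + 1
    if out <= 0:
        raise ValueError(f"layer output would be empty (size={size}, k={k}, s={s})")
    return out


def _pad_hw(x: np.ndarray, kh: int, kw: int, s: int, padding: str,
            value: float = 0.0) -> np.ndarray:
    if padding != "same":
        return x
    pt, pb = same_pad_amounts(x.shape[0], kh, s)
    pl, pr = same_pad_amounts(x.shape[1], kw, s)
    if pt or pb or pl or pr:
        x = np.pad(x, ((pt, pb), (pl, pr), (0, 0)), constant_values=value)
    return x


class Graph:
    """Layer-application context: dispatches on shape vs array inputs."""

    def __init__(self, rng: np.random.Generator | None = None):
        self.rng = rng

    # -- primitive layers ------------------------------------------------
    def conv(self, x, c_out: int, kernel, stride: int = 1,
             padding: str = "valid", act: bool = True):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if _is_shape(x):
            return FeatureShape(_out_dim(x.h, kh, stride, padding),
                                _out_dim(x.w, kw, stride, padding), c_out)
        c_in = x.shape[2]
        w = self.rng.normal(0, np.sqrt(2.0 / (kh * kw * c_in)),
                            size=(kh, kw, c_in, c_out)).astype(np.float32)
        xp = _pad_hw(x, kh, kw, stride, padding)
        ho = (xp.shape[0] - kh) // stride + 1
        wo = (xp.shape[1] - kw) // stride + 1
        out = np.zeros((ho, wo, c_out), dtype=np.float32)
        for ki in range(kh):
            for kj in range(kw):
                patch = xp[ki:ki + stride * ho:stride,
                           kj:kj + stride * wo:stride, :]
                out += (patch.reshape(-1, c_in) @ w[ki, kj]).reshape(ho, wo, c_out)
        return np.maximum(out, 0.0) if act else out

    def sepconv(self, x, c_out: int, kernel: int = 3, stride: int = 1,
                padding: str = "same", act: bool = True):
        if _is_shape(x):
            return FeatureShape(_out_dim(x.h, kernel, stride, padding),
                                _out_dim(x.w, kernel, stride, padding), c_out)
        c_in = x.shape[2]
        dw = self.rng.normal(0, np.sqrt(2.0 / (kernel * kernel)),
                             size=(kernel, kernel, c_in)).astype(np.float32)
        xp = _pad_hw(x, kernel, kernel, stride, padding)
        ho = (xp.shape[0] - kernel) // stride + 1
        wo = (xp.shape[1] - kernel) // stride + 1
        mid = np.zeros((ho, wo, c_in), dtype=np.float32)
        for ki in range(kernel):
            for kj in range(kernel):
                mid += xp[ki:ki + stride * ho:stride,
                          kj:kj + stride * wo:stride, :] * dw[ki, kj]
        pw = self.rng.normal(0, np.sqrt(2.0 / c_in),
                             size=(c_in, c_out)).astype(np.float32)
        out = (mid.reshape(-1, c_in) @ pw).reshape(ho, wo, c_out)
        return np.maximum(out, 0.0) if act else out

    def _pool(self, x, k: int, stride: int, padding: str, kind: str):
        if _is_shape(x):
            return FeatureShape(_out_dim(x.h, k, stride, padding),
                                _out_dim(x.w, k, stride, padding), x.c)
        fill = -np.inf if kind == "max" else 0.0
        xp = _pad_hw(x, k, k, stride, padding, value=fill)
        ho = (xp.shape[0] - k) // stride + 1
        wo = (xp.shape[1] - k) // stride + 1
        acc = None
        for ki in range(k):
            for kj in range(k):
                patch = xp[ki:ki + stride * ho:stride,
                           kj:kj + stride * wo:stride, :]
                if acc is None:
                    acc = patch.copy()
                elif kind == "max":
                    np.maximum(acc, patch, out=acc)
                else:
                    acc += patch
        return acc if kind == "max" else acc / (k * k)

    def maxpool(self, x, k: int = 3, stride: int = 2, padding: str = "valid"):
        return self._pool(x, k, stride, padding, "max")

    def avgpool(self, x, k: int = 3, stride: int = 1, padding: str = "same"):
        return self._pool(x, k, stride, padding, "avg")

    def concat(self, xs):
        if _is_shape(xs[0]):
            if len({(s.h, s.w) for s in xs}) != 1:
                raise ValueError(f"concat spatial mismatch: {xs}")
            return FeatureShape(xs[0].h, xs[0].w, sum(s.c for s in xs))
        return np.concatenate(xs, axis=-1)

    def add(self, a, b, scale_b: float = 1.0, act: bool = True):
        if _is_shape(a):
            if a != b:
                raise ValueError(f"residual add shape mismatch: {a} vs {b}")
            return a
        out = a + scale_b * b
        return np.maximum(out, 0.0) if act else out


# ---------------------------------------------------------------------------
# Inception V3
# ---------------------------------------------------------------------------

def _inception_stem(g: Graph, x):
    x = g.conv(x, 32, 3, stride=2)
    x = g.conv(x, 32, 3)
    x = g.conv(x, 64, 3, padding="same")
    x = g.maxpool(x, 3, 2)
    x = g.conv(x, 80, 1)
    x = g.conv(x, 192, 3)
    x = g.maxpool(x, 3, 2)
    return x


def inception_v3(x, g: Graph):
    x = _inception_stem(g, x)
    # mixed 0-2 (5x5-style factorized blocks)
    for pool_proj in (32, 64, 64):
        b0 = g.conv(x, 64, 1)
        b1 = g.conv(g.conv(x, 48, 1), 64, 5, padding="same")
        b2 = g.conv(g.conv(g.conv(x, 64, 1), 96, 3, padding="same"),
                    96, 3, padding="same")
        b3 = g.conv(g.avgpool(x), pool_proj, 1)
        x = g.concat([b0, b1, b2, b3])
    # mixed 3 (grid reduction)
    b0 = g.conv(x, 384, 3, stride=2)
    b1 = g.conv(g.conv(g.conv(x, 64, 1), 96, 3, padding="same"), 96, 3, stride=2)
    x = g.concat([b0, b1, g.maxpool(x, 3, 2)])
    # mixed 4-7 (7x1 / 1x7 factorized blocks)
    for mid in (128, 160, 160, 192):
        b0 = g.conv(x, 192, 1)
        b1 = g.conv(x, mid, 1)
        b1 = g.conv(b1, mid, (1, 7), padding="same")
        b1 = g.conv(b1, 192, (7, 1), padding="same")
        b2 = g.conv(x, mid, 1)
        b2 = g.conv(b2, mid, (7, 1), padding="same")
        b2 = g.conv(b2, mid, (1, 7), padding="same")
        b2 = g.conv(b2, mid, (7, 1), padding="same")
        b2 = g.conv(b2, 192, (1, 7), padding="same")
        b3 = g.conv(g.avgpool(x), 192, 1)
        x = g.concat([b0, b1, b2, b3])
    # mixed 8 (grid reduction)
    b0 = g.conv(g.conv(x, 192, 1), 320, 3, stride=2)
    b1 = g.conv(x, 192, 1)
    b1 = g.conv(b1, 192, (1, 7), padding="same")
    b1 = g.conv(b1, 192, (7, 1), padding="same")
    b1 = g.conv(b1, 192, 3, stride=2)
    x = g.concat([b0, b1, g.maxpool(x, 3, 2)])
    # mixed 9-10 (expanded-filter-bank blocks)
    for _ in range(2):
        b0 = g.conv(x, 320, 1)
        b1 = g.conv(x, 384, 1)
        b1 = g.concat([g.conv(b1, 384, (1, 3), padding="same"),
                       g.conv(b1, 384, (3, 1), padding="same")])
        b2 = g.conv(g.conv(x, 448, 1), 384, 3, padding="same")
        b2 = g.concat([g.conv(b2, 384, (1, 3), padding="same"),
                       g.conv(b2, 384, (3, 1), padding="same")])
        b3 = g.conv(g.avgpool(x), 192, 1)
        x = g.concat([b0, b1, b2, b3])
    return x


# ---------------------------------------------------------------------------
# InceptionResNet V2
# ---------------------------------------------------------------------------

def inception_resnet_v2(x, g: Graph):
    x = _inception_stem(g, x)
    # mixed 5b
    b0 = g.conv(x, 96, 1)
    b1 = g.conv(g.conv(x, 48, 1), 64, 5, padding="same")
    b2 = g.conv(g.conv(g.conv(x, 64, 1), 96, 3, padding="same"),
                96, 3, padding="same")
    b3 = g.conv(g.avgpool(x), 64, 1)
    x = g.concat([b0, b1, b2, b3])  # 320 channels
    # 10 x block35 (residual, scale 0.17)
    for _ in range(10):
        b0 = g.conv(x, 32, 1)
        b1 = g.conv(g.conv(x, 32, 1), 32, 3, padding="same")
        b2 = g.conv(g.conv(g.conv(x, 32, 1), 48, 3, padding="same"),
                    64, 3, padding="same")
        up = g.conv(g.concat([b0, b1, b2]), 320 if _is_shape(x) else x.shape[2],
                    1, act=False)
        x = g.add(x, up, scale_b=0.17)
    # reduction 6a
    b0 = g.conv(x, 384, 3, stride=2)
    b1 = g.conv(g.conv(g.conv(x, 256, 1), 256, 3, padding="same"),
                384, 3, stride=2)
    x = g.concat([b0, b1, g.maxpool(x, 3, 2)])  # 1088 channels
    # 20 x block17 (residual, scale 0.10)
    for _ in range(20):
        b0 = g.conv(x, 192, 1)
        b1 = g.conv(x, 128, 1)
        b1 = g.conv(b1, 160, (1, 7), padding="same")
        b1 = g.conv(b1, 192, (7, 1), padding="same")
        up = g.conv(g.concat([b0, b1]), 1088 if _is_shape(x) else x.shape[2],
                    1, act=False)
        x = g.add(x, up, scale_b=0.10)
    # reduction 7a
    b0 = g.conv(g.conv(x, 256, 1), 384, 3, stride=2)
    b1 = g.conv(g.conv(x, 256, 1), 288, 3, stride=2)
    b2 = g.conv(g.conv(g.conv(x, 256, 1), 288, 3, padding="same"),
                320, 3, stride=2)
    x = g.concat([b0, b1, b2, g.maxpool(x, 3, 2)])  # 2080 channels
    # 10 x block8 (residual, scale 0.20; final block unscaled, linear)
    for i in range(10):
        b0 = g.conv(x, 192, 1)
        b1 = g.conv(x, 192, 1)
        b1 = g.conv(b1, 224, (1, 3), padding="same")
        b1 = g.conv(b1, 256, (3, 1), padding="same")
        up = g.conv(g.concat([b0, b1]), 2080 if _is_shape(x) else x.shape[2],
                    1, act=False)
        last = i == 9
        x = g.add(x, up, scale_b=1.0 if last else 0.20, act=not last)
    return g.conv(x, 1536, 1)


# ---------------------------------------------------------------------------
# Xception
# ---------------------------------------------------------------------------

def xception(x, g: Graph):
    x = g.conv(x, 32, 3, stride=2)
    x = g.conv(x, 64, 3)
    # entry flow: three strided residual blocks
    for c in (128, 256, 728):
        shortcut = g.conv(x, c, 1, stride=2, padding="same", act=False)
        y = g.sepconv(x, c)
        y = g.sepconv(y, c)
        y = g.maxpool(y, 3, 2, padding="same")
        x = g.add(shortcut, y, act=False)
    # middle flow: eight identity residual blocks
    for _ in range(8):
        y = g.sepconv(x, 728)
        y = g.sepconv(y, 728)
        y = g.sepconv(y, 728)
        x = g.add(x, y, act=False)
    # exit flow
    shortcut = g.conv(x, 1024, 1, stride=2, padding="same", act=False)
    y = g.sepconv(x, 728)
    y = g.sepconv(y, 1024)
    y = g.maxpool(y, 3, 2, padding="same")
    x = g.add(shortcut, y, act=False)
    x = g.sepconv(x, 1536)
    x = g.sepconv(x, 2048)
    return x


REFERENCE_BACKBONES = {
    "inception_v3": inception_v3,
    "inception_resnet_v2": inception_resnet_v2,
    "xception": xception,
}


def feature_map_shape(name: str,
                      input_shape: tuple[int, int, int] = (450, 600, 3)
                      ) -> FeatureShape:
    """Output (H, W, C) of a backbone, by shape propagation through its graph."""
    fn = REFERENCE_BACKBONES[name]
    h, w, c = input_shape
    return fn(FeatureShape(h, w, c), Graph())


def forward(name: str, image: np.ndarray, seed: int = 0) -> np.ndarray:
    """Real forward pass of one H x W x 3 image through a randomly
    initialized build of the named backbone."""
    fn = REFERENCE_BACKBONES[name]
    g = Graph(rng=np.random.default_rng(seed))
    return fn(np.asarray(image, dtype=np.float32), g)
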