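"""Small trainable convolutional backbones.

``TinyBackbone`` emits a feature map of an exactly requested (H, W, C)
geometry from any sufficiently large input: stride-2 'same' convolutions
halve the spatial dims while they remain at least twice the target, and
a final 'valid' convolution with a fitted kernel lands exactly on the
target.  This makes every fusion builder testable at desk scale,
including the mixed-geometry case (e.g. branches emitting 12x17 and
14x19 maps from one input), with gradients available end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ..nn.autodiff import Var
from ..nn.layers import Conv2D, Module, ReLU, Sequential


@dataclass
class BackboneSpec:
    """Declarative description of a feature extractor."""

    name: str
    builder: Callable[[tuple[int, int, int], np.random.Generator], Module]
    expected_map: tuple[int, int, int] | None = None
    pretrained: bool = False
    descriptor: dict | None = None  # serializable recipe, when one exists

    def build(self, input_shape: tuple[int, int, int],
              rng: np.random.Generator) -> Module:
        try:
            module = self.builder(input_shape, rng)
        except Exception as exc:
            raise RuntimeError(
                f"failed to build backbone {self.name!r}: {exc}") from exc
        return module


class TinyBackbone(Module):
    def __init__(self, input_shape: tuple[int, int, int],
                 out_map: tuple[int, int, int], width: int = 8, *,
                 rng: np.random.Generator, name: str = "tiny"):
        h, w, c_in = input_shape
        th, tw, tc = out_map
        if th > h or tw > w:
            raise ValueError(f"target map {out_map} larger than input {input_shape}")
        steps = []
        c_cur = c_in
        while -(-h // 2) >= th and -(-w // 2) >= tw:
            steps.append(Conv2D(c_cur, width, 3, stride=2, padding="same",
                                rng=rng, name=f"{name}.down{len(steps)}"))
            steps.append(ReLU())
            c_cur = width
            h, w = -(-h // 2), -(-w // 2)
        kh, kw = h - th + 1, w - tw + 1
        steps.append(Conv2D(c_cur, tc, (kh, kw), rng=rng, name=f"{name}.fit"))
        steps.append(ReLU())
        self.net = Sequential(*steps)
        self.out_map = (th, tw, tc)

    def __call__(self, x: Var) -> Var:
        return self.net(x)


def tiny_backbone(seed: int, out_map: tuple[int, int, int],
                  width: int = 8, name: str | None = None) -> BackboneSpec:
    """A :class:`BackboneSpec` for a randomly initialized tiny extractor."""
    name = name or f"tiny_{out_map[0]}x{out_map[1]}x{out_map[2]}"

    def builder(input_shape, rng=None):
        rng = rng if rng is not None else np.random.default_rng(seed)
        return TinyBackbone(input_shape, out_map, width=width, rng=rng, name=name)

    return BackboneSpec(name=name, builder=builder, expected_map=tuple(out_map),
                        descriptor={"kind": "tiny", "seed": seed,
                                    "out_map": list(out_map), "width": width,
                                    "name": name})
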