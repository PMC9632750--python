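"""Style-transfer upsampling: executing an augmentation plan through a
pluggable stylization backend.

The default backend is a statistical color transfer: the content image is
mapped into CIE Lab (a decorrelated luminance/chrominance space), each
channel's mean and standard deviation are affinely matched to the style
image's statistics, the result is blended with the original by
``strength`` and mapped back to RGB.  Any other stylizer (e.g. a neural
network served externally) can be registered under a name and swapped in
without touching the planner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from skimage.color import lab2rgb, rgb2lab

from .balance import AugmentationPlan
from .dataio import ImageRecord, LabeledDataset, Provenance

logger = logging.getLogger(__name__)


@dataclass
class StylizationRequest:
    content: ImageRecord
    style: ImageRecord
    strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.content.label != self.style.label:
            raise ValueError(
                f"content ({self.content.label}) and style "
                f"({self.style.label}) must share a class label")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")


class StylizerBackend(Protocol):
    name: str

    def stylize(self, req: StylizationRequest) -> np.ndarray: ...


def statistical_style_transfer(req: StylizationRequest) -> np.ndarray:
    """Match Lab-channel mean/std of the content image to the style image.

    A zero-variance style channel keeps the content statistics for that
    channel.  Output has the content's shape, clipped to [0, 1].
    """
    content = np.asarray(req.content.pixels, dtype=np.float64)
    style = np.asarray(req.style.pixels, dtype=np.float64)
    if content.ndim != 3 or style.ndim != 3:
        raise ValueError("both images must be H x W x 3")
    if content.max() > 1.0:
        content = content / 255.0
    if style.max() > 1.0:
        style = style / 255.0
    c_lab = rgb2lab(content)
    s_lab = rgb2lab(style)
    out = np.empty_like(c_lab)
    for ch in range(3):
        c_mu, c_sd = c_lab[..., ch].mean(), c_lab[..., ch].std()
        s_mu, s_sd = s_lab[..., ch].mean(), s_lab[..., ch].std()
        if s_sd == 0.0 or c_sd == 0.0:
            out[..., ch] = c_lab[..., ch]
            continue
        out[..., ch] = (c_lab[..., ch] - c_mu) * (s_sd / c_sd) + s_mu
    blended = req.strength * out + (1.0 - req.strength) * c_lab
    rgb = lab2rgb(blended)
    return np.clip(rgb, 0.0, 1.0).astype(np.float32)


class StatisticalBackend:
    name = "statistical"

    def stylize(self, req: StylizationRequest) -> np.ndarray:
        return statistical_style_transfer(req)


_BACKENDS: dict[str, Callable[[], StylizerBackend]] = {
    "statistical": StatisticalBackend,
}


def register_backend(name: str, factory: Callable[[], StylizerBackend]) -> None:
    _BACKENDS[name] = factory


def get_backend(name: str) -> StylizerBackend:
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise KeyError(f"unknown stylizer backend {name!r}; "
                       f"registered: {sorted(_BACKENDS)}") from None


def execute_plan(train: LabeledDataset, plan: AugmentationPlan,
                 backend: StylizerBackend | None = None, seed: int = 0,
                 strength: float = 1.0) -> LabeledDataset:
    """Create the styled records an :class:`AugmentationPlan` prescribes.

    Classes with deficit ratio >= 1: every content image spawns
    ``num_add`` styled images, with style sources drawn from the same
    class without replacement (excluding the content image itself).
    Classes with ratio < 1: ``num_sub`` uniformly chosen content images
    each spawn one styled image.  Deterministic under a fixed seed; the
    input dataset is never mutated.
    """
    backend = backend or StatisticalBackend()
    rng = np.random.default_rng(seed)
    out = list(train.records)
    for cls in train.classes:
        cp = plan.per_class.get(cls)
        if cp is None or (cp.num_add == 0 and cp.num_sub == 0):
            continue
        members = train.by_class(cls)
        if len(members) != cp.n_before:
            raise ValueError(
                f"plan for class {cls!r} was computed for {cp.n_before} "
                f"images but the dataset has {len(members)}")
        if cp.num_add >= 1:
            for rec in members:
                pool = [m for m in members if m.id != rec.id]
                if cp.num_add <= len(pool):
                    idx = rng.choice(len(pool), size=cp.num_add, replace=False)
                else:
                    logger.warning(
                        "class %s: only %d candidate style images for "
                        "num_add=%d; sampling with replacement",
                        cls, len(pool), cp.num_add)
                    idx = rng.choice(len(pool), size=cp.num_add, replace=True)
                for j, i in enumerate(idx):
                    style = pool[int(i)]
                    styled = backend.stylize(StylizationRequest(
                        content=rec, style=style, strength=strength, seed=seed))
                    out.append(ImageRecord(
                        id=f"{rec.id}_styled_{j}", pixels=styled,
                        label=rec.label, provenance=Provenance.STYLED,
                        source_id=rec.id))
        else:
            chosen = rng.choice(len(members), size=cp.num_sub, replace=False)
            for j, i in enumerate(chosen):
                rec = members[int(i)]
                pool = [m for m in members if m.id != rec.id]
                style = pool[int(rng.integers(len(pool)))]
                styled = backend.stylize(StylizationRequest(
                    content=rec, style=style, strength=strength, seed=seed))
                out.append(ImageRecord(
                    id=f"{rec.id}_styled_sub_{j}", pixels=styled,
                    label=rec.label, provenance=Provenance.STYLED,
                    source_id=rec.id))
    return LabeledDataset(out, train.classes)
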