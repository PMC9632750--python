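"""Class-imbalance treatments.

Four strategies are provided, mirroring how severely imbalanced
dermoscopy datasets are usually rebalanced before training:

* rotation upsampling — every minority-class image is joined by its
  left-right mirror, up-down mirror and 180-degree rotation (4x count);
* style-transfer allocation — per-class counts of styled images needed
  to reach the majority class, computed from the deficit ratio
  ``(n_majority - n_class) / n_class`` with flooring (the planner here;
  execution lives in :mod:`dermofuse.styletransfer`);
* class weights — ``n_samples / (n_classes * count)`` loss reweighting;
* pixel perturbation — duplicate images shifted by a small random
  intensity offset drawn without replacement from ``[1, pixel_max]``
  with ``pixel_max = deficit / (2 * n_classes)`` (8-bit scale).

The flooring in the allocation is deliberate: when the deficit ratio is
4.13 the plan adds exactly 4 styled images per content image, leaving a
small residual deficit rather than topping classes up to an exact match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import LabeledDataset, Provenance


def rotate_lr(img: np.ndarray) -> np.ndarray:
    """Mirror about the vertical centerline (left-right flip)."""
    _check_image(img)
    return img[:, ::-1].copy()


def rotate_ud(img: np.ndarray) -> np.ndarray:
    """Mirror about the horizontal centerline (up-down flip)."""
    _check_image(img)
    return img[::-1].copy()


def rotate_sym(img: np.ndarray) -> np.ndarray:
    """Left-right then up-down flip; equivalent to a 180-degree rotation."""
    _check_image(img)
    return img[::-1, ::-1].copy()


def _check_image(img: np.ndarray) -> None:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")


_ROTATIONS = (
    (Provenance.ROTATE_LR, rotate_lr),
    (Provenance.ROTATE_UD, rotate_ud),
    (Provenance.ROTATE_SYM, rotate_sym),
)


def augment_rotations(train: LabeledDataset, majority_class: str) -> LabeledDataset:
    """Add the three mirror variants of every non-majority image.

    Originals of all classes (including the majority) are retained, so
    minority classes end at 4x their incoming count and the majority is
    unchanged.
    """
    if majority_class not in train.classes:
        raise ValueError(f"majority class {majority_class!r} not in class list")
    out = []
    for rec in train.records:
        out.append(rec)
        if rec.label == majority_class:
            continue
        for prov, fn in _ROTATIONS:
            out.append(rec.with_pixels(fn(rec.pixels),
                                       id=f"{rec.id}_{prov.value}",
                                       provenance=prov))
    return LabeledDataset(out, train.classes)


@dataclass
class ClassPlan:
    """Planned style-transfer additions for one class."""

    n_before: int
    n_target: int
    ratio: float
    num_add: int
    num_sub: int
    n_after: int


@dataclass
class AugmentationPlan:
    """Per-class allocation of styled-image additions."""

    majority_class: str
    per_class: dict[str, ClassPlan]

    @property
    def total_styled(self) -> int:
        return sum(p.num_add * p.n_before + p.num_sub
                   for p in self.per_class.values())

    def to_dict(self) -> dict:
        return {
            "majority_class": self.majority_class,
            "per_class": {cls: vars(p) for cls, p in self.per_class.items()},
        }


def compute_allocation(counts: dict[str, int],
                       majority_class: str) -> AugmentationPlan:
    """Plan styled-image additions from post-rotation per-class counts.

    For each class the deficit ratio ``(n_majority - n) / n`` determines
    the treatment: ratio >= 1 means every image spawns ``floor(ratio)``
    styled copies; ratio < 1 means only the raw deficit ``n_majority - n``
    images are styled (one styled copy each), topping the class up to the
    majority count exactly.
    """
    if majority_class not in counts:
        raise ValueError(f"majority class {majority_class!r} not in counts")
    n_target = counts[majority_class]
    if any(n <= 0 for n in counts.values()):
        empty = [c for c, n in counts.items() if n <= 0]
        raise ValueError(f"empty class(es): {empty}")
    if n_target != max(counts.values()):
        raise ValueError(
            f"{majority_class!r} ({n_target}) is not the largest class")
    per_class = {}
    for cls, n in counts.items():
        ratio = (n_target - n) / n
        if ratio >= 1:
            num_add = int(np.floor(ratio))
            num_sub = 0
            n_after = n * (1 + num_add)
        else:
            num_add = 0
            num_sub = n_target - n
            n_after = n_target
        per_class[cls] = ClassPlan(n_before=n, n_target=n_target, ratio=ratio,
                                   num_add=num_add, num_sub=num_sub,
                                   n_after=n_after)
    return AugmentationPlan(majority_class=majority_class, per_class=per_class)


def class_weights(counts: dict[str, int]) -> dict[str, float]:
    """Inverse-frequency loss weights: ``n_samples / (n_classes * count)``.

    Balanced counts give unit weights; the identity
    ``sum_i weight_i * count_i == n_samples`` always holds.
    """
    if any(n <= 0 for n in counts.values()):
        raise ValueError("every class must be non-empty")
    n_samples = sum(counts.values())
    n_classes = len(counts)
    return {cls: n_samples / (n_classes * n) for cls, n in counts.items()}


@dataclass
class PerturbationSpec:
    """Random intensity-shift upsampling for one minority class.

    ``differences`` is the gap to the majority count (post-rotation);
    the admissible shift magnitudes are the integers in
    ``[1, floor(differences / (2 * n_classes))]`` on the 8-bit scale,
    drawn without replacement until the pool is exhausted.
    """

    differences: int
    n_classes: int

    def __post_init__(self):
        self.pixel_max = int(np.floor(self.differences / (2 * self.n_classes)))
        if self.pixel_max < 1:
            raise ValueError(
                f"pixel_max = {self.pixel_max} < 1; the perturbation scheme "
                f"needs a deficit of at least 2 * n_classes")
        self._pool: list[int] = []

    def draw(self, rng: np.random.Generator) -> int:
        """Draw a shift magnitude without replacement; the pool resets with
        a warning once exhausted."""
        if not self._pool:
            if hasattr(self, "_drawn_once"):
                warnings.warn("perturbation value pool exhausted; resetting",
                              stacklevel=2)
            self._drawn_once = True
            self._pool = list(rng.permutation(np.arange(1, self.pixel_max + 1)))
        return int(self._pool.pop())


def pixel_perturbation(img: np.ndarray, spec: PerturbationSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Shift all channels by a random +/-v (8-bit units), clipping to range.

    Images in [0, 1] are shifted by ``v / 255``; 8-bit images by ``v``.
    """
    _check_image(img)
    v = spec.draw(rng)
    sign = 1 if rng.random() < 0.5 else -1
    if np.issubdtype(img.dtype, np.integer):
        out = img.astype(np.int32) + sign * v
        return np.clip(out, 0, 255).astype(img.dtype)
    out = img + np.float32(sign * v / 255.0)
    return np.clip(out, 0.0, 1.0)


def perturbation_upsample(train: LabeledDataset, majority_class: str,
                          seed: int = 0) -> LabeledDataset:
    """Balance every minority class exactly by adding perturbed duplicates.

    Content images are drawn uniformly without replacement (cycling if the
    deficit exceeds the class size); each duplicate gets an intensity
    shift from the class's :class:`PerturbationSpec`.
    """
    counts = train.counts
    n_target = counts[majority_class]
    n_classes = len(train.classes)
    rng = np.random.default_rng(seed)
    out = list(train.records)
    for cls in train.classes:
        deficit = n_target - counts[cls]
        if deficit <= 0:
            continue
        spec = PerturbationSpec(differences=deficit, n_classes=n_classes)
        members = train.by_class(cls)
        order = rng.permutation(len(members))
        for k in range(deficit):
            if k and k % len(members) == 0:
                order = rng.permutation(len(members))
            src = members[order[k % len(members)]]
            out.append(src.with_pixels(
                pixel_perturbation(src.pixels, spec, rng),
                id=f"{src.id}_perturbed_{k}", provenance=Provenance.PERTURBED))
    return LabeledDataset(out, train.classes)
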