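"""Synthetic dermoscopy-like image generator.

Generates labeled lesion images with the severe class imbalance of the
seven-class pigmented-lesion archive (printed counts 6,705 / 1,113 /
1,099 / 514 / 327 / 142 / 115 across nv, mel, bkl, bcc, akiec, vasc,
df), at a configurable scale so every pipeline stage is testable
without downloads.  Each image is a noisy skin-tone background with one
elliptical lesion whose hue, radius jitter and border irregularity
(sinusoidal radial perturbation) depend on the class; disjoint hue
ranges per class make small datasets learnably separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb

from .dataio import HAM10000_CLASSES, ImageRecord, LabeledDataset, write_dataset

# full-archive per-class image counts (class -> count)
HAM10000_COUNTS = {
    "nv": 6705, "mel": 1113, "bkl": 1099, "bcc": 514,
    "akiec": 327, "vasc": 142, "df": 115,
}

#: per-class appearance: (hue_lo, hue_hi, border_irregularity, texture_noise)
#: hue ranges are disjoint and spread around the hue circle so that even
#: small synthetic datasets are learnably separable by lesion color
DEFAULT_APPEARANCE = {
    "nv":    (0.00, 0.04, 0.10, 0.02),
    "mel":   (0.26, 0.30, 0.35, 0.05),
    "bkl":   (0.13, 0.17, 0.20, 0.04),
    "bcc":   (0.55, 0.59, 0.25, 0.03),
    "akiec": (0.40, 0.44, 0.30, 0.04),
    "vasc":  (0.83, 0.87, 0.12, 0.03),
    "df":    (0.68, 0.72, 0.15, 0.03),
}


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic dataset."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(HAM10000_COUNTS))
    image_size: tuple[int, int] = (64, 64)
    seed: int = 0
    appearance: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_APPEARANCE))

    def __post_init__(self):
        if any(n <= 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be positive")
        missing = set(self.class_counts) - set(self.appearance)
        if missing:
            raise ValueError(f"no appearance parameters for {sorted(missing)}")

    @property
    def classes(self) -> tuple[str, ...]:
        ordered = [c for c in HAM10000_CLASSES if c in self.class_counts]
        extra = [c for c in self.class_counts if c not in ordered]
        return tuple(ordered + extra)


def scaled_counts(scale: float, base: dict[str, int] | None = None,
                  min_count: int = 2) -> dict[str, int]:
    """Scale the archive counts, rounding to the nearest integer with a
    floor of ``min_count`` so stratified 3:1:1 splitting stays feasible."""
    base = base or HAM10000_COUNTS
    if scale <= 0:
        raise ValueError("scale must be positive")
    return {c: max(min_count, int(np.rint(n * scale))) for c, n in base.items()}


def _draw_lesion(class_name: str, spec: SyntheticSpec,
                 rng: np.random.Generator):
    """Draw one image plus its lesion mask and ellipse semi-axes."""
    h, w = spec.image_size
    hue_lo, hue_hi, irregularity, noise_scale = spec.appearance[class_name]

    # skin-tone background with additive gaussian noise
    base = np.array([0.80, 0.60, 0.48]) + rng.normal(0, 0.03, size=3)
    img = np.clip(base[None, None, :] + rng.normal(0, 0.02, size=(h, w, 3)),
                  0, 1)

    # elliptical lesion with sinusoidal radial border perturbation
    cy = h / 2 + rng.uniform(-0.08, 0.08) * h
    cx = w / 2 + rng.uniform(-0.08, 0.08) * w
    a = h * rng.uniform(0.18, 0.28)   # semi-axis (rows)
    b = w * rng.uniform(0.18, 0.28)   # semi-axis (cols)
    k = rng.integers(3, 7)            # lobes of the border wobble
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / a, (xx - cx) / b
    boundary = 1.0 + irregularity * np.sin(k * np.arctan2(dy, dx) + phase)
    mask = np.hypot(dy, dx) <= boundary

    hue = rng.uniform(hue_lo, hue_hi)
    sat = rng.uniform(0.75, 0.9)
    val = rng.uniform(0.45, 0.55)
    lesion_rgb = hsv2rgb(np.array([[[hue, sat, val]]]))[0, 0]
    texture = rng.normal(0, noise_scale, size=(h, w, 3))
    lesion = np.clip(lesion_rgb[None, None, :] + texture, 0, 1)
    img[mask] = lesion[mask]
    return np.clip(img, 0, 1).astype(np.float32), mask, a, b


def generate_lesion_image(class_name: str, spec: SyntheticSpec,
                          rng: np.random.Generator,
                          image_id: str | None = None) -> ImageRecord:
    """One lesion image: skin background + one irregular ellipse."""
    img, _, _, _ = _draw_lesion(class_name, spec, rng)
    image_id = image_id or f"{class_name}_{rng.integers(1 << 30)}"
    return ImageRecord(id=image_id, pixels=img, label=class_name)


def lesion_mask_area(class_name: str, spec: SyntheticSpec,
                     rng: np.random.Generator) -> tuple[int, float]:
    """Realized lesion pixel count vs the analytic ellipse area pi*a*b."""
    _, mask, a, b = _draw_lesion(class_name, spec, rng)
    return int(mask.sum()), float(np.pi * a * b)


def generate_dataset(spec: SyntheticSpec,
                     out_dir: str | Path | None = None) -> LabeledDataset:
    """A full synthetic dataset matching ``spec.class_counts`` exactly.

    With ``out_dir`` the images and a ``metadata.csv`` manifest are also
    written in the layout :func:`dermofuse.dataio.load_dataset` consumes.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for cls in spec.classes:
        for i in range(spec.class_counts[cls]):
            records.append(generate_lesion_image(
                cls, spec, rng, image_id=f"{cls}_{i:05d}"))
    ds = LabeledDataset(records, spec.classes)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds
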