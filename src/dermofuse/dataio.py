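"""Dataset ingestion, preprocessing and stratified splitting.

Images are RGB arrays in row-major order (origin top-left).  Raw inputs
are 8-bit; preprocessing resizes to a fixed target (default 450 rows by
600 columns, nearest-neighbor) and rescales intensities to [0, 1] by
min-max normalization ``(X - X_min) / (X_max - X_min)``.  By default the
range is the fixed 8-bit one (``X_min=0, X_max=255``) so that contrast
relationships between images are preserved; an optional per-image mode
uses each image's own extrema.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

DEFAULT_TARGET_H = 450
DEFAULT_TARGET_W = 600

HAM10000_CLASSES = ("akiec", "bcc", "bkl", "df", "nv", "mel", "vasc")


class Provenance(str, enum.Enum):
    ORIGINAL = "original"
    ROTATE_LR = "rotate_lr"
    ROTATE_UD = "rotate_ud"
    ROTATE_SYM = "rotate_sym"
    STYLED = "styled"
    PERTURBED = "perturbed"


@dataclass
class ImageRecord:
    """One labeled RGB image with provenance tracking."""

    id: str
    pixels: np.ndarray
    label: str
    provenance: Provenance = Provenance.ORIGINAL
    source_id: str | None = None

    def __post_init__(self):
        if self.source_id is None:
            self.source_id = self.id
        if self.provenance == Provenance.ORIGINAL and self.source_id != self.id:
            raise ValueError(
                f"original record {self.id!r} must have source_id == id")

    def with_pixels(self, pixels: np.ndarray, *, id: str,
                    provenance: Provenance) -> "ImageRecord":
        return ImageRecord(id=id, pixels=pixels, label=self.label,
                           provenance=provenance, source_id=self.id)


@dataclass
class LabeledDataset:
    """Ordered collection of records over a closed class list."""

    records: list[ImageRecord]
    classes: tuple[str, ...]

    def __post_init__(self):
        self.classes = tuple(self.classes)
        bad = {r.label for r in self.records} - set(self.classes)
        if bad:
            raise ValueError(f"labels outside the class list: {sorted(bad)}")

    @property
    def counts(self) -> dict[str, int]:
        c = {cls: 0 for cls in self.classes}
        for r in self.records:
            c[r.label] += 1
        return c

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids: set[str]) -> "LabeledDataset":
        return LabeledDataset([r for r in self.records if r.id in ids],
                              self.classes)

    def by_class(self, label: str) -> list[ImageRecord]:
        return [r for r in self.records if r.label == label]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack pixels into (N, H, W, 3) float32 and labels into class indices."""
        x = np.stack([r.pixels for r in self.records]).astype(np.float32)
        index = {c: i for i, c in enumerate(self.classes)}
        y = np.array([index[r.label] for r in self.records], dtype=np.intp)
        return x, y


@dataclass
class DatasetSplits:
    train: LabeledDataset
    valid: LabeledDataset
    test: LabeledDataset
    ratio: tuple[int, int, int] = (3, 1, 1)

    def __iter__(self):
        yield from (self.train, self.valid, self.test)


def load_dataset(image_dir: str | Path, metadata: str | Path | pd.DataFrame,
                 classes: tuple[str, ...] = HAM10000_CLASSES) -> LabeledDataset:
    """Read a metadata table (columns ``image_id,label``) and its images.

    Pixels are left raw (8-bit).  Missing files, unknown labels and empty
    tables are hard errors naming the offending row.
    """
    image_dir = Path(image_dir)
    if isinstance(metadata, (str, Path)):
        meta = pd.read_csv(metadata)
    else:
        meta = metadata
    required = {"image_id", "label"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if len(meta) == 0:
        raise ValueError("empty dataset: metadata has no rows")
    records = []
    for row in meta.itertuples(index=False):
        image_id, label = str(row.image_id), str(row.label)
        if label not in classes:
            raise ValueError(f"unknown label {label!r} for image {image_id!r}")
        path = None
        for ext in ("", ".png", ".jpg", ".jpeg", ".PNG", ".JPG"):
            cand = image_dir / f"{image_id}{ext}"
            if cand.is_file():
                path = cand
                break
        if path is None:
            raise FileNotFoundError(
                f"image file for id {image_id!r} not found under {image_dir}")
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("RGB"))
        records.append(ImageRecord(id=image_id, pixels=pixels, label=label))
    return LabeledDataset(records, classes)


def preprocess_image(raw: np.ndarray, target_h: int = DEFAULT_TARGET_H,
                     target_w: int = DEFAULT_TARGET_W, *,
                     per_image: bool = False) -> np.ndarray:
    """Resize (nearest-neighbor) then min-max normalize to [0, 1].

    ``per_image=True`` uses the image's own min/max; a constant image then
    maps to all zeros by convention (max == min).  The default divides by
    the fixed 8-bit range.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 array, got shape {raw.shape}")
    if target_h <= 0 or target_w <= 0:
        raise ValueError("target dimensions must be positive")
    if np.issubdtype(raw.dtype, np.floating) and raw.max() <= 1.0:
        # already-normalized input: quantize back to the 8-bit scale so the
        # operation is idempotent up to round-trip quantization
        raw = np.clip(np.round(raw * 255.0), 0, 255).astype(np.uint8)
    if raw.shape[:2] != (target_h, target_w):
        im = Image.fromarray(raw.astype(np.uint8))
        im = im.resize((target_w, target_h), resample=Image.NEAREST)
        raw = np.asarray(im)
    x = raw.astype(np.float32)
    if per_image:
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            return np.zeros((target_h, target_w, 3), dtype=np.float32)
        return (x - lo) / (hi - lo)
    return x / 255.0


def preprocess_dataset(ds: LabeledDataset, target_h: int = DEFAULT_TARGET_H,
                       target_w: int = DEFAULT_TARGET_W, *,
                       per_image: bool = False) -> LabeledDataset:
    records = [replace(r, pixels=preprocess_image(r.pixels, target_h, target_w,
                                                  per_image=per_image))
               for r in ds.records]
    return LabeledDataset(records, ds.classes)


def _largest_remainder(n: int, ratio: tuple[int, ...]) -> list[int]:
    """Split ``n`` into parts proportional to ``ratio``: floor, then hand the
    remaining units to the largest fractional parts (ties to earlier parts)."""
    total = sum(ratio)
    exact = [n * r / total for r in ratio]
    parts = [int(e) for e in exact]
    rem = n - sum(parts)
    order = sorted(range(len(ratio)), key=lambda i: (parts[i] - exact[i], i))
    for i in order[:rem]:
        parts[i] += 1
    return parts


def stratified_split(ds: LabeledDataset, ratio: tuple[int, int, int] = (3, 1, 1),
                     seed: int = 0) -> DatasetSplits:
    """Deterministic per-class split into train/valid/test.

    Within every class the ids are shuffled with the seeded generator and
    allocated by largest-remainder rounding of the ratio, so realized
    per-class proportions are within one record of the exact fractions.
    """
    if len(ratio) != 3 or any(r <= 0 for r in ratio):
        raise ValueError("ratio must be three positive integers")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in ds.classes:
        members = [r.id for r in ds.by_class(cls)]
        if not members:
            raise ValueError(f"class {cls!r} has zero members")
        perm = rng.permutation(len(members))
        parts = _largest_remainder(len(members), ratio)
        bounds = np.cumsum(parts)
        for pos, idx in enumerate(perm):
            part = int(np.searchsorted(bounds, pos, side="right"))
            assignment[members[idx]] = part
    buckets = [set(), set(), set()]
    for rid, part in assignment.items():
        buckets[part].add(rid)
    return DatasetSplits(train=ds.subset(buckets[0]),
                         valid=ds.subset(buckets[1]),
                         test=ds.subset(buckets[2]),
                         ratio=tuple(ratio))


def write_manifest(splits: DatasetSplits, path: str | Path) -> pd.DataFrame:
    """Write a split manifest CSV (image_id,label,split,provenance,source_id)."""
    rows = []
    for name, part in zip(("train", "valid", "test"), splits):
        for r in part.records:
            rows.append({"image_id": r.id, "label": r.label, "split": name,
                         "provenance": r.provenance.value,
                         "source_id": r.source_id})
    frame = pd.DataFrame(rows, columns=["image_id", "label", "split",
                                        "provenance", "source_id"])
    frame.to_csv(path, index=False)
    return frame


def write_dataset(ds: LabeledDataset, out_dir: str | Path,
                  metadata_name: str = "metadata.csv") -> Path:
    """Write records as PNGs plus a metadata CSV consumable by load_dataset."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in ds.records:
        px = r.pixels
        if px.dtype != np.uint8:
            px = np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(px).save(out_dir / "images" / f"{r.id}.png")
        rows.append({"image_id": r.id, "label": r.label})
    meta_path = out_dir / metadata_name
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path
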