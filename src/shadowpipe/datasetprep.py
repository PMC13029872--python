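"""Labeled image sets, input-size standardization and the stratified split.

Classifier inputs are square grayscale images (default 229 x 229).  Because
resizing destroys the organism-size signal, the original pixel dimensions of
every image are recorded *before* any resize and carried through as the
classifier's secondary input.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

TARGET_PX = 229  # network input side length
SPLIT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class ImageRecord:
    """One labeled image with its pre-resize size metadata."""

    image: np.ndarray
    label: str
    original_size: tuple[int, int]  # (height, width) before any resize
    split: str = "none"  # train / val / test / none
    name: str = ""
    provenance: str = "original"  # e.g. "original" or "augmented:<ops>"


@dataclass
class LabeledImageSet:
    """Images + class labels + original-size metadata + split assignment."""

    records: list[ImageRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def subset(self, split: str) -> "LabeledImageSet":
        return LabeledImageSet([r for r in self.records if r.split == split])

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filename": [r.name for r in self.records],
                "class": [r.label for r in self.records],
                "split": [r.split for r in self.records],
                "original_h": [r.original_size[0] for r in self.records],
                "original_w": [r.original_size[1] for r in self.records],
                "provenance": [r.provenance for r in self.records],
            }
        )

    def content_hash(self) -> str:
        """Order-sensitive hash over image bytes, labels and sizes."""
        h = hashlib.sha256()
        for r in self.records:
            h.update(np.ascontiguousarray(r.image, dtype=np.float64).tobytes())
            h.update(r.label.encode())
            h.update(repr(r.original_size).encode())
        return h.hexdigest()


def standardize_image(img: np.ndarray, target_px: int = TARGET_PX):
    """Resize to a target square, returning the pre-resize (h, w) unchanged.

    Anisotropic stretch to square: the lost aspect/scale information is
    compensated by the classifier's size input rather than by letterboxing.
    Bilinear interpolation with anti-aliasing on downscale.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    original_size = (int(img.shape[0]), int(img.shape[1]))
    if original_size == (target_px, target_px):
        return img.copy(), original_size
    out = resize(img, (target_px, target_px), order=1, anti_aliasing=True,
                 preserve_range=True)
    return np.clip(out, 0.0, 1.0), original_size


def standardize_dataset(dataset: LabeledImageSet, target_px: int = TARGET_PX) -> LabeledImageSet:
    out = []
    for r in dataset.records:
        std, orig = standardize_image(r.image, target_px)
        # original_size recorded at creation wins over the pre-resize shape
        size = r.original_size if r.original_size is not None else orig
        out.append(replace(r, image=std, original_size=size))
    return LabeledImageSet(out)


def split_dataset(
    dataset: LabeledImageSet,
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS,
    seed: int = 0,
) -> LabeledImageSet:
    """Stratified train/val/test split (default 70/15/15).

    Per class, images are shuffled with the seed and the three split sizes
    are apportioned by largest remainder (ties favor train), so every
    split's count is within one image of its exact quota — per-class
    proportions always land inside fraction +/- 1/n.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(dataset.records):
        by_class.setdefault(r.label, []).append(i)
    for label, idx in sorted(by_class.items()):
        if len(idx) < 3:
            raise ValueError(f"class {label!r} has fewer than 3 images; cannot split")
    rng = np.random.default_rng(seed)
    records = [replace(r) for r in dataset.records]
    f_train, f_val, f_test = fractions
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n = len(idx)
        quotas = np.array([f_train * n, f_val * n, f_test * n])
        counts = np.floor(quotas).astype(int)
        # largest-remainder apportionment; ties favor train, then val
        for k in np.argsort(-(quotas - counts), kind="stable")[: n - counts.sum()]:
            counts[k] += 1
        n_train, n_val, _ = counts
        for j, i in enumerate(idx):
            if j < n_train:
                records[i].split = "train"
            elif j < n_train + n_val:
                records[i].split = "val"
            else:
                records[i].split = "test"
    return LabeledImageSet(records)


def write_split_manifest(dataset: LabeledImageSet, path: str | Path) -> None:
    dataset.manifest().to_csv(path, index=False)


def load_class_tree_directory(root: str | Path) -> LabeledImageSet:
    """Read a class-per-folder tree of grayscale PNGs."""
    from .io import read_image

    root = Path(root)
    records = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(class_dir.glob("*.png")):
            img = read_image(f)
            records.append(
                ImageRecord(
                    image=img,
                    label=class_dir.name,
                    original_size=(img.shape[0], img.shape[1]),
                    name=f.name,
                )
            )
    return LabeledImageSet(records)


def write_class_tree_directory(dataset: LabeledImageSet, root: str | Path) -> None:
    from .io import write_image

    root = Path(root)
    for i, r in enumerate(dataset.records):
        name = r.name or f"img_{i:06d}.png"
        write_image(root / r.label / name, r.image)
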