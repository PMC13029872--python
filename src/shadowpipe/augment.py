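"""Class-balanced dataset augmentation.

Each augmented copy is produced by a fixed chain — slight Gaussian blur,
additive Gaussian noise, then one randomly drawn scale/rotation/reflection
— applied to the base image.  Per-class multiplicative factors control how
many copies (including the original) appear in the output; a factor of 0.5
downsamples an over-represented class to its larger half instead.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import rescale, resize, rotate

from .datasetprep import ImageRecord, LabeledImageSet

# Factors used for the project's base and secondary (gelatinous) datasets.
BASE_FACTORS = {
    "Chaetognath": 14,
    "Crustacean": 0.5,
    "DetritusA": 14,
    "DetritusB": 14,
    "Gelatinous": 2,
    "Larvacean": 2,
}
SECONDARY_FACTORS = {
    "Annelid": 8,
    "Ctenophora": 5,
    "Doliolid": 8,
    "Medusozoa": 2,
    "Radiolaria": 3,
    "Siphonophora": 7,
}


@dataclass
class AugmentParams:
    """Magnitudes of the augmentation chain.

    Blur and noise are 'slight' relative to silhouettes tens of pixels
    across; silhouettes have no canonical orientation in the water column,
    so rotation spans the full circle and both reflections are allowed.
    """

    blur_sigma: float = 1.0  # px
    noise_sigma: float = 0.02  # intensity on [0, 1]
    scale_range: tuple[float, float] = (0.8, 1.2)
    rotation_range: tuple[float, float] = (0.0, 360.0)
    reflect_horizontal: bool = True
    reflect_vertical: bool = True

    def validate(self) -> None:
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be >= 0")
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError("scale_range must satisfy 0 < lo <= hi")


def _border_fill(img: np.ndarray) -> float:
    border = np.concatenate([img[0, :], img[-1, :], img[:, 0], img[:, -1]])
    return float(np.median(border))


def _rotate_exact(img: np.ndarray, angle: float, cval: float) -> np.ndarray:
    """Rotation; multiples of 90 degrees are lossless."""
    angle = angle % 360.0
    if np.isclose(angle % 90.0, 0.0):
        return np.rot90(img, k=int(round(angle / 90.0)) % 4).copy()
    return rotate(img, angle, resize=False, order=1, cval=cval,
                  preserve_range=True)


def augment_image(img: np.ndarray, params: AugmentParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Blur -> noise -> random scale/rotation/reflection, canvas preserved.

    The empty background exposed by shrink/rotation is filled with the
    median border intensity, avoiding dark corner artifacts that would
    mimic silhouettes.  Deterministic given the generator state.
    """
    params.validate()
    img = np.asarray(img, dtype=np.float64)
    out = img
    if params.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, params.blur_sigma)
    if params.noise_sigma > 0:
        out = out + rng.normal(0.0, params.noise_sigma, size=out.shape)
    out = np.clip(out, 0.0, 1.0)

    fill = _border_fill(out)
    lo, hi = params.scale_range
    scale = float(rng.uniform(lo, hi))
    if not np.isclose(scale, 1.0):
        scaled = rescale(out, scale, order=1, anti_aliasing=scale < 1,
                         preserve_range=True)
        canvas = np.full_like(out, fill)
        h, w = out.shape
        sh, sw = scaled.shape
        if scale < 1.0:
            r0, c0 = (h - sh) // 2, (w - sw) // 2
            canvas[r0:r0 + sh, c0:c0 + sw] = scaled
        else:
            r0, c0 = (sh - h) // 2, (sw - w) // 2
            canvas = scaled[r0:r0 + h, c0:c0 + w]
        out = canvas

    angle = float(rng.uniform(*params.rotation_range))
    out = _rotate_exact(out, angle, cval=fill)
    if params.reflect_horizontal and rng.random() < 0.5:
        out = out[:, ::-1]
    if params.reflect_vertical and rng.random() < 0.5:
        out = out[::-1, :]
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)


def _check_factor(factor) -> None:
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if factor < 1 and factor != 0.5:
        raise ValueError("the only supported downsampling factor is 0.5")
    if factor >= 1 and int(factor) != factor:
        raise ValueError("factors >= 1 must be integers")


def augment_class(
    records: list[ImageRecord],
    factor,
    params: AugmentParams | None = None,
    rng: np.random.Generator | None = None,
    keep_larger: bool = True,
) -> list[ImageRecord]:
    """Apply one class's multiplicative factor.

    Integer k: each original plus (k - 1) augmented copies, in source
    order.  Factor 0.5: keep ceil(n/2) images — by default the *larger*
    half by original pixel area (ties broken by name/order), retaining the
    informative large specimens of an over-represented class.
    """
    _check_factor(factor)
    params = params or AugmentParams()
    rng = rng or np.random.default_rng(0)
    if factor == 0.5:
        n_keep = int(np.ceil(len(records) / 2))
        order = sorted(
            range(len(records)),
            key=lambda i: (
                -records[i].original_size[0] * records[i].original_size[1]
                if keep_larger
                else records[i].original_size[0] * records[i].original_size[1],
                records[i].name,
                i,
            ),
        )
        kept = sorted(order[:n_keep])
        return [replace(records[i]) for i in kept]
    k = int(factor)
    out: list[ImageRecord] = []
    for rec in records:
        out.append(replace(rec))
        for j in range(k - 1):
            img = augment_image(rec.image, params, rng)
            stem = rec.name.rsplit(".", 1)[0] if rec.name else "img"
            out.append(
                replace(
                    rec,
                    image=img,
                    name=f"{stem}_aug{j + 1}.png",
                    provenance=f"augmented:{rec.name or stem}",
                )
            )
    return out


def build_augmented_dataset(
    dataset: LabeledImageSet,
    factors: dict | None = None,
    params: AugmentParams | None = None,
    seed: int = 0,
    keep_larger: bool = True,
) -> LabeledImageSet:
    """Apply the factor table per class; absent classes get factor 1.

    Augmentation must start from original raw images: feeding an already
    augmented set here would augment twice, so records with augmented
    provenance are rejected.
    """
    factors = BASE_FACTORS if factors is None else factors
    for r in dataset.records:
        if r.provenance.startswith("augmented"):
            raise ValueError("dataset already contains augmented images; "
                             "augmentation is never applied twice")
    out: list[ImageRecord] = []
    by_class: dict[str, list[ImageRecord]] = {}
    for r in dataset.records:
        by_class.setdefault(r.label, []).append(r)
    for label in sorted(by_class):
        factor = factors.get(label, 1)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
        )
        out.extend(augment_class(by_class[label], factor, params, rng,
                                 keep_larger=keep_larger))
    return LabeledImageSet(out)
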