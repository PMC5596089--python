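"""Synthetic crop dataset for the recognizer: rendered silhouettes of the
four classes with pose, scale and illumination jitter, plus the rescaling /
horizontal-mirroring augmentation used before training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import CLASSES

__all__ = ["CropDataset", "make_crops", "augment", "mirror", "rescale"]


@dataclass
class CropDataset:
    images: list[np.ndarray]            # H x W x 3 floats in [0, 1]
    labels: list[int]                   # indices into CLASSES
    split: list[str] = field(default_factory=list)   # "train" | "val"

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must align")
        bad = [l for l in self.labels if not 0 <= l < len(CLASSES)]
        if bad:
            raise ValueError(f"labels outside the {len(CLASSES)}-class set: {bad}")
        if not self.split:
            self.split = ["train"] * len(self.images)

    def __len__(self) -> int:
        return len(self.images)

    def split_arrays(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        idx = [i for i, s in enumerate(self.split) if s == which]
        if not idx:
            return np.empty((0,)), np.empty((0,), dtype=int)
        return (
            np.stack([self.images[i] for i in idx]),
            np.array([self.labels[i] for i in idx], dtype=int),
        )

    def train_val_split(self, train_fraction: float = 0.7, seed: int = 0) -> "CropDataset":
        """Random split (default 7:3) that keeps every class present in the
        training part when possible."""
        rng = np.random.default_rng(seed)
        split = ["val"] * len(self)
        by_class: dict[int, list[int]] = {}
        for i, l in enumerate(self.labels):
            by_class.setdefault(l, []).append(i)
        for members in by_class.values():
            members = list(members)
            rng.shuffle(members)
            n_train = max(1, int(round(train_fraction * len(members))))
            for i in members[:n_train]:
                split[i] = "train"
        return CropDataset(list(self.images), list(self.labels), split)


def _texture(rng: np.random.Generator, size: int) -> np.ndarray:
    base = rng.random((size // 4 + 1, size // 4 + 1, 3))
    img = ndimage.zoom(base, (4, 4, 1), order=1)[:size, :size]
    return np.clip(img, 0.0, 1.0)


def _silhouette(label: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of the object outline on a size x size grid."""
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    cx = 0.5 + rng.uniform(-0.08, 0.08)
    base = 0.9 + rng.uniform(-0.05, 0.03)       # ground line
    s = 1.0 + rng.uniform(-0.15, 0.15)          # overall scale

    if label == "can":
        wdt, hgt = 0.42 * s, 0.40 * s
        mask = (np.abs(xx - cx) < wdt / 2) & (yy > base - hgt) & (yy < base)
    elif label == "bottle":
        wdt, hgt = 0.30 * s, 0.62 * s
        neck_w, neck_h = 0.11 * s, 0.22 * s
        body = (np.abs(xx - cx) < wdt / 2) & (yy > base - hgt + neck_h) & (yy < base)
        neck = (np.abs(xx - cx) < neck_w / 2) & (yy > base - hgt) & (yy <= base - hgt + neck_h)
        mask = body | neck
    elif label == "cup":
        wdt, hgt = 0.40 * s, 0.42 * s
        body = (np.abs(xx - cx) < wdt / 2) & (yy > base - hgt) & (yy < base)
        hy, hx = base - hgt / 2, cx + wdt / 2
        r = ((xx - hx) ** 2 + (yy - hy) ** 2) ** 0.5
        handle = (r > 0.07 * s) & (r < 0.13 * s) & (xx > hx)
        mask = body | handle
    else:
        raise ValueError(f"no silhouette for label {label!r}")
    return mask


def make_crops(n_per_class: int, size: int = 32, seed: int = 0) -> CropDataset:
    """Render ``n_per_class`` crops per class at ``size`` x ``size``."""
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for label_idx, label in enumerate(CLASSES):
        for _ in range(n_per_class):
            img = _texture(rng, size) * rng.uniform(0.35, 0.7)
            if label != "background":
                mask = _silhouette(label, size, rng)
                color = rng.uniform(0.4, 1.0, 3)
                shade = 1.0 - 0.5 * (np.mgrid[0:size, 0:size][1] / (size - 1))
                img[mask] = (color[None, :] * shade[mask, None])
            illum = rng.uniform(0.8, 1.2)
            images.append(np.clip(img * illum, 0.0, 1.0))
            labels.append(label_idx)
    return CropDataset(images, labels)


def mirror(image: np.ndarray) -> np.ndarray:
    """Horizontal reflection (flip the column axis)."""
    return image[:, ::-1].copy()


def rescale(image: np.ndarray, factor: float) -> np.ndarray:
    """Spatial rescaling by ``factor``, center-cropped or edge-padded back
    to the original shape.  ``factor == 1`` is pixel-identical."""
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    if factor == 1.0:
        return image.copy()
    h, w = image.shape[:2]
    zoomed = ndimage.zoom(image, (factor, factor, 1), order=1)
    zh, zw = zoomed.shape[:2]
    if zh >= h:
        i0, j0 = (zh - h) // 2, (zw - w) // 2
        return np.clip(zoomed[i0:i0 + h, j0:j0 + w], 0.0, 1.0)
    out = np.zeros_like(image)
    i0, j0 = (h - zh) // 2, (w - zw) // 2
    out[i0:i0 + zh, j0:j0 + zw] = np.clip(zoomed, 0.0, 1.0)
    return out


def augment(dataset: CropDataset, scale_factor: float = 1.2) -> CropDataset:
    """Add a mirrored and a rescaled copy of every crop (n -> 3n); labels
    and split assignments carry over."""
    if len(dataset) == 0:
        raise ValueError("cannot augment an empty dataset")
    images = list(dataset.images)
    labels = list(dataset.labels)
    split = list(dataset.split)
    for img, lbl, spl in zip(dataset.images, dataset.labels, dataset.split):
        images.append(mirror(img))
        labels.append(lbl)
        split.append(spl)
        images.append(rescale(img, scale_factor))
        labels.append(lbl)
        split.append(spl)
    return CropDataset(images, labels, split)
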