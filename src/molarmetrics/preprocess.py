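"""Radiograph preprocessing and annotation-preserving augmentation.

CLAHE (contrast limited adaptive histogram equalization) enhances local
contrast tile by tile with bilinear blending between tile mappings; it is
the standard preprocessing step for panoramic-radiograph crops.  The
augmentation applies identical rigid transforms (small rotations, optional
horizontal flips) to an image and both of its masks, reproducibly from a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

from . import annotations as anno
from .errors import ImageFormatError
from .geometry import Point, rotate_image, rotate_region


@dataclass
class AugmentationPolicy:
    """Seeded policy for rigid augmentation of tooth crops."""

    max_rotation_deg: float = 15.0
    allow_horizontal_flip: bool = True
    n_variants: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


def clahe_enhance(
    image: np.ndarray,
    clip_limit: float = 0.02,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast limited adaptive histogram equalization.

    ``clip_limit`` is the fractional clipping threshold in [0, 1] (1 leaves
    the per-tile histograms unclipped); ``tiles`` is the tile grid.  The
    output preserves the input dtype and value range.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ImageFormatError("CLAHE expects a single-channel image")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    h, w = image.shape
    kernel = (max(1, int(np.ceil(h / tiles[0]))), max(1, int(np.ceil(w / tiles[1]))))
    if np.ptp(image) == 0:
        # no contrast to enhance; equalization is constant-preserving
        return image.copy()
    out = exposure.equalize_adapthist(image, kernel_size=kernel, clip_limit=clip_limit)
    if np.issubdtype(image.dtype, np.integer):
        lo = float(image.min())
        hi = float(image.max())
        return np.rint(out * (hi - lo) + lo).astype(image.dtype)
    return out.astype(image.dtype, copy=False)


def augment_pair(
    annotation: anno.ToothAnnotation,
    policy: AugmentationPolicy,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Generate rigidly transformed (image, apical mask, coronal mask) triples.

    Each variant draws one rotation uniformly in ±max_rotation_deg and, when
    flips are allowed, applies a horizontal flip with probability 1/2; the
    image and both masks receive the identical transform.
    """
    rng = np.random.default_rng(policy.seed)
    apical, coronal = anno.annotation_masks(annotation)
    image = np.asarray(annotation.image)
    h, w = image.shape
    center = Point((h - 1) / 2.0, (w - 1) / 2.0)
    out = []
    for _ in range(policy.n_variants):
        angle = float(rng.uniform(-policy.max_rotation_deg, policy.max_rotation_deg))
        flip = bool(policy.allow_horizontal_flip and rng.random() < 0.5)
        img_v = rotate_image(image, angle, center)
        ap_v = rotate_region(apical, angle, center)
        co_v = rotate_region(coronal, angle, center)
        if flip:
            img_v = img_v[:, ::-1].copy()
            ap_v = ap_v[:, ::-1].copy()
            co_v = co_v[:, ::-1].copy()
        out.append((img_v, ap_v, co_v))
    return out
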