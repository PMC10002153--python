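"""Overlay rendering: masks, landmarks, and the a/b/c segments.

The point of the overlays is explicability: an expert looking at the tool's
output must be able to verify visually where the masks were, where the
landmarks were placed, and which segments were measured, before trusting
the I3M score.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw

from .evalstats import render_confusion_map  # noqa: F401  (re-exported)
from .geometry import AlignedToothMasks
from .tda import Measurement

APICAL_TINT = (70, 130, 255)
CORONAL_TINT = (255, 210, 60)
SEGMENT_COLORS = {"a": (255, 60, 60), "b": (60, 200, 90), "c": (80, 170, 255)}


def _to_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.max() > 0:
        img = img / img.max() * 255.0
    return np.repeat(img.astype(np.uint8)[..., None], 3, axis=2)


def render_overlay(
    image: np.ndarray,
    aligned: AlignedToothMasks,
    measurement: Measurement | None = None,
    mask_alpha: float = 0.35,
) -> np.ndarray:
    """RGB uint8 overlay of the aligned masks and measurement landmarks.

    The a and b segments join the apex-flank landmark pairs; the c segment
    joins the highest and lowest point of the aligned tooth.
    """
    rgb = _to_rgb(image).astype(float)
    for mask, tint in ((aligned.apical, APICAL_TINT), (aligned.coronal, CORONAL_TINT)):
        rgb[mask] = (1 - mask_alpha) * rgb[mask] + mask_alpha * np.array(tint)
    img = Image.fromarray(rgb.astype(np.uint8))
    draw = ImageDraw.Draw(img)
    if measurement is not None:
        lm = measurement.landmarks
        pairs = []
        if "a_left" in lm and "a_right" in lm:
            pairs = [("a", lm["a_left"], lm["a_right"]), ("b", lm["b_left"], lm["b_right"])]
        elif "coronal_left" in lm:
            pairs = [
                ("a", lm["coronal_left"], lm["apical_left"]),
                ("b", lm["coronal_right"], lm["apical_right"]),
            ]
        if "highest" in lm and "lowest" in lm:
            pairs.append(("c", lm["highest"], lm["lowest"]))
        for name, p, q in pairs:
            draw.line(
                [(p.col, p.row), (q.col, q.row)], fill=SEGMENT_COLORS[name], width=2
            )
        for p in lm.values():
            draw.ellipse(
                [p.col - 2, p.row - 2, p.col + 2, p.row + 2],
                outline=(255, 255, 255),
            )
    return np.asarray(img)
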