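"""Pixel-grid geometry shared by both measurement engines.

Conventions
-----------
All coordinates are ``(row, col)`` with the origin at the top-left pixel
center and the row index increasing *downward* (crown-up radiograph
orientation: the "lowest" point of a structure is the one with the largest
row).  Pixel ``(i, j)`` has its center at the continuous coordinate
``(i, j)``.

Rotations use the convention that a positive angle rotates the offset
``(dr, dc)`` from the rotation center by

    dr' = cos(t) * dr - sin(t) * dc
    dc' = sin(t) * dr + cos(t) * dc

which is self-consistent between :func:`rotate_points` (analytic) and
:func:`rotate_region` / :func:`rotate_image` (resampled via inverse
mapping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateGeometryError,
    EmptyMaskError,
    MaskOverlapError,
    ShapeMismatchError,
)


class Point(NamedTuple):
    """A continuous pixel-center coordinate."""

    row: float
    col: float


@dataclass
class AlignedToothMasks:
    """A two-part segmentation after vertical alignment.

    After alignment the coronal barycenter sits above the apical one on the
    same pixel column (within resampling tolerance), so the tooth height c
    can be read off as a vertical extent.
    """

    apical: np.ndarray
    coronal: np.ndarray
    rotation_deg: float
    rotation_center: Point
    apical_barycenter: Point
    coronal_barycenter: Point


def barycenter(mask: np.ndarray) -> Point:
    """Unweighted centroid of the true pixels of a boolean mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("barycenter of an empty mask is undefined")
    return Point(float(rows.mean()), float(cols.mean()))


def rotate_points(
    points: np.ndarray, angle_deg: float, center: Point
) -> np.ndarray:
    """Rotate an ``(n, 2)`` array of (row, col) points about ``center``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    t = math.radians(angle_deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    return (pts - center) @ rot.T + center


def _rotate_raster(arr: np.ndarray, angle_deg: float, center: Point, order: int) -> np.ndarray:
    # Inverse mapping: each output pixel samples the input at the location
    # obtained by rotating it by -angle about the center.
    h, w = arr.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    src = rotate_points(coords, -angle_deg, center)
    out = ndimage.map_coordinates(
        arr.astype(float), [src[:, 0], src[:, 1]], order=order, cval=0.0
    )
    return out.reshape(h, w)


def rotate_region(mask: np.ndarray, angle_deg: float, center: Point) -> np.ndarray:
    """Rigidly rotate a boolean mask.

    The binary indicator is resampled bilinearly and re-binarized at 0.5,
    which approximates area-coverage resampling: labels stay binary while
    thin structures (root-wall tips) suffer less quantization jitter than
    under nearest-neighbor sampling.  The output grid equals the input
    grid; content rotated out of frame is dropped.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    if angle_deg % 360 == 0:
        return mask.copy()
    return _rotate_raster(mask.astype(float), angle_deg, center, order=1) >= 0.5


def rotate_image(image: np.ndarray, angle_deg: float, center: Point) -> np.ndarray:
    """Rigidly rotate a grayscale image (bilinear resampling)."""
    if angle_deg % 360 == 0:
        return image.copy()
    out = _rotate_raster(image, angle_deg, center, order=1)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(image.dtype)


def alignment_rotation(coronal_bc: Point, apical_bc: Point) -> float:
    """Angle (degrees) mapping the coronal->apical barycenter vector onto the
    downward vertical, crown on top."""
    dr = apical_bc.row - coronal_bc.row
    dc = apical_bc.col - coronal_bc.col
    if dr == 0 and dc == 0:
        raise DegenerateGeometryError("coincident barycenters")
    # R(t) @ (dr, dc) = (|v|, 0): atan2 also supplies the 180-degree flip
    # when the crown starts out below the root.
    return math.degrees(math.atan2(-dc, dr))


def align_vertical(apical: np.ndarray, coronal: np.ndarray) -> AlignedToothMasks:
    """Rotate both masks so the barycenters share a column, crown above root.

    The rotation center is the midpoint of the two barycenters, which keeps
    both regions in frame symmetrically.
    """
    if apical.shape != coronal.shape:
        raise ShapeMismatchError("masks must share a shape")
    if np.any(apical & coronal):
        raise MaskOverlapError("apical and coronal masks overlap")
    bc_ap = barycenter(apical)
    bc_co = barycenter(coronal)
    angle = alignment_rotation(bc_co, bc_ap)
    center = Point((bc_ap.row + bc_co.row) / 2.0, (bc_ap.col + bc_co.col) / 2.0)
    ap_rot = rotate_region(apical, angle, center)
    co_rot = rotate_region(coronal, angle, center)
    return AlignedToothMasks(
        apical=ap_rot,
        coronal=co_rot,
        rotation_deg=angle,
        rotation_center=center,
        apical_barycenter=barycenter(ap_rot),
        coronal_barycenter=barycenter(co_rot),
    )
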