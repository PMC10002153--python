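"""Radii-partition measurement of apex widths and tooth height (TDA).

Pipeline, on a vertically aligned two-part segmentation:

1.  *Canal midlines.*  Row by row, background gaps flanked on both sides by
    apical-mask pixels are root-canal cross sections; the gap midpoint is
    equidistant to the left and right canal walls.  Midpoints are linked
    across rows into per-canal polylines; the polylines that reach the most
    apical rows end at the middles of the open apices.  A tooth without two
    such canals has closed (or invisible) apices and is excluded, exactly as
    such radiographs were excluded from the underlying study design.
2.  *Radii partition.*  Rays cast at 1° steps from every midline point
    label the first boundary pixel they hit as *inner* (pulp–dentine
    interface); boundary pixels never hit first are *outer*
    (tooth–environment interface).  On each side of a canal, the most apical
    pixel where the inner and outer boundaries meet is the wall extremity —
    the flank of the open apex.
3.  *Measurement.*  a and b are the Euclidean distances between the two
    wall extremities of the mesial (left) and distal (right) apex; c is the
    vertical extent of the union of both masks after alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ClosedApexError, DegenerateGeometryError
from .geometry import AlignedToothMasks, Point

__all__ = [
    "CanalMidline",
    "WallPartition",
    "Measurement",
    "canal_midlines",
    "radii_partition",
    "measure_tda",
    "tooth_height",
    "boundary_pixels",
]


@dataclass
class CanalMidline:
    """Equidistant centerline of one root canal, crown side first."""

    points: list[Point]
    widths: list[float]

    @property
    def apex_middle(self) -> Point:
        return self.points[-1]


@dataclass
class WallPartition:
    """One canal wall split into its two interfaces plus the apex flank."""

    inner_boundary: np.ndarray  # boolean grid, pulp–dentine interface
    outer_boundary: np.ndarray  # boolean grid, tooth–environment interface
    extremity: Point


@dataclass
class Measurement:
    """The a, b, c lengths (pixels) with their defining landmarks."""

    a_px: float
    b_px: float
    c_px: float
    method: str
    landmarks: dict[str, Point] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# canal midlines


def despeckle(mask: np.ndarray, min_px: int = 5) -> np.ndarray:
    """Drop connected components smaller than ``min_px`` (8-connectivity).

    Isolated specks from segmentation noise would otherwise split canal
    gaps and masquerade as boundary landmarks.
    """
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def _row_gaps(row_mask: np.ndarray) -> list[tuple[float, float]]:
    """(midpoint_col, width) of every background run flanked by mask pixels."""
    cols = np.nonzero(row_mask)[0]
    if cols.size < 2:
        return []
    gaps = []
    jumps = np.nonzero(np.diff(cols) > 1)[0]
    for j in jumps:
        left, right = cols[j], cols[j + 1]
        gaps.append(((left + right) / 2.0, float(right - left - 1)))
    return gaps


def canal_midlines(
    aligned: AlignedToothMasks,
    max_col_jump: float = 5.0,
    max_row_skip: int = 2,
    reach_tolerance_rows: int | None = None,
    min_rows: int = 4,
) -> list[CanalMidline]:
    """Extract the root-canal centerlines of an aligned tooth.

    Midpoints of flanked background gaps are linked across rows by nearest
    column (tolerating ``max_row_skip`` missing rows, e.g. from resampling
    or segmentation noise).  Only polylines whose terminal row reaches the
    apical mask's lowest rows are canals; if more than two reach, the
    narrower ones are kept (root canals are narrow slits, while the
    inter-radicular space widens apically).
    """
    apical = despeckle(aligned.apical)
    occupied = np.nonzero(apical.any(axis=1))[0]
    if occupied.size == 0:
        raise ClosedApexError("empty apical mask")
    bottom = int(occupied.max())

    # active polyline: dict(points, widths, last_row)
    active: list[dict] = []
    finished: list[dict] = []
    for r in range(int(occupied.min()), bottom + 1):
        gaps = _row_gaps(apical[r])
        still_active, expired = [], []
        for pl in active:
            if r - pl["last_row"] > max_row_skip + 1:
                expired.append(pl)
            else:
                still_active.append(pl)
        finished.extend(expired)
        active = still_active

        used = [False] * len(gaps)
        # match existing polylines to this row's midpoints, nearest column
        # first; a canal's width varies slowly row to row, so a gap whose
        # width is incompatible with the polyline's cannot continue it
        for pl in sorted(active, key=lambda p: -p["last_row"]):
            w_last = pl["widths"][-1]
            best, best_d = None, max_col_jump
            for i, (mid, w) in enumerate(gaps):
                d = abs(mid - pl["points"][-1].col)
                if used[i] or d > best_d:
                    continue
                if abs(w - w_last) > max(4.0, 0.6 * w_last):
                    continue
                best, best_d = i, d
            if best is not None:
                used[best] = True
                mid, w = gaps[best]
                pl["points"].append(Point(float(r), mid))
                pl["widths"].append(w)
                pl["last_row"] = r
        for i, (mid, w) in enumerate(gaps):
            if not used[i]:
                active.append(
                    {"points": [Point(float(r), mid)], "widths": [w], "last_row": r}
                )
    finished.extend(active)

    # a canal is an extended structure: single-row gap artifacts (mask
    # resampling fragments near the tips) are not candidate canals
    finished = [pl for pl in finished if len(pl["points"]) >= min_rows]
    if reach_tolerance_rows is None:
        # the two roots' tips rarely end on the same row (rotation,
        # segmentation error), so "lowest rows" is relative to band height
        span = bottom - int(occupied.min())
        reach_tolerance_rows = max(3, int(round(0.3 * span)))
    reaching = [
        pl for pl in finished if pl["last_row"] >= bottom - reach_tolerance_rows
    ]
    if not reaching:
        raise ClosedApexError("no open canal reaches the apical rows")

    def width_trend(pl: dict) -> float:
        w = pl["widths"]
        k = min(3, len(w))
        return float(np.median(w[-k:]) - np.median(w[:k]))

    # among gaps that reach the apical rows, prefer the ones that narrow
    # apically — an open apex converges toward its tip, while the
    # inter-radicular space widens; resampling can erode a tooth's true
    # bottom row, so raw terminal depth only breaks trend ties
    reaching.sort(key=lambda pl: (width_trend(pl), -pl["last_row"]))
    if len(reaching) > 2:
        reaching = reaching[:2]
    reaching.sort(key=lambda pl: pl["points"][-1].col)
    return [CanalMidline(points=pl["points"], widths=pl["widths"]) for pl in reaching]


# ---------------------------------------------------------------------------
# radii partition


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels 8-adjacent to the background (or the image edge)."""
    interior = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3)), border_value=0
    )
    return mask & ~interior


def _first_hits(
    mask: np.ndarray,
    origin: Point,
    n_angles: int,
    step: float = 0.5,
    max_t: float | None = None,
) -> np.ndarray:
    """Boolean grid of the first mask pixel hit by each of n_angles rays."""
    h, w = mask.shape
    angles = np.arange(n_angles) * (2 * math.pi / n_angles)
    dirs = np.stack([np.sin(angles), np.cos(angles)], axis=1)  # (row, col) steps
    if max_t is None:
        max_t = math.hypot(h, w)
    ts = np.arange(step, max_t, step)
    # positions: (n_angles, n_steps, 2)
    pos = origin + ts[None, :, None] * dirs[:, None, :]
    rr = np.rint(pos[..., 0]).astype(int)
    cc = np.rint(pos[..., 1]).astype(int)
    inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    hit = np.zeros(rr.shape, dtype=bool)
    hit[inside] = mask[rr[inside], cc[inside]]
    hit &= inside
    out = np.zeros_like(mask, dtype=bool)
    first = hit.argmax(axis=1)  # first True along each ray (0 if none)
    rays = np.nonzero(hit.any(axis=1))[0]
    out[rr[rays, first[rays]], cc[rays, first[rays]]] = True
    return out


def radii_partition(
    apical: np.ndarray,
    midline: CanalMidline,
    angle_step_deg: float = 1.0,
) -> tuple[WallPartition, WallPartition]:
    """Partition the apical boundary into inner/outer interfaces and locate
    the two apex flanks of one canal.

    Returns the (left, right) wall partitions relative to the canal midline.
    """
    if not midline.points:
        raise DegenerateGeometryError("empty midline")
    apical = despeckle(apical)
    if not apical.any():
        raise DegenerateGeometryError("empty apical mask")
    boundary = boundary_pixels(apical)
    n_angles = int(round(360 / angle_step_deg))
    # rays never need to march past the far corner of the mask bounding box
    rs, cs = np.nonzero(apical)
    r0, r1 = float(rs.min()), float(rs.max())
    c0, c1 = float(cs.min()), float(cs.max())
    inner = np.zeros_like(apical, dtype=bool)
    for p in midline.points:
        reach = max(
            math.hypot(p.row - r, p.col - c)
            for r in (r0, r1)
            for c in (c0, c1)
        )
        inner |= _first_hits(apical, p, n_angles, max_t=reach + 2.0)
    inner &= boundary
    if not inner.any():
        raise DegenerateGeometryError("radii partition produced an empty inner set")
    outer = boundary & ~inner
    if not outer.any():
        raise DegenerateGeometryError("radii partition produced an empty outer set")

    # the apex flank is where the canal-facing (inner) boundary ends: its
    # most apical pixels.  Requiring explicit 8-adjacency to an outer pixel
    # breaks down when segmentation error erodes the tip row (the outer set
    # vanishes locally), so every inner pixel is a candidate and the
    # most-apical / nearest-to-terminus rule locates the flank.
    trans_r, trans_c = np.nonzero(inner)
    apex = midline.apex_middle

    def side_extremity(on_side: np.ndarray) -> Point:
        if not on_side.any():
            raise DegenerateGeometryError("no inner/outer transition on one side")
        rs, cs = trans_r[on_side], trans_c[on_side]
        top = rs.max()
        near = rs >= top - 2  # near-ties from resampling jitter
        d2 = (rs[near] - apex.row) ** 2 + (cs[near] - apex.col) ** 2
        k = int(np.argmin(d2))
        r, c = float(rs[near][k]), float(cs[near][k])
        # the pulp–dentine interface lies between this wall pixel's center
        # and the canal background: half-pixel correction toward the canal
        d = math.hypot(r - apex.row, c - apex.col)
        if d > 0:
            r += 0.5 * (apex.row - r) / d
            c += 0.5 * (apex.col - c) / d
        return Point(r, c)

    left_ext = side_extremity(trans_c < apex.col)
    right_ext = side_extremity(trans_c > apex.col)
    left = WallPartition(inner_boundary=inner, outer_boundary=outer, extremity=left_ext)
    right = WallPartition(inner_boundary=inner, outer_boundary=outer, extremity=right_ext)
    return left, right


# ---------------------------------------------------------------------------
# measurement


def tooth_height(aligned: AlignedToothMasks) -> float:
    """Vertical extent (max row − min row) of the aligned two-part mask."""
    union = aligned.apical | aligned.coronal
    rows = np.nonzero(union.any(axis=1))[0]
    return float(rows.max() - rows.min())


def measure_tda(aligned: AlignedToothMasks) -> Measurement:
    """Measure a, b, c on an aligned tooth with the radii-partition method."""
    midlines = canal_midlines(aligned)
    if len(midlines) < 2:
        raise ClosedApexError(
            f"found {len(midlines)} open canal(s); two apices are required"
        )
    mesial, distal = midlines[0], midlines[1]
    m_left, m_right = radii_partition(aligned.apical, mesial)
    d_left, d_right = radii_partition(aligned.apical, distal)
    a = math.dist(m_left.extremity, m_right.extremity)
    b = math.dist(d_left.extremity, d_right.extremity)
    c = tooth_height(aligned)
    union = aligned.apical | aligned.coronal
    rows, cols = np.nonzero(union)
    top_i = int(np.argmin(rows))
    bot_i = int(np.argmax(rows))
    landmarks = {
        "a_left": m_left.extremity,
        "a_right": m_right.extremity,
        "b_left": d_left.extremity,
        "b_right": d_right.extremity,
        "mesial_apex_middle": mesial.apex_middle,
        "distal_apex_middle": distal.apex_middle,
        "highest": Point(float(rows[top_i]), float(cols[top_i])),
        "lowest": Point(float(rows[bot_i]), float(cols[bot_i])),
    }
    return Measurement(a_px=a, b_px=b, c_px=c, method="TDA", landmarks=landmarks)
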