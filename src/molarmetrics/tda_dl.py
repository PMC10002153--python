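"""Skeleton-endpoint measurement of apex widths (TDA-DL geometry).

This variant replaces the radii partition by an inverted-U centerline of
the apical band: the band is skeletonized, spurs are pruned, and the two
most apical skeleton tips (one on each side of the band) are the *apical
limit points*.  The *coronal limit points* are the lowest coronal-mask
pixels on each side of the vertical line through the barycenters.  The a
and b widths are then the coronal-to-apical limit-point distances on the
left and right side; c is shared with the radii-partition method.

The original procedure infers the U-shape centerline with a trained
network; here the default backend is deterministic medial-axis
skeletonization, and any callable mapping an apical mask to five ordered
(row, col) control points can be plugged in instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import DegenerateGeometryError
from .geometry import AlignedToothMasks, Point
from .tda import Measurement, tooth_height

__all__ = [
    "UShapeSkeleton",
    "apical_skeleton",
    "coronal_limit_points",
    "measure_tda_dl",
    "SkeletonBackend",
]

#: backend contract: apical mask -> 5 ordered (row, col) control points,
#: left end first, right end last
SkeletonBackend = Callable[[np.ndarray], Sequence[tuple[float, float]]]


@dataclass
class UShapeSkeleton:
    """Medial polyline of the apical band with its five control points."""

    polyline: list[Point]
    control_points: list[Point]  # [left end, 3 interior, right end]

    @property
    def left_end(self) -> Point:
        return self.control_points[0]

    @property
    def right_end(self) -> Point:
        return self.control_points[-1]


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rr, cc = np.nonzero(skel)
    pixels = set(zip(rr.tolist(), cc.tolist()))
    for r, c in pixels:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if q in pixels:
                    g.add_edge((r, c), q, weight=math.hypot(dr, dc))
    return g


def _prune_spurs(g: nx.Graph, min_len: float) -> None:
    """Iteratively remove terminal branches shorter than ``min_len`` pixels."""
    changed = True
    while changed and g.number_of_nodes() > 2:
        changed = False
        tips = [n for n in g.nodes if g.degree(n) == 1]
        for tip in tips:
            if tip not in g:
                continue
            # walk from the tip to the first branch point
            path = [tip]
            length = 0.0
            cur, prev = tip, None
            while g.degree(cur) <= 2:
                nxt = [n for n in g.neighbors(cur) if n != prev]
                if not nxt:
                    break
                length += g.edges[cur, nxt[0]]["weight"]
                prev, cur = cur, nxt[0]
                if g.degree(cur) > 2:
                    break
                path.append(cur)
            if g.degree(cur) > 2 and length < min_len:
                g.remove_nodes_from(path)
                changed = True


def apical_skeleton(
    apical: np.ndarray,
    spur_px: float = 5.0,
) -> UShapeSkeleton:
    """Inverted-U medial centerline of the apical band.

    The morphological skeleton is pruned of spurs shorter than ``spur_px``,
    the two most apical remaining tips (one on each side of the band's
    column median, outermost among near-ties) become the end points, and the
    polyline is the shortest skeleton path between them.  Three interior
    control points are placed at arc-length quartiles; they are reported for
    overlays only.
    """
    from .tda import despeckle

    apical = despeckle(apical)
    if not apical.any():
        raise DegenerateGeometryError("empty apical mask")
    skel = skeletonize(apical)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() < 2:
        raise DegenerateGeometryError("no band-like skeleton")
    _prune_spurs(g, spur_px)

    nodes = np.array(list(g.nodes))
    # band-likeness: an inverted U descends well below its own thickness;
    # a blob (solid disk) has a stubby skeleton instead
    thickness = float(ndimage.distance_transform_edt(apical).max())
    row_span = float(nodes[:, 0].max() - nodes[:, 0].min())
    if row_span < 1.5 * thickness:
        raise DegenerateGeometryError("apical mask is not band-like")

    rr, cc = np.nonzero(apical)
    median_col = float(np.median(cc))
    top_row = nodes[:, 0].min()
    mid_row = (top_row + nodes[:, 0].max()) / 2.0

    # geodesic distances from the band's top center: the fallback endpoint
    # criterion when skeletonization closes a branch into a loop (no tip)
    top_band = nodes[nodes[:, 0] <= top_row + 2]
    center_idx = int(np.argmin(np.abs(top_band[:, 1] - median_col)))
    center_node = tuple(int(v) for v in top_band[center_idx])
    dist = nx.single_source_dijkstra_path_length(g, center_node, weight="weight")
    tips = [n for n in g.nodes if g.degree(n) == 1 and n in dist]

    def end_point(on_left: bool) -> tuple[int, int]:
        if on_left:
            side = lambda n: n[1] < median_col
        else:
            side = lambda n: n[1] >= median_col
        # an end of the inverted U is the node geodesically farthest from the
        # top center on its side: descending branches accumulate distance, so
        # this lands on the outermost wall tip and stays robust when a branch
        # retracts unevenly or closes into a loop during skeletonization
        side_nodes = [n for n in dist if side(n)]
        if not side_nodes or not any(n[0] >= mid_row for n in side_nodes):
            raise DegenerateGeometryError("skeleton does not descend on one side")
        return max(side_nodes, key=lambda n: dist[n])

    left_end = end_point(True)
    right_end = end_point(False)
    path = nx.shortest_path(g, left_end, right_end, weight="weight")

    polyline = [Point(float(r), float(c)) for r, c in path]

    # skeleton tips retract from the true medial end of a branch by a
    # variable amount (half thickness plus discretization); extend each end
    # along its terminal direction to the wall end minus the local radius
    dt = ndimage.distance_transform_edt(apical)

    branch_nodes = {n for n in g.nodes if g.degree(n) > 2}

    def refine_end(pts: list[Point]) -> Point:
        tip = pts[0]
        # the terminal direction must be fit within the tip's own branch:
        # nodes past the first junction belong to the bridge, not the wall
        stop = min(8, len(pts))
        for i, p in enumerate(pts[:stop]):
            if (int(p.row), int(p.col)) in branch_nodes and i >= 2:
                stop = i + 1
                break
        seg = np.asarray(pts[:stop], dtype=float)
        if len(seg) < 2:
            return tip
        # terminal direction from a principal-component fit of the last
        # few path nodes (a two-point difference is too jittery on a
        # discrete skeleton)
        centered = seg - seg.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d = vt[0]
        toward_tip = np.array([tip.row, tip.col]) - seg[-1]
        if float(d @ toward_tip) < 0:
            d = -d
        dr, dc = float(d[0]), float(d[1])
        # wall half-thickness read a few steps up the branch, where the
        # medial radius is not yet eroded by the branch end
        back = seg[-1]
        radius = float(dt[int(round(back[0])), int(round(back[1]))])
        h, w = apical.shape
        e = 0.0
        while e < 3.0 * radius + 3.0:
            r = tip.row + (e + 0.25) * dr
            c = tip.col + (e + 0.25) * dc
            if not (0 <= round(r) < h and 0 <= round(c) < w):
                break
            if not apical[int(round(r)), int(round(c))]:
                break
            e += 0.25
        shift = max(0.0, e - radius)
        return Point(tip.row + shift * dr, tip.col + shift * dc)

    if len(polyline) >= 2:
        polyline[0] = refine_end(polyline)
        polyline[-1] = refine_end(polyline[::-1])
    # arc length along the path
    seg = [0.0]
    for p, q in zip(polyline[:-1], polyline[1:]):
        seg.append(seg[-1] + math.dist(p, q))
    total = seg[-1]
    controls = [polyline[0]]
    for frac in (0.25, 0.5, 0.75):
        k = int(np.searchsorted(seg, frac * total))
        controls.append(polyline[min(k, len(polyline) - 1)])
    controls.append(polyline[-1])
    return UShapeSkeleton(polyline=polyline, control_points=controls)


def coronal_limit_points(
    coronal: np.ndarray, axis_col: float
) -> tuple[Point, Point]:
    """Lowest coronal pixels on each side of the vertical line ``axis_col``.

    Ties within a side are broken toward the smallest |col − axis_col|.
    """
    rr, cc = np.nonzero(coronal)
    if rr.size == 0:
        raise DegenerateGeometryError("empty coronal mask")

    def lowest(side: np.ndarray) -> Point:
        if not side.any():
            raise DegenerateGeometryError("no coronal pixels on one side of the axis")
        rs, cs = rr[side], cc[side]
        max_row = rs.max()
        at = rs == max_row
        k = int(np.argmin(np.abs(cs[at] - axis_col)))
        return Point(float(max_row), float(cs[at][k]))

    return lowest(cc < axis_col), lowest(cc > axis_col)


def _default_backend(spur_px: float) -> SkeletonBackend:
    def backend(apical: np.ndarray) -> Sequence[tuple[float, float]]:
        return [tuple(p) for p in apical_skeleton(apical, spur_px=spur_px).control_points]

    return backend


def measure_tda_dl(
    aligned: AlignedToothMasks,
    skeleton_backend: SkeletonBackend | None = None,
    spur_px: float = 5.0,
) -> Measurement:
    """Measure a, b, c on an aligned tooth with the skeleton-endpoint method."""
    backend = skeleton_backend or _default_backend(spur_px)
    controls = [Point(float(r), float(c)) for r, c in backend(aligned.apical)]
    if len(controls) != 5:
        raise DegenerateGeometryError(
            f"skeleton backend returned {len(controls)} control points, expected 5"
        )
    apical_left, apical_right = controls[0], controls[-1]
    axis_col = (aligned.apical_barycenter.col + aligned.coronal_barycenter.col) / 2.0
    coronal_left, coronal_right = coronal_limit_points(aligned.coronal, axis_col)
    a = math.dist(coronal_left, apical_left)
    b = math.dist(coronal_right, apical_right)
    c = tooth_height(aligned)
    union = aligned.apical | aligned.coronal
    rows, cols = np.nonzero(union)
    top_i = int(np.argmin(rows))
    bot_i = int(np.argmax(rows))
    landmarks = {
        "highest": Point(float(rows[top_i]), float(cols[top_i])),
        "lowest": Point(float(rows[bot_i]), float(cols[bot_i])),
        "coronal_left": coronal_left,
        "coronal_right": coronal_right,
        "apical_left": apical_left,
        "apical_right": apical_right,
        "control_1": controls[1],
        "control_2": controls[2],
        "control_3": controls[3],
    }
    return Measurement(a_px=a, b_px=b, c_px=c, method="TDA_DL", landmarks=landmarks)
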