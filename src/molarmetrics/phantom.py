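"""Synthetic third-molar phantoms with analytic ground truth.

No radiograph data ship with this package, so every pipeline stage is
exercised on stylized tooth phantoms built from explicit polygons:

* a **coronal** region = an elliptical crown cap continued by two
  root-body prongs, whose two lowest points ("cusps" in the annotation
  sense: the most cervical mineralized points flanking the canals) sit on
  the inner flank of each root canal, a small cervical gap above the
  apical band;
* an **apical** region = a short band of four trapezoidal root walls (two
  per root, converging downward) joined by a bridge, leaving two open
  canals whose openings at the bottom have the target widths a and b.

All landmark coordinates (wall tips, cusps, top/bottom extremes, skeleton
end points) are constructed analytically, rotated together with the scene,
and stored, so recovery of a, b, c and of the I3M decision can be tested
against exact ground truth.  The rendering (two gray levels plus Gaussian
noise) is deliberately schematic: the measurement contract is geometric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Point as ShPoint
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .annotations import ToothAnnotation, rasterize_geometry
from .errors import PhantomGeometryError
from .geometry import Point
from .scoring import DEFAULT_THRESHOLD, classify_age, compute_i3m
from .tda import Measurement

__all__ = [
    "PhantomSpec",
    "PhantomTooth",
    "generate_phantom",
    "generate_cohort",
    "degrade_mask",
    "DEFAULT_COHORT_RANGES",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom tooth (all lengths in pixels)."""

    image_size: int = 256
    a_px: float = 10.0  # mesial apex width
    b_px: float = 12.0  # distal apex width
    c_px: float = 150.0  # tooth height
    wall_thickness_px: float = 6.0
    crown_width_px: float = 120.0
    cervical_gap_px: float = 1.0
    rotation_deg: float = 0.0
    noise_sd: float = 6.0
    seed: int = 0
    # secondary geometry (defaults emulate a late-developing mandibular molar)
    apical_band_px: float = 12.0  # height of the apical wall band
    taper_px: float = 3.0  # canal half-width excess at the band top
    bridge_px: float = 4.0  # inter-wall bridge height at the band top
    crown_height_frac: float = 0.30  # crown cap height as a fraction of c


@dataclass
class PhantomTooth:
    """A generated phantom with its masks and analytic truth."""

    image: np.ndarray
    apical_mask: np.ndarray
    coronal_mask: np.ndarray
    truth: Measurement  # radii-partition sense (apex widths)
    truth_dl: Measurement  # skeleton-endpoint sense (limit-point gaps)
    truth_decision: str
    spec: PhantomSpec
    landmarks: dict[str, Point] = field(default_factory=dict)
    apical_geom: object = None  # shapely polygons, for annotation export
    coronal_geom: object = None
    canal_centers: tuple[float, float] = (0.0, 0.0)  # columns, pre-rotation


def _rect(c0: float, c1: float, r0: float, r1: float) -> Polygon:
    return Polygon([(c0, r0), (c1, r0), (c1, r1), (c0, r1)])


def _wall(c_top_in: float, c_bot_in: float, r0: float, r1: float, t: float, sign: int) -> Polygon:
    """Trapezoidal wall: inner edge from (r0, c_top_in) to (r1, c_bot_in),
    thickness t toward sign (−1 = leftward, +1 = rightward)."""
    return Polygon(
        [
            (c_top_in, r0),
            (c_top_in + sign * t, r0),
            (c_bot_in + sign * t, r1),
            (c_bot_in, r1),
        ]
    )


def _ellipse(cx: float, cy: float, rx: float, ry: float, n: int = 72) -> Polygon:
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + rx * np.cos(ang), cy + ry * np.sin(ang)]))


def generate_phantom(spec: PhantomSpec) -> PhantomTooth:
    """Build one phantom tooth from its spec (bit-reproducible)."""
    s = spec
    S = s.image_size
    if not (0 < s.a_px < s.c_px and 0 < s.b_px < s.c_px and s.c_px <= S):
        raise PhantomGeometryError("need 0 < a, b < c <= image_size")
    if s.wall_thickness_px < 2:
        raise PhantomGeometryError("wall thickness must be >= 2 px")
    t = s.wall_thickness_px
    col0 = (S - 1) / 2.0
    r_top = (S - 1) / 2.0 - s.c_px / 2.0
    r_bot = r_top + s.c_px
    r_btop = r_bot - s.apical_band_px  # top of the apical band
    r_cusp = r_btop - s.cervical_gap_px  # lowest coronal row (cusp tips)

    sep = s.crown_width_px * 0.5  # distance between the two root centers
    mesial = col0 - sep / 2.0
    distal = col0 + sep / 2.0

    # root half-extents at the band top (canal half-width + taper + wall)
    half_m = s.a_px / 2.0 + s.taper_px + t
    half_d = s.b_px / 2.0 + s.taper_px + t
    inter_gap = (distal - half_d) - (mesial + half_m)
    if inter_gap < 3:
        raise PhantomGeometryError("root walls overlap between the roots")
    if mesial - half_m < 1 or distal + half_d > S - 2:
        raise PhantomGeometryError("root walls leave the frame")
    if r_cusp - 6 <= r_top + s.crown_height_frac * s.c_px:
        raise PhantomGeometryError("tooth too short for crown + prongs + band")

    # --- apical band: four converging walls plus a bridge ------------------
    walls = []
    for center, width in ((mesial, s.a_px), (distal, s.b_px)):
        half_tip = width / 2.0
        half_top = half_tip + s.taper_px
        walls.append(_wall(center - half_top, center - half_tip, r_btop, r_bot, t, -1))
        walls.append(_wall(center + half_top, center + half_tip, r_btop, r_bot, t, +1))
    bridge = _rect(mesial - half_m, distal + half_d, r_btop, r_btop + s.bridge_px)
    apical_geom = unary_union(walls + [bridge])

    # --- coronal region: crown cap + prongs + cusp wedges ------------------
    crown_h = s.crown_height_frac * s.c_px
    crown = _ellipse(col0, r_top + crown_h / 2.0, s.crown_width_px / 2.0, crown_h / 2.0)
    # make the analytic top point exact
    crown = unary_union(
        [crown, _rect(col0 - s.crown_width_px / 6.0, col0 + s.crown_width_px / 6.0,
                      r_top, r_top + crown_h / 2.0)]
    )
    r_prong_top = r_top + crown_h / 2.0
    r_prong_bot = r_cusp - 3.0
    prongs = [
        _rect(mesial - half_m, mesial + half_m, r_prong_top, r_prong_bot),
        _rect(distal - half_d, distal + half_d, r_prong_top, r_prong_bot),
    ]
    # cusp wedges: lowest coronal points, one per side, on the canal's inner
    # flank (the most cervical mineralized point next to each canal)
    cusp_m = Point(r_cusp, mesial + s.a_px / 2.0)
    cusp_d = Point(r_cusp, distal - s.b_px / 2.0)
    wedges = [
        Polygon([(cusp_m.col - 4, r_prong_bot), (cusp_m.col + 4, r_prong_bot),
                 (cusp_m.col, cusp_m.row)]),
        Polygon([(cusp_d.col - 4, r_prong_bot), (cusp_d.col + 4, r_prong_bot),
                 (cusp_d.col, cusp_d.row)]),
    ]
    coronal_geom = unary_union([crown] + prongs + wedges)

    # --- analytic landmarks ------------------------------------------------
    landmarks = {
        "top": Point(r_top, col0),
        "bottom": Point(r_bot, col0),
        "a_left": Point(r_bot, mesial - s.a_px / 2.0),
        "a_right": Point(r_bot, mesial + s.a_px / 2.0),
        "b_left": Point(r_bot, distal - s.b_px / 2.0),
        "b_right": Point(r_bot, distal + s.b_px / 2.0),
        "mesial_apex_middle": Point(r_bot, mesial),
        "distal_apex_middle": Point(r_bot, distal),
        "cusp_left": cusp_m,
        "cusp_right": cusp_d,
        # medial-axis tips of the outer walls (mid-thickness, half a
        # thickness above the tip row)
        "dl_apical_left": Point(r_bot - t / 2.0, mesial - s.a_px / 2.0 - t / 2.0),
        "dl_apical_right": Point(r_bot - t / 2.0, distal + s.b_px / 2.0 + t / 2.0),
    }

    # --- scene rotation ----------------------------------------------------
    if s.rotation_deg % 360 != 0:
        origin = (col0, (S - 1) / 2.0)  # shapely (x, y) = (col, row)
        apical_geom = affinity.rotate(apical_geom, s.rotation_deg, origin=origin)
        coronal_geom = affinity.rotate(coronal_geom, s.rotation_deg, origin=origin)
        landmarks = {
            k: _rotate_landmark(p, s.rotation_deg, origin) for k, p in landmarks.items()
        }

    apical_mask = rasterize_geometry(apical_geom, (S, S))
    coronal_mask = rasterize_geometry(coronal_geom, (S, S))
    if not apical_mask.any() or not coronal_mask.any():
        raise PhantomGeometryError("mask rasterized to empty")
    if np.any(apical_mask & coronal_mask):
        raise PhantomGeometryError("apical and coronal masks overlap")

    # --- truth measurements -------------------------------------------------
    truth = Measurement(
        a_px=math.dist(landmarks["a_left"], landmarks["a_right"]),
        b_px=math.dist(landmarks["b_left"], landmarks["b_right"]),
        c_px=math.dist(landmarks["top"], landmarks["bottom"]),
        method="TRUTH",
        landmarks=landmarks,
    )
    truth_dl = Measurement(
        a_px=math.dist(landmarks["cusp_left"], landmarks["dl_apical_left"]),
        b_px=math.dist(landmarks["cusp_right"], landmarks["dl_apical_right"]),
        c_px=truth.c_px,
        method="TRUTH_DL",
        landmarks=landmarks,
    )
    truth_decision = classify_age(compute_i3m(truth), DEFAULT_THRESHOLD)

    # --- rendering ----------------------------------------------------------
    rng = np.random.default_rng(s.seed)
    image = np.full((S, S), 30.0)
    image[coronal_mask] = 185.0
    image[apical_mask] = 160.0
    if s.noise_sd > 0:
        image += rng.normal(0.0, s.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return PhantomTooth(
        image=image,
        apical_mask=apical_mask,
        coronal_mask=coronal_mask,
        truth=truth,
        truth_dl=truth_dl,
        truth_decision=truth_decision,
        spec=s,
        landmarks=landmarks,
        apical_geom=apical_geom,
        coronal_geom=coronal_geom,
        canal_centers=(mesial, distal),
    )


def _rotate_landmark(p: Point, angle_deg: float, origin: tuple[float, float]) -> Point:
    q = affinity.rotate(ShPoint(p.col, p.row), angle_deg, origin=origin)
    return Point(float(q.y), float(q.x))


#: study-condition parameter ranges for cohort simulation
DEFAULT_COHORT_RANGES = {
    "a_px": (6.0, 20.0),
    "b_px": (6.0, 20.0),
    "c_px": (120.0, 200.0),
    "rotation_deg": (-20.0, 20.0),
    "crown_width_px": (100.0, 130.0),
}


def generate_cohort(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[PhantomTooth]:
    """Draw ``n`` phantoms with parameters uniform over ``ranges``.

    Unlisted parameters keep their :class:`PhantomSpec` defaults.  A draw
    that violates the geometric constraints is resampled up to 10 times.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES if ranges is None else ranges)
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        last_err: Exception | None = None
        for _attempt in range(10):
            params = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
            spec = replace(
                PhantomSpec(), seed=int(rng.integers(0, 2**31 - 1)), **params
            )
            try:
                cohort.append(generate_phantom(spec))
                last_err = None
                break
            except PhantomGeometryError as err:
                last_err = err
        if last_err is not None:
            raise last_err
    return cohort


def phantom_annotation(tooth: PhantomTooth, source_id: str = "") -> ToothAnnotation:
    """Express a phantom as a labelme-style annotation (polygon vertices)."""
    def coords(geom) -> list[tuple[float, float]]:
        poly = max(getattr(geom, "geoms", [geom]), key=lambda g: g.area)
        return [(float(x), float(y)) for x, y in poly.exterior.coords[:-1]]

    i3m = compute_i3m(tooth.truth)
    return ToothAnnotation(
        image=tooth.image,
        apical_polygon=coords(tooth.apical_geom),
        coronal_polygon=coords(tooth.coronal_geom),
        source_id=source_id,
        expert_i3m=float(i3m),
        expert_decision=tooth.truth_decision,
    )


def write_phantom_dataset(cohort: list[PhantomTooth], out_dir) -> "pd.DataFrame":
    """Write a cohort as PNG + labelme JSON + a truth CSV table.

    Returns the truth table (source_id, a_px, b_px, c_px, i3m, decision).
    """
    import pandas as pd
    from pathlib import Path

    from .annotations import write_labelme

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tooth in enumerate(cohort):
        sid = f"phantom_{i:04d}"
        ann = phantom_annotation(tooth, source_id=f"{sid}.png")
        from PIL import Image

        Image.fromarray(tooth.image).save(out_dir / f"{sid}.png")
        write_labelme(ann, out_dir / f"{sid}.json", embed_image=False)
        i3m = compute_i3m(tooth.truth)
        rows.append(
            {
                "source_id": sid,
                "a_px": tooth.truth.a_px,
                "b_px": tooth.truth.b_px,
                "c_px": tooth.truth.c_px,
                "i3m": i3m,
                "decision": tooth.truth_decision,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "truth.csv", index=False)
    return table


def degrade_mask(mask: np.ndarray, severity: float, seed: int = 0) -> np.ndarray:
    """Simulate segmentation error as a smooth boundary displacement.

    The mask boundary is moved locally by a spatially correlated Gaussian
    field (the dominant error mode of CNN segmentations: the contour is
    placed a few pixels off, coherently along the edge), plus sparse
    speckle near the region.  severity 0 is the identity; the expected IoU
    against the input decreases monotonically with severity.
    """
    if not mask.any():
        raise ValueError("cannot degrade an empty mask")
    if severity <= 0:
        return mask.copy()
    severity = min(float(severity), 1.0)
    rng = np.random.default_rng(seed)
    # signed distance to the boundary, positive inside
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    sd = np.where(mask, d_in - 0.5, 0.5 - d_out)
    field = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=6.0)
    field /= max(field.std(), 1e-12)
    # tanh bounds the local shift to ±amplitude, and the local amplitude
    # scales with structure thickness: segmentation error displaces the
    # contour of a large region by more pixels than it can displace a thin
    # wall without destroying it (thin structures are displaced, not
    # obliterated)
    thickness = ndimage.gaussian_filter(d_in, sigma=6.0)
    scale = np.clip(thickness / 3.0, 0.3, 1.0)
    amplitude = 4.0 * severity
    out = sd > amplitude * np.tanh(field) * scale
    # sparse speckle in a loose neighborhood of the region
    neigh = ndimage.binary_dilation(mask, iterations=6)
    flip = (rng.random(mask.shape) < 0.003 * severity) & neigh
    out ^= flip
    return out
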