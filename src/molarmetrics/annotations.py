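"""Reading and writing two-part tooth annotations.

The on-disk format is the labelme JSON dialect: a ``shapes`` list of
labeled polygons (``points`` are ``[x, y]`` = ``[col, row]`` image
coordinates), the raster either embedded base64 (``imageData``) or referenced
by ``imagePath``, plus ``imageHeight`` / ``imageWidth``.

One annotation holds exactly one *apical* and one *coronal* polygon — the
two-part instance segmentation of the mineralized tissue of a mandibular
third molar — and optionally the expert's I3M value and minor/adult call
for later comparison.
"""

from __future__ import annotations

import base64
import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon

from .errors import AnnotationSchemaError, DegenerateGeometryError, ImageFormatError

#: accepted label spellings, all case-insensitive
DEFAULT_LABEL_ALIASES = {
    "apical": ("apical", "apex", "root"),
    "coronal": ("coronal", "crown"),
}


@dataclass
class ToothAnnotation:
    """A 256x256-style tooth crop with its two polygon masks."""

    image: np.ndarray
    apical_polygon: list[tuple[float, float]]  # (col, row) vertices
    coronal_polygon: list[tuple[float, float]]
    source_id: str = ""
    side: str = "unknown"  # {left, right, unknown}
    expert_i3m: float | None = None
    expert_decision: str | None = None


def _match_label(label: str, aliases: dict[str, tuple[str, ...]]) -> str | None:
    low = label.strip().lower()
    for canonical, names in aliases.items():
        if low in names:
            return canonical
    return None


def _decode_image(doc: dict, base_dir: Path | None) -> np.ndarray:
    if doc.get("imageData"):
        raw = base64.b64decode(doc["imageData"])
        img = Image.open(io.BytesIO(raw))
    elif doc.get("imagePath") and base_dir is not None:
        img = Image.open(base_dir / doc["imagePath"])
    else:
        h = int(doc.get("imageHeight", 256))
        w = int(doc.get("imageWidth", 256))
        return np.zeros((h, w), dtype=np.uint8)
    if img.mode not in ("L", "I", "I;16", "F"):
        img = img.convert("L")
    return np.asarray(img)


def read_labelme(
    path_or_text: str | Path,
    label_aliases: dict[str, tuple[str, ...]] | None = None,
) -> ToothAnnotation:
    """Parse a labelme-dialect JSON document into a :class:`ToothAnnotation`.

    ``path_or_text`` may be a filesystem path or raw JSON text.  The document
    must contain exactly one polygon shape per region label.
    """
    aliases = label_aliases or DEFAULT_LABEL_ALIASES
    base_dir: Path | None = None
    text: str
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str)
        and not path_or_text.lstrip().startswith("{")
    ):
        p = Path(path_or_text)
        text = p.read_text()
        base_dir = p.parent
    else:
        text = str(path_or_text)
    doc = json.loads(text)

    found: dict[str, list[tuple[float, float]]] = {}
    for shape in doc.get("shapes", []):
        canonical = _match_label(str(shape.get("label", "")), aliases)
        if canonical is None:
            continue
        if shape.get("shape_type", "polygon") != "polygon":
            raise AnnotationSchemaError(
                f"region {canonical!r} must be a polygon shape"
            )
        if canonical in found:
            raise AnnotationSchemaError(f"duplicate {canonical!r} shape")
        pts = [(float(x), float(y)) for x, y in shape["points"]]
        if len(pts) < 3:
            raise AnnotationSchemaError(f"{canonical!r} polygon needs >= 3 vertices")
        found[canonical] = pts
    missing = {"apical", "coronal"} - set(found)
    if missing:
        raise AnnotationSchemaError(f"missing region shapes: {sorted(missing)}")

    flags = doc.get("flags", {}) or {}
    return ToothAnnotation(
        image=_decode_image(doc, base_dir),
        apical_polygon=found["apical"],
        coronal_polygon=found["coronal"],
        source_id=str(doc.get("imagePath", "") or flags.get("source_id", "")),
        side=str(flags.get("side", "unknown")),
        expert_i3m=flags.get("expert_i3m"),
        expert_decision=flags.get("expert_decision"),
    )


def write_labelme(
    annotation: ToothAnnotation,
    path: str | Path,
    embed_image: bool = True,
) -> None:
    """Serialize an annotation back to the labelme JSON dialect."""
    path = Path(path)
    h, w = annotation.image.shape[:2]
    doc = {
        "version": "5.0.0",
        "flags": {
            "source_id": annotation.source_id,
            "side": annotation.side,
            "expert_i3m": annotation.expert_i3m,
            "expert_decision": annotation.expert_decision,
        },
        "shapes": [
            {
                "label": "apical",
                "points": [[float(x), float(y)] for x, y in annotation.apical_polygon],
                "shape_type": "polygon",
                "group_id": None,
            },
            {
                "label": "coronal",
                "points": [[float(x), float(y)] for x, y in annotation.coronal_polygon],
                "shape_type": "polygon",
                "group_id": None,
            },
        ],
        "imagePath": annotation.source_id or path.with_suffix(".png").name,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }
    if embed_image:
        buf = io.BytesIO()
        Image.fromarray(np.asarray(annotation.image)).save(buf, format="PNG")
        doc["imageData"] = base64.b64encode(buf.getvalue()).decode("ascii")
    else:
        doc["imageData"] = None
    path.write_text(json.dumps(doc))


def rasterize_geometry(geom, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize any shapely geometry: a pixel is true iff its center lies in
    the geometry (boundary inclusive)."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    shapely.prepare(geom)
    hit = shapely.intersects_xy(geom, cc.ravel().astype(float), rr.ravel().astype(float))
    return hit.reshape(h, w)


def rasterize_polygon(
    polygon: list[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a simple polygon given as (col, row) vertices.

    Pixel (i, j) is true iff its center (i, j) lies inside the polygon;
    centers exactly on the boundary count as inside.  A zero-area polygon is
    degenerate.
    """
    if len(polygon) < 3:
        raise DegenerateGeometryError("polygon needs at least 3 vertices")
    poly = Polygon([(float(x), float(y)) for x, y in polygon])
    if poly.area == 0:
        raise DegenerateGeometryError("zero-area polygon")
    if not poly.is_valid:
        poly = poly.buffer(0)
    return rasterize_geometry(poly, shape)


def annotation_masks(annotation: ToothAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the apical and coronal polygons onto the image grid."""
    shape = annotation.image.shape[:2]
    return (
        rasterize_polygon(annotation.apical_polygon, shape),
        rasterize_polygon(annotation.coronal_polygon, shape),
    )


def load_grayscale(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF raster as a single-channel array."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        raise ImageFormatError(f"{path}: expected a single-channel image")
    return arr
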