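"""Region-of-interest annotations: read, rasterize, and apply to class maps.

Quantification is restricted to manually outlined regions — epidermis or
tumor included, dermis or stroma excluded.  ROIs are polygon sets in
pixel coordinates (GeoJSON) or binary mask PNGs; rasterization uses the
pixel-center rule, with exclude polygons winning over include on overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape

from .classify import PixelClass

ROLES = ("include", "exclude")


class RoiParseError(ValueError):
    """A ROI file is malformed; the message names the offending feature."""


@dataclass(frozen=True)
class RoiPolygon:
    """One annotation polygon: exterior vertices in pixel coordinates
    (x rightward, y downward, 0-based), optional holes, and a role."""

    vertices: tuple[tuple[float, float], ...]
    role: str = "include"
    holes: tuple[tuple[tuple[float, float], ...], ...] = ()


@dataclass(frozen=True)
class RoiPolygonSet:
    """A set of include/exclude polygons referring to one image frame."""

    polygons: tuple[RoiPolygon, ...]

    def __len__(self) -> int:
        return len(self.polygons)


def _ring_vertices(ring: list, feature_label: str) -> tuple[tuple[float, float], ...]:
    verts = [tuple(float(c) for c in pt) for pt in ring]
    if len(verts) >= 2 and verts[0] == verts[-1]:
        verts = verts[:-1]  # drop GeoJSON ring closure
    if len(verts) < 3:
        raise RoiParseError(
            f"{feature_label}: a polygon ring needs at least 3 distinct "
            f"vertices, got {len(verts)}"
        )
    for v in verts:
        if not all(np.isfinite(v)):
            raise RoiParseError(f"{feature_label}: non-finite coordinate {v}")
    return tuple(verts)


def _polygons_from_geometry(geom: dict, role: str, label: str) -> list[RoiPolygon]:
    gtype = geom.get("type")
    if gtype == "Polygon":
        ring_sets = [geom["coordinates"]]
    elif gtype == "MultiPolygon":
        ring_sets = geom["coordinates"]
    else:
        raise RoiParseError(
            f"{label}: unsupported geometry type {gtype!r} "
            "(expected Polygon or MultiPolygon)"
        )
    polys = []
    for rings in ring_sets:
        if len(rings) == 0:
            raise RoiParseError(f"{label}: polygon with no rings")
        exterior = _ring_vertices(rings[0], label)
        holes = tuple(_ring_vertices(r, label) for r in rings[1:])
        polys.append(RoiPolygon(vertices=exterior, role=role, holes=holes))
    return polys


def read_roi(path: str | Path) -> RoiPolygonSet:
    """Read a GeoJSON annotation file into a polygon set.

    Features must be Polygon or MultiPolygon and may carry a ``role``
    property (``include`` or ``exclude``; default include).  Malformed
    features raise :class:`RoiParseError` naming the feature.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise RoiParseError(f"{path}: not valid JSON ({exc})") from exc

    if doc.get("type") == "FeatureCollection":
        features = doc.get("features", [])
    elif doc.get("type") == "Feature":
        features = [doc]
    else:
        raise RoiParseError(
            f"{path}: expected a GeoJSON Feature or FeatureCollection, "
            f"got type {doc.get('type')!r}"
        )

    polygons: list[RoiPolygon] = []
    for i, feat in enumerate(features):
        label = f"{path.name} feature {i}"
        props = feat.get("properties") or {}
        role = props.get("role", "include")
        if role not in ROLES:
            raise RoiParseError(f"{label}: unknown role {role!r}")
        geom = feat.get("geometry")
        if geom is None:
            raise RoiParseError(f"{label}: missing geometry")
        polygons.extend(_polygons_from_geometry(geom, role, label))
    return RoiPolygonSet(polygons=tuple(polygons))


def _shapely_union(polys: list[RoiPolygon]):
    import shapely.geometry as sg

    geoms = [sg.Polygon(p.vertices, holes=[list(h) for h in p.holes]) for p in polys]
    return shapely.union_all(geoms) if geoms else None


def rasterize(rois: RoiPolygonSet, width: int, height: int) -> np.ndarray:
    """Rasterize a polygon set to a boolean in-analysis mask.

    A pixel is in-analysis iff its center (x + 0.5, y + 0.5) lies inside
    the union of include polygons and outside the union of exclude
    polygons; exclude wins over include on overlap.  An empty polygon set
    yields an all-false mask.
    """
    if width < 1 or height < 1:
        raise ValueError("mask dimensions must be >= 1")
    includes = [p for p in rois.polygons if p.role == "include"]
    excludes = [p for p in rois.polygons if p.role == "exclude"]
    mask = np.zeros((height, width), dtype=bool)
    inc = _shapely_union(includes)
    if inc is None or inc.is_empty:
        return mask
    xs, ys = np.meshgrid(
        np.arange(width) + 0.5, np.arange(height) + 0.5, indexing="xy"
    )
    mask = shapely.contains_xy(inc, xs.ravel(), ys.ravel()).reshape(height, width)
    exc = _shapely_union(excludes)
    if exc is not None and not exc.is_empty:
        mask &= ~shapely.contains_xy(exc, xs.ravel(), ys.ravel()).reshape(
            height, width
        )
    return mask


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG (nonzero = in-analysis) to a boolean array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return arr > 0


def apply_mask(class_map, mask) -> np.ndarray:
    """Relabel out-of-analysis pixels as excluded; idempotent.

    In-analysis pixels keep their labels.  Raises ``ValueError`` on a
    dimension mismatch.
    """
    cmap = np.asarray(class_map)
    m = np.asarray(mask, dtype=bool)
    if cmap.shape != m.shape:
        raise ValueError(
            f"class map shape {cmap.shape} does not match mask shape {m.shape}"
        )
    out = cmap.copy()
    out[~m] = int(PixelClass.EXCLUDED)
    return out
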