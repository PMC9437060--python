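"""Domain geometry: region membership, coastal segmentation, stranding
and exit classification for particle positions.

All geometry is planar (local Cartesian metres).  Regions are closed sets:
a point on a boundary counts as inside.  Stranding is defined geometrically
as the intersection of a particle's displacement segment with a coastline,
so results do not depend on the forcing grid resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from shapely.geometry import (
    LineString, Point, Polygon, mapping, shape as shapely_shape,
)


@dataclass
class CoastalSegment:
    """One stretch of coastline (nominally 5 km) used to bin strandings."""

    id: str
    coast: str
    polyline: np.ndarray  # (n, 2) ordered planar points
    length: float

    def as_linestring(self) -> LineString:
        return LineString(self.polyline)


def polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def segment_coastline(polyline, segment_length: float, coast: str = "coast",
                      id_prefix: str = "Seg", start_index: int = 1):
    """Cut an ordered coastline polyline into consecutive segments.

    Every segment has arc length ``segment_length`` except possibly the
    last; ids are ``{prefix}{k}`` numbered from ``start_index`` in polyline
    order.  The concatenation of the returned polylines reproduces the
    input polyline.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must contain at least two points")
    if segment_length <= 0:
        raise ValueError("segment_length must be > 0")
    seg_d = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg_d)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")

    cuts = np.arange(0.0, total, segment_length)
    cuts = np.append(cuts, total)

    def point_at(s):
        i = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(pts) - 2)
        denom = cum[i + 1] - cum[i]
        t = 0.0 if denom == 0 else (s - cum[i]) / denom
        return pts[i] + t * (pts[i + 1] - pts[i])

    segments = []
    for k in range(len(cuts) - 1):
        s0, s1 = cuts[k], cuts[k + 1]
        inner = pts[(cum > s0 + 1e-9) & (cum < s1 - 1e-9)]
        poly = np.vstack([point_at(s0)[None], inner, point_at(s1)[None]])
        segments.append(CoastalSegment(
            id=f"{id_prefix}{start_index + k}", coast=coast,
            polyline=poly, length=float(s1 - s0)))
    return segments


@dataclass
class DomainGeometry:
    """Coastlines, named regions and gates of the model domain."""

    land_polygons: dict  # label -> shapely Polygon (closed, non-intersecting)
    spawning_region: Polygon
    strait_region: Polygon
    exit_gates: dict  # label -> (LineString, outward unit normal (nx, ny))
    open_boundary: Polygon
    segments: list = field(default_factory=list)  # CoastalSegment, all coasts

    def __post_init__(self):
        labels = list(self.land_polygons)
        if len(set(labels)) != len(labels):
            raise ValueError("land polygon labels must be unique")
        for label, poly in self.land_polygons.items():
            if not poly.is_valid:
                raise ValueError(f"land polygon {label!r} is invalid")
        if set(self.exit_gates) != {"tyrrhenian_gate", "ionian_gate"}:
            raise ValueError("exit_gates must be tyrrhenian_gate and ionian_gate")
        g1, g2 = (self.exit_gates[k][0] for k in
                  ("tyrrhenian_gate", "ionian_gate"))
        if g1.intersects(g2):
            raise ValueError("exit gates must not intersect")
        self._land_union = shapely.union_all(list(self.land_polygons.values()))
        shapely.prepare(self._land_union)
        shapely.prepare(self.strait_region)
        shapely.prepare(self.spawning_region)
        self._land_list = list(self.land_polygons.items())

    # -- membership ---------------------------------------------------------

    def on_land(self, x, y):
        """Vectorised closed land membership."""
        return shapely.intersects_xy(self._land_union, x, y)

    def in_strait(self, x, y):
        return shapely.intersects_xy(self.strait_region, x, y)

    def in_domain(self, x, y):
        b = self.open_boundary.bounds
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= b[0]) & (x <= b[2]) & (y >= b[1]) & (y <= b[3])

    def locate(self, position) -> set:
        """All region labels containing a point (closed membership)."""
        x, y = position
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError("position must be finite")
        labels = set()
        if self.on_land(x, y):
            labels.add("land")
        if self.in_strait(x, y):
            labels.add("strait_region")
        if shapely.intersects_xy(self.spawning_region, x, y):
            labels.add("spawning_region")
        return labels

    # -- stranding ----------------------------------------------------------

    def detect_stranding(self, prev_position, new_position):
        """First coastline contact along a displacement step, or None.

        Returns ``(coast_label, CoastalSegment, contact_point)`` for the
        earliest crossing of any land-polygon boundary along the path from
        ``prev_position`` to ``new_position``.
        """
        p0 = np.asarray(prev_position, dtype=float)
        p1 = np.asarray(new_position, dtype=float)
        path = LineString([p0, p1])
        best = None  # (param distance, label, contact point)
        for label, poly in self._land_list:
            if not path.intersects(poly):
                continue
            hit = path.intersection(poly.exterior)
            if hit.is_empty:
                # path starts/ends inside without crossing the ring (should
                # not happen for a water start) - fall back to the boundary
                hit = shapely.shortest_line(Point(p0), poly.exterior)
                hit = Point(hit.coords[-1])
            for geom in getattr(hit, "geoms", [hit]):
                for coord in geom.coords:
                    d = path.project(Point(coord))
                    if best is None or d < best[0]:
                        best = (d, label, np.array(coord[:2]))
        if best is None:
            return None
        _, label, contact = best
        segment = self.nearest_segment(contact, label)
        return label, segment, contact

    def nearest_segment(self, point, coast_label: Optional[str] = None):
        """Nearest coastal segment to a point, optionally on a given coast."""
        candidates = [s for s in self.segments
                      if coast_label is None or s.coast == coast_label]
        if not candidates:
            candidates = self.segments
        if not candidates:
            return None
        p = Point(point)
        return min(candidates, key=lambda s: s.as_linestring().distance(p))

    # -- exits --------------------------------------------------------------

    def classify_exit(self, position):
        """Gate whose outward half-plane contains the point, else None."""
        x, y = position
        for label, (gate, normal) in self.exit_gates.items():
            gx, gy = gate.coords[0]
            if (x - gx) * normal[0] + (y - gy) * normal[1] > 0:
                return label.replace("_gate", "")
        return None

    # -- raster helpers -----------------------------------------------------

    def land_mask(self, x_axis, y_axis) -> np.ndarray:
        """Boolean (ny, nx) mask: cell centre on land."""
        xx, yy = np.meshgrid(np.asarray(x_axis), np.asarray(y_axis))
        return self.on_land(xx.ravel(), yy.ravel()).reshape(xx.shape)

    # -- GeoJSON ------------------------------------------------------------

    def to_geojson(self) -> dict:
        feats = []

        def feat(geom, props):
            return {"type": "Feature", "geometry": mapping(geom),
                    "properties": props}

        for label, poly in self.land_polygons.items():
            coast = label if not label.startswith("island:") else label
            feats.append(feat(poly, {"label": label, "kind": "land",
                                     "coast": coast}))
        feats.append(feat(self.spawning_region,
                          {"label": "spawning_region", "kind": "region"}))
        feats.append(feat(self.strait_region,
                          {"label": "strait_region", "kind": "region"}))
        for label, (gate, normal) in self.exit_gates.items():
            feats.append(feat(gate, {"label": label, "kind": "gate",
                                     "outward_normal": list(normal)}))
        feats.append(feat(self.open_boundary,
                          {"label": "open_boundary", "kind": "boundary"}))
        for seg in self.segments:
            feats.append(feat(seg.as_linestring(),
                              {"label": seg.id, "kind": "segment",
                               "coast": seg.coast, "length_m": seg.length}))
        return {"type": "FeatureCollection",
                "properties": {"crs": "local Cartesian metres (planar)"},
                "features": feats}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, source) -> "DomainGeometry":
        if isinstance(source, (str, bytes)):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = source
        land, gates, segments = {}, {}, []
        spawning = strait = boundary = None
        for f in data["features"]:
            props = f["properties"]
            geom = shapely_shape(f["geometry"])
            kind = props.get("kind")
            if kind == "land":
                land[props["label"]] = geom
            elif kind == "region" and props["label"] == "spawning_region":
                spawning = geom
            elif kind == "region" and props["label"] == "strait_region":
                strait = geom
            elif kind == "gate":
                gates[props["label"]] = (geom, tuple(props["outward_normal"]))
            elif kind == "boundary":
                boundary = geom
            elif kind == "segment":
                pts = np.asarray(geom.coords)
                segments.append(CoastalSegment(
                    id=props["label"], coast=props["coast"],
                    polyline=pts, length=float(props["length_m"])))
        return cls(land_polygons=land, spawning_region=spawning,
                   strait_region=strait, exit_gates=gates,
                   open_boundary=boundary, segments=segments)
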