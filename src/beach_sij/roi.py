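"""Subchondral ROI propagation from open-polyline joint delineations.

The observer defines the sacroiliac joint as an open polyline in mm
coordinates with an anchor line at each end giving the joint/cortex angle.
From that single delineation a pair of closed polygonal ROIs is constructed
automatically, one on each side of the joint, by offsetting the polyline
perpendicular to itself to a fixed subchondral depth (10 mm by default).
Offsets use mitered joins (bevelled beyond a miter limit of twice the depth)
and end edges parallel to the anchor lines, so the ROI ends follow the
joint/cortex angle rather than being squared off.

Coordinates: x increases with column index, y with row index; the centre of
pixel (r, c) lies at (c * col_spacing, r * row_spacing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

__all__ = [
    "JointDelineation",
    "SubchondralROISet",
    "PixelSample",
    "DelineationError",
    "OffsetError",
    "propagate_rois",
    "rasterize_polygon",
    "select_slices",
    "pool_pixels",
]


class DelineationError(ValueError):
    """The joint delineation violates its invariants."""


class OffsetError(ValueError):
    """Perpendicular offsetting failed (e.g. curvature radius < depth)."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _perp(t: np.ndarray) -> np.ndarray:
    # 90 degree counter-clockwise rotation
    return np.array([-t[1], t[0]])


def _line_intersection(p, d, q, e, eps=1e-12):
    """Intersection of lines p + s*d and q + u*e; None if (near-)parallel."""
    denom = d[0] * e[1] - d[1] * e[0]
    scale = max(np.hypot(*d) * np.hypot(*e), 1.0)
    if abs(denom) < eps * scale:
        return None
    s = ((q[0] - p[0]) * e[1] - (q[1] - p[1]) * e[0]) / denom
    return np.asarray(p, dtype=float) + s * np.asarray(d, dtype=float)


@dataclass
class JointDelineation:
    """One observer's delineation of one joint on one slice.

    ``polyline`` is an ordered (n >= 2, 2) array of [x, y] vertices in mm.
    ``anchor_start`` / ``anchor_end`` are (2, 2) segments attached at the
    first / last polyline vertex; their direction sets the angle of the ROI
    end edge at that extremity.
    """

    slice_index: int
    joint_side: str
    polyline: np.ndarray
    anchor_start: np.ndarray
    anchor_end: np.ndarray

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.anchor_start = np.asarray(self.anchor_start, dtype=float)
        self.anchor_end = np.asarray(self.anchor_end, dtype=float)
        if self.joint_side not in ("left", "right"):
            raise DelineationError("joint_side must be 'left' or 'right'")
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2 or self.polyline.shape[1] != 2:
            raise DelineationError("polyline must be an (n>=2, 2) array")
        seg = np.diff(self.polyline, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) < 1e-9):
            raise DelineationError("consecutive polyline vertices must be distinct")
        if not LineString(self.polyline).is_simple:
            raise DelineationError("polyline must be simple (non-self-intersecting)")
        for name, anchor in (("anchor_start", self.anchor_start), ("anchor_end", self.anchor_end)):
            if anchor.shape != (2, 2):
                raise DelineationError(f"{name} must be a (2, 2) segment")
        from shapely.geometry import Point

        end0, end1 = self.polyline[0], self.polyline[-1]
        if LineString(self.anchor_start).distance(Point(end0)) > 1e-6:
            raise DelineationError("anchor_start must be attached at the first vertex")
        if LineString(self.anchor_end).distance(Point(end1)) > 1e-6:
            raise DelineationError("anchor_end must be attached at the last vertex")

    def anchor_direction(self, which: str) -> np.ndarray:
        """Unit direction of an anchor line (undirected; sign is irrelevant)."""
        anchor = self.anchor_start if which == "start" else self.anchor_end
        return _unit(anchor[1] - anchor[0])


@dataclass
class SubchondralROISet:
    """The pair of subchondral polygons of one joint on one slice.

    ``polygons`` maps side-of-joint name ('sacral' or 'iliac') to a closed
    shapely polygon sharing the joint polyline as common boundary.
    """

    slice_index: int
    joint_side: str
    polygons: dict[str, Polygon]
    depth_mm: float


@dataclass
class PixelSample:
    """Pooled pixel values of one patient/timepoint/map over all ROIs."""

    patient_id: str
    kind: str
    values: np.ndarray
    n_pixels: int = field(default=-1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.n_pixels < 0:
            self.n_pixels = self.values.size
        if self.n_pixels != self.values.size:
            raise ValueError("n_pixels inconsistent with pooled values")


def _offset_chain(
    verts: np.ndarray,
    depth: float,
    sign: int,
    dir_start: np.ndarray,
    dir_end: np.ndarray,
    miter_limit: float,
) -> list[np.ndarray]:
    """Offset an open polyline by ``depth`` toward the side given by ``sign``.

    Returns the offset chain from the first to the last vertex.  Interior
    joins are mitered, falling back to a bevel when the miter point lies
    further than ``miter_limit`` from the vertex; end points lie on the lines
    through the polyline endpoints along the anchor directions.
    """
    seg = np.diff(verts, axis=0)
    tangents = [_unit(s) for s in seg]
    normals = [sign * _perp(t) for t in tangents]
    k = len(tangents)

    chain: list[np.ndarray] = []
    # start cap: anchor line through first vertex meets first offset line
    p = _line_intersection(verts[0], dir_start, verts[0] + depth * normals[0], tangents[0])
    if p is None:
        raise OffsetError("anchor_start is parallel to the first segment")
    chain.append(p)
    seg_starts = [0]  # chain index of each segment's start point

    for i in range(1, k):  # interior vertex i joins segments i-1 and i
        a = _line_intersection(
            verts[i - 1] + depth * normals[i - 1], tangents[i - 1],
            verts[i] + depth * normals[i], tangents[i],
        )
        if a is None:  # collinear segments: offsets coincide
            chain.append(verts[i] + depth * normals[i])
        elif np.linalg.norm(a - verts[i]) > miter_limit:
            chain.append(verts[i] + depth * normals[i - 1])
            chain.append(verts[i] + depth * normals[i])
        else:
            chain.append(a)
        seg_starts.append(len(chain) - 1)

    p = _line_intersection(verts[-1], dir_end, verts[-1] + depth * normals[-1], tangents[-1])
    if p is None:
        raise OffsetError("anchor_end is parallel to the last segment")
    chain.append(p)

    # a segment whose offset runs backwards means the local curvature radius
    # is smaller than the offset depth: the polygon would self-intersect
    for i in range(k):
        start = chain[seg_starts[i]]
        end = chain[seg_starts[i] + 1] if i < k - 1 else chain[-1]
        if float(np.dot(end - start, tangents[i])) <= 0:
            raise OffsetError(
                f"offset at depth {depth} mm self-intersects near vertex {i + 1} "
                "(curvature radius smaller than depth)"
            )
    return chain


def _side_polygon(delin: JointDelineation, depth: float, sign: int) -> Polygon:
    chain = _offset_chain(
        delin.polyline,
        depth,
        sign,
        delin.anchor_direction("start"),
        delin.anchor_direction("end"),
        miter_limit=2.0 * depth,
    )
    ring = list(delin.polyline) + list(reversed(chain))
    poly = Polygon(ring)
    if not poly.is_valid:
        raise OffsetError("offset polygon is self-intersecting")
    return poly


def propagate_rois(delineation: JointDelineation, depth_mm: float = 10.0) -> SubchondralROISet:
    """Construct the sacral/iliac subchondral polygon pair for one joint-slice.

    Each polygon is the strip swept by offsetting the joint polyline
    perpendicular by ``depth_mm`` toward that side, with end edges parallel
    to the anchor lines.  For a 'left' joint the iliac side is the -x
    (lateral) side and the sacral side the +x (medial) side; mirrored for a
    'right' joint.
    """
    if depth_mm < 0:
        raise ValueError("depth_mm must be >= 0")
    if depth_mm == 0:
        empty = Polygon()
        return SubchondralROISet(
            delineation.slice_index, delineation.joint_side,
            {"sacral": empty, "iliac": empty}, 0.0,
        )
    pos = _side_polygon(delineation, depth_mm, +1)
    neg = _side_polygon(delineation, depth_mm, -1)

    # clip any residual overlap from noisy offsetting by the shared polyline side
    inter = pos.intersection(neg)
    if inter.area > 1e-9:
        neg = neg.difference(pos)

    line_mid = delineation.polyline.mean(axis=0)
    pos_is_minus_x = pos.centroid.x < line_mid[0]
    if delineation.joint_side == "left":
        names = ("iliac", "sacral") if pos_is_minus_x else ("sacral", "iliac")
    else:
        names = ("sacral", "iliac") if pos_is_minus_x else ("iliac", "sacral")
    return SubchondralROISet(
        delineation.slice_index,
        delineation.joint_side,
        {names[0]: pos, names[1]: neg},
        depth_mm,
    )


def rasterize_polygon(
    polygon: Polygon,
    grid_shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
) -> np.ndarray:
    """Boolean (rows, cols) mask of pixels whose centre lies in the polygon.

    Pixel (r, c) has its centre at (x, y) = (c * dc, r * dr).  A centre
    exactly on the boundary counts as inside.
    """
    rows, cols = grid_shape
    dr, dc = pixel_spacing_mm
    mask = np.zeros((rows, cols), dtype=bool)
    if polygon.is_empty or polygon.area == 0:
        return mask
    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(0, int(np.ceil(minx / dc - 1e-9)))
    c1 = min(cols - 1, int(np.floor(maxx / dc + 1e-9)))
    r0 = max(0, int(np.ceil(miny / dr - 1e-9)))
    r1 = min(rows - 1, int(np.floor(maxy / dr + 1e-9)))
    if c0 > c1 or r0 > r1:
        warnings.warn("polygon lies outside the pixel grid; mask is empty", stacklevel=2)
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = shapely.points(cc.ravel() * dc, rr.ravel() * dr)
    shapely.prepare(polygon)
    inside = shapely.covers(polygon, pts).reshape(rr.shape)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    if not mask.any():
        warnings.warn("polygon covers no pixel centre; mask is empty", stacklevel=2)
    return mask


def select_slices(kind: str, synovial_slices: Sequence[int]) -> list[int]:
    """Slice-inclusion rule per map kind.

    ADC maps use every slice where the synovial joint is visible; PDFF maps
    (acquired with much thinner slices) use alternate slices, starting at the
    first synovial slice.
    """
    idx = list(synovial_slices)
    if not idx:
        raise ValueError("synovial slice range is empty")
    kind = kind.upper()
    if kind == "ADC":
        return idx
    if kind == "PDFF":
        return idx[::2]
    raise ValueError(f"unknown map kind {kind!r}")


def pool_pixels(
    qmap,
    roi_sets: Mapping[int, Iterable[SubchondralROISet]],
    slice_indices: Sequence[int],
    patient_id: str = "",
) -> PixelSample:
    """Pool masked pixel values over all ROIs of the included slices.

    ``roi_sets`` maps slice index to the ROI sets (both joints) on that
    slice.  The result is the order-independent multiset of values from both
    joints and both sides of every included slice.
    """
    missing = [s for s in slice_indices if s not in roi_sets]
    if missing:
        raise ValueError(f"missing ROI sets for included slices: {missing}")
    chunks: list[np.ndarray] = []
    n_pixels = 0
    for s in slice_indices:
        plane = qmap.values[s]
        for roi in roi_sets[s]:
            for poly in roi.polygons.values():
                m = rasterize_polygon(poly, qmap.grid_shape, qmap.pixel_spacing_mm)
                n_pixels += int(m.sum())
                chunks.append(plane[m])
    values = np.concatenate(chunks) if chunks else np.empty(0)
    return PixelSample(patient_id=patient_id, kind=qmap.kind, values=values, n_pixels=n_pixels)
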