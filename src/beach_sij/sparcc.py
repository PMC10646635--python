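"""SPARCC visual-score arithmetic on quadrant-level annotations.

Bone marrow oedema (BME) is scored over 6 consecutive slices with each
sacroiliac joint divided into 4 quadrants.  Every quadrant with BME scores 1;
for each joint on each slice an extra point is added if the oedema extends
more than 10 mm deep from the joint line and another if it is at least as
intense as cerebrospinal fluid, giving a maximum of
6 slices x 2 joints x (4 + 1 + 1) = 72.  The depth/intensity increments are
applied per joint per slice: a strictly per-quadrant bonus could not reach
the canonical maximum of 72.

The structural fat score counts fat-metaplasia quadrants over its own slice
set; the default layout (6 x 2 x 4, maximum 48) is configurable because the
canonical decomposition of the published maximum is ambiguous.

Quadrants are ordered (iliac-upper, sacral-upper, iliac-lower, sacral-lower):
the joint polyline splits the subchondral band into iliac/sacral sides and
the normal through the polyline midpoint splits it into upper/lower halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .cohort import JOINTS, GroundTruth
from .config import SPARCCConfig
from .roi import JointDelineation, propagate_rois

QUADRANT_NAMES = ("iliac_upper", "sacral_upper", "iliac_lower", "sacral_lower")


class AnnotationError(ValueError):
    """Annotation flags violate the scoring rules."""


@dataclass
class SPARCCAnnotation:
    """Binary lesion calls of one rater for one patient/timepoint.

    ``bme`` has shape (slices, joints, quadrants); ``depth`` and
    ``intensity`` (slices, joints); ``fat`` (fat slices, joints, quadrants).
    Joint axis order is (left, right); quadrant order is
    :data:`QUADRANT_NAMES`.
    """

    bme: np.ndarray
    depth: np.ndarray
    intensity: np.ndarray
    fat: np.ndarray
    config: SPARCCConfig = field(default_factory=SPARCCConfig)

    def __post_init__(self) -> None:
        c = self.config
        self.bme = np.asarray(self.bme, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int8)
        self.intensity = np.asarray(self.intensity, dtype=np.int8)
        self.fat = np.asarray(self.fat, dtype=np.int8)
        expect = {
            "bme": (c.n_slices, c.n_joints, c.n_quadrants),
            "depth": (c.n_slices, c.n_joints),
            "intensity": (c.n_slices, c.n_joints),
            "fat": (c.fat_n_slices, c.n_joints, c.n_quadrants),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise AnnotationError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.isin(arr, (0, 1)).all():
                raise AnnotationError(f"{name} flags must be binary")

    def validate(self) -> None:
        """Depth/intensity increments require oedema in >= 1 quadrant."""
        present = self.bme.any(axis=2)
        for name, arr in (("depth", self.depth), ("intensity", self.intensity)):
            bad = (arr == 1) & ~present
            if bad.any():
                s, j = np.argwhere(bad)[0]
                raise AnnotationError(
                    f"{name} flag set without any quadrant BME flag "
                    f"(slice {s}, joint {JOINTS[j]})"
                )

    @classmethod
    def zeros(cls, config: SPARCCConfig | None = None) -> "SPARCCAnnotation":
        c = config or SPARCCConfig()
        return cls(
            bme=np.zeros((c.n_slices, c.n_joints, c.n_quadrants)),
            depth=np.zeros((c.n_slices, c.n_joints)),
            intensity=np.zeros((c.n_slices, c.n_joints)),
            fat=np.zeros((c.fat_n_slices, c.n_joints, c.n_quadrants)),
            config=c,
        )

    @classmethod
    def full(cls, config: SPARCCConfig | None = None) -> "SPARCCAnnotation":
        c = config or SPARCCConfig()
        ann = cls.zeros(c)
        ann.bme[:] = 1
        ann.depth[:] = 1
        ann.intensity[:] = 1
        ann.fat[:] = 1
        return ann


@dataclass
class SPARCCScores:
    bme_total: int
    sss_fat_total: int


def score_bme(annotation: SPARCCAnnotation) -> int:
    """SPARCC bone-marrow-oedema total: quadrant flags plus per-joint-slice
    depth and intensity increments."""
    annotation.validate()
    return int(annotation.bme.sum() + annotation.depth.sum() + annotation.intensity.sum())


def score_sss_fat(annotation: SPARCCAnnotation) -> int:
    """Structural fat score: count of fat-metaplasia quadrant flags."""
    annotation.validate()
    return int(annotation.fat.sum())


def score(annotation: SPARCCAnnotation) -> SPARCCScores:
    return SPARCCScores(score_bme(annotation), score_sss_fat(annotation))


# ---------------------------------------------------------------------------
# quadrant geometry and the ideal (noise-free) rater


def _true_delineation(truth: GroundTruth, joint: str, slice_index: int) -> JointDelineation:
    a0, a1 = truth.anchors[joint]
    return JointDelineation(
        slice_index=slice_index,
        joint_side=joint,
        polyline=truth.polylines[joint],
        anchor_start=a0,
        anchor_end=a1,
    )


def _midpoint_and_tangent(polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    line = LineString(polyline)
    mid = line.interpolate(0.5, normalized=True)
    ahead = line.interpolate(min(0.5 + 1e-3, 1.0), normalized=True)
    behind = line.interpolate(max(0.5 - 1e-3, 0.0), normalized=True)
    t = np.array([ahead.x - behind.x, ahead.y - behind.y])
    t /= np.hypot(*t)
    return np.array([mid.x, mid.y]), t


def quadrant_polygons(
    delineation: JointDelineation, depth_mm: float = 10.0
) -> dict[str, Polygon]:
    """Split the two subchondral side polygons into the 4 SPARCC quadrants.

    Upper/lower are taken along the polyline (vertices are ordered top to
    bottom), split by the normal line through the polyline midpoint.
    """
    rois = propagate_rois(delineation, depth_mm)
    mid, t = _midpoint_and_tangent(delineation.polyline)
    n = np.array([-t[1], t[0]])
    big = 1e4
    # half-plane containing points before the midpoint along the tangent
    upper_half = Polygon(
        [mid + n * big, mid - n * big, mid - n * big - t * big, mid + n * big - t * big]
    )
    quads: dict[str, Polygon] = {}
    for side, poly in rois.polygons.items():
        upper = poly.intersection(upper_half)
        lower = poly.difference(upper_half)
        quads[f"{side}_upper"] = upper
        quads[f"{side}_lower"] = lower
    return quads


def annotate_from_truth(
    truth: GroundTruth,
    config: SPARCCConfig | None = None,
    timepoint: str = "pre",
    treatment_effect: float = 0.0,
    depth_mm: float = 10.0,
    probe_depth_mm: float = 30.0,
) -> SPARCCAnnotation:
    """Ideal rater: derive the SPARCC annotation from ground-truth lesions.

    A quadrant is flagged iff the lesion mask intersects the quadrant
    polygon; the depth increment fires iff oedema pixels of that joint-slice
    extend more than ``depth_mm`` perpendicular from the joint line, and the
    intensity increment iff a CSF-intense oedema lesion contributes to a
    flagged joint-slice.
    """
    c = config or SPARCCConfig()
    ann = SPARCCAnnotation.zeros(c)
    dr, dc = truth.pixel_spacing_mm
    zt = truth.slice_thickness_mm
    oedema = truth.lesion_masks["oedema"][timepoint]
    fat = truth.lesion_masks["fat"][timepoint]
    lesions = truth.lesions_at(timepoint, treatment_effect)

    scoring = truth.scoring_slices[: c.n_slices]
    lines = {j: LineString(truth.polylines[j]) for j in JOINTS}
    for ln in lines.values():
        shapely.prepare(ln)
    for ji, joint in enumerate(JOINTS):
        line = lines[joint]
        other = lines[[j for j in JOINTS if j != joint][0]]
        delin = _true_delineation(truth, joint, 0)
        quads = quadrant_polygons(delin, depth_mm)
        prepared_quads = {k: v for k, v in quads.items()}
        for g in prepared_quads.values():
            shapely.prepare(g)

        for si, slice_idx in enumerate(scoring):
            for mask, target, is_oedema in ((oedema[slice_idx], ann.bme, True),
                                            (fat[slice_idx], ann.fat, False)):
                if si >= target.shape[0] or not mask.any():
                    continue
                rr, cc = np.nonzero(mask)
                pts = shapely.points(cc * dc, rr * dr)
                for qi, qname in enumerate(QUADRANT_NAMES):
                    side, half = qname.split("_")
                    poly = prepared_quads.get(f"{side}_{half}")
                    if poly is None or poly.is_empty:
                        continue
                    if shapely.covers(poly, pts).any():
                        target[si, ji, qi] = 1

            if ann.bme[si, ji].any() and oedema[slice_idx].any():
                # oedema pixels belonging to this joint (nearest joint line,
                # within the probe band) extending beyond the 10 mm depth
                rr, cc = np.nonzero(oedema[slice_idx])
                pts = shapely.points(cc * dc, rr * dr)
                d_here = shapely.distance(line, pts)
                d_other = shapely.distance(other, pts)
                mine = (d_here <= d_other) & (d_here <= probe_depth_mm)
                if mine.any() and d_here[mine].max() > depth_mm:
                    ann.depth[si, ji] = 1
                z_mm = slice_idx * zt
                for les in lesions:
                    if les.kind != "oedema" or not les.csf_intense or les.joint != joint:
                        continue
                    if abs(les.centre_mm[2] - z_mm) < les.radius_mm:
                        ann.intensity[si, ji] = 1
                        break
    ann.validate()
    return ann


def annotation_to_frame(ann: SPARCCAnnotation):
    """Long-format table of an annotation (one row per quadrant flag slot)."""
    import pandas as pd

    rows = []
    for si in range(ann.config.n_slices):
        for ji, joint in enumerate(JOINTS):
            for qi, quad in enumerate(QUADRANT_NAMES):
                rows.append(
                    {
                        "slice": si,
                        "joint": joint,
                        "quadrant": quad,
                        "bme": int(ann.bme[si, ji, qi]),
                        "depth": int(ann.depth[si, ji]),
                        "intensity": int(ann.intensity[si, ji]),
                        "fat": int(ann.fat[si, ji, qi]) if si < ann.fat.shape[0] else 0,
                    }
                )
    return pd.DataFrame(rows)
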