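"""Synthetic sacroiliac-joint cohort generator.

Emulates the data the analysis pipeline assumes: paired (pre/post biologic
therapy) ADC and PDFF volumes of both sacroiliac joints with focal oedema
and fat-metaplasia lesions, two radiology readers who delineate the joints
with positional jitter, two visual raters who call lesion quadrants with
imperfect sensitivity/specificity, and paired clinical scores whose change
distributions are configurable.

Randomness: a single integer seed; every patient/stage draws from a
substream spawned with a fixed key, so any patient is reproducible in
isolation and whole cohorts are bit-identical across runs.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps
from shapely.geometry import LineString

from .cohort import (
    JOINTS,
    ClinicalVisit,
    Cohort,
    GroundTruth,
    Lesion,
    Patient,
)
from .config import ClinicalEffect, SPARCCConfig, SyntheticConfig
from .maps import QuantitativeMap
from .roi import JointDelineation
from .sparcc import SPARCCAnnotation, annotate_from_truth

# substream keys (fixed offsets under the global seed)
_S_GEOMETRY = 0
_S_LESIONS = 1
_S_MAP = 2
_S_CLINICAL = 3
_S_READER = 4
_S_RATER = 5

ANCHOR_LENGTH_MM = 8.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _rotate(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


# ---------------------------------------------------------------------------
# geometry


def _make_polyline(rng: np.random.Generator, centre_x: float, top_y: float,
                   length: float, bow: float) -> np.ndarray:
    """A gently curved, roughly vertical open polyline with 3-6 vertices."""
    n = int(rng.integers(3, 7))
    ys = np.linspace(top_y, top_y + length, n)
    s = np.linspace(-1.0, 1.0, n)
    xs = centre_x + bow * (1.0 - s**2) + rng.normal(0.0, 0.5, n)
    return np.column_stack([xs, ys])


def _make_anchors(
    rng: np.random.Generator, polyline: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor segments at both polyline ends, near-perpendicular to the joint."""
    t0 = polyline[1] - polyline[0]
    t0 = t0 / np.hypot(*t0)
    t1 = polyline[-1] - polyline[-2]
    t1 = t1 / np.hypot(*t1)
    d0 = _rotate(np.array([-t0[1], t0[0]]), rng.normal(0.0, math.radians(8)))
    d1 = _rotate(np.array([-t1[1], t1[0]]), rng.normal(0.0, math.radians(8)))
    a0 = np.array([polyline[0] - d0 * ANCHOR_LENGTH_MM / 2, polyline[0] + d0 * ANCHOR_LENGTH_MM / 2])
    a1 = np.array([polyline[-1] - d1 * ANCHOR_LENGTH_MM / 2, polyline[-1] + d1 * ANCHOR_LENGTH_MM / 2])
    return a0, a1


def _make_geometry(cfg: SyntheticConfig, rng: np.random.Generator) -> GroundTruth:
    rows, cols = cfg.grid_shape
    dr, dc = cfg.pixel_spacing_mm
    cx = (cols - 1) * dc / 2 + rng.normal(0.0, 2.0)
    cy = (rows - 1) * dr / 2 + rng.normal(0.0, 2.0)
    sep = cfg.joint_separation_mm + rng.normal(0.0, 3.0)
    length = cfg.joint_length_mm + rng.normal(0.0, 3.0)
    top_y = cy - length / 2

    polylines: dict[str, np.ndarray] = {}
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for joint, sign in (("left", -1.0), ("right", 1.0)):
        bow = sign * rng.uniform(1.5, 4.0)
        poly = _make_polyline(rng, cx + sign * sep / 2, top_y, length, bow)
        polylines[joint] = poly
        anchors[joint] = _make_anchors(rng, poly)

    # the central band of slices shows the synovial joint; the first 6
    # synovial slices are the SPARCC scoring stack
    n = cfg.n_slices
    first = min(1, n - 1)
    last = max(first + 1, n - 1)
    synovial = list(range(first, last))
    if not synovial:
        synovial = [0]
    scoring = synovial[:6]

    return GroundTruth(
        polylines=polylines,
        anchors=anchors,
        synovial_slices=synovial,
        scoring_slices=scoring,
        lesions=[],
        lesion_masks={},
        pixel_spacing_mm=cfg.pixel_spacing_mm,
        slice_thickness_mm=cfg.slice_thickness_mm,
        grid_shape=cfg.grid_shape,
    )


def _place_lesions(cfg: SyntheticConfig, truth: GroundTruth,
                   rng: np.random.Generator) -> list[Lesion]:
    lesions: list[Lesion] = []
    n_oedema = int(rng.integers(cfg.lesion_count_range[0], cfg.lesion_count_range[1] + 1))
    n_fat = int(rng.integers(cfg.fat_lesion_count_range[0], cfg.fat_lesion_count_range[1] + 1))
    zt = cfg.slice_thickness_mm
    for kind, count in (("oedema", n_oedema), ("fat", n_fat)):
        for _ in range(count):
            joint = JOINTS[int(rng.integers(0, 2))]
            line = LineString(truth.polylines[joint])
            u = rng.uniform(0.15, 0.85)
            p = line.interpolate(u, normalized=True)
            ahead = line.interpolate(min(u + 1e-3, 1.0), normalized=True)
            t = np.array([ahead.x - p.x, ahead.y - p.y])
            t /= np.hypot(*t)
            nvec = np.array([-t[1], t[0]])
            side = 1.0 if rng.random() < 0.5 else -1.0
            d = rng.uniform(2.0, 7.0)
            centre2d = np.array([p.x, p.y]) + side * d * nvec
            z_slice = int(rng.choice(truth.scoring_slices))
            z = z_slice * zt + rng.uniform(-0.5, 0.5) * zt
            radius = rng.uniform(*cfg.lesion_radius_range_mm)
            scale = rng.uniform(0.7, 1.3)
            lesions.append(
                Lesion(
                    kind=kind,
                    joint=joint,
                    centre_mm=(float(centre2d[0]), float(centre2d[1]), float(z)),
                    radius_mm=float(radius),
                    adc_shift=cfg.oedema_adc_shift * scale if kind == "oedema" else 0.0,
                    pdff_shift=(cfg.oedema_pdff_shift if kind == "oedema"
                                else cfg.fat_lesion_pdff_shift) * scale,
                    csf_intense=(kind == "oedema" and rng.random() < cfg.csf_intense_prob),
                )
            )
    return lesions


def _marrow_mask(cfg: SyntheticConfig, truth: GroundTruth) -> np.ndarray:
    """In-plane mask of marrow within ``marrow_band_mm`` of either joint line."""
    rows, cols = cfg.grid_shape
    dr, dc = cfg.pixel_spacing_mm
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    pts = shapely.points(cc.ravel() * dc, rr.ravel() * dr)
    dist = np.full(pts.shape, np.inf)
    for joint in JOINTS:
        line = LineString(truth.polylines[joint])
        shapely.prepare(line)
        dist = np.minimum(dist, shapely.distance(line, pts))
    return (dist <= cfg.marrow_band_mm).reshape(rows, cols)


def _lesion_fields(
    cfg: SyntheticConfig,
    truth: GroundTruth,
    lesions: Iterable[Lesion],
    marrow: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Per-voxel intensity offset fields and ground-truth lesion masks.

    Lesions have a parabolic radial profile (peak shift at the centre, zero
    at the boundary).  Overlapping lesions of the same kind combine by
    maximum so intensities saturate instead of summing beyond physical
    bounds.  Everything is confined to the marrow band.
    """
    S = cfg.n_slices
    rows, cols = cfg.grid_shape
    dr, dc = cfg.pixel_spacing_mm
    zt = cfg.slice_thickness_mm
    adc_off = np.zeros((S, rows, cols))
    pdff_oed = np.zeros((S, rows, cols))  # negative offsets
    pdff_fat = np.zeros((S, rows, cols))
    masks = {
        "oedema": np.zeros((S, rows, cols), dtype=bool),
        "fat": np.zeros((S, rows, cols), dtype=bool),
    }
    xs = np.arange(cols) * dc
    ys = np.arange(rows) * dr
    for les in lesions:
        cxm, cym, czm = les.centre_mm
        r = les.radius_mm
        if r <= 0:
            continue
        c0 = max(0, int(np.floor((cxm - r) / dc)))
        c1 = min(cols - 1, int(np.ceil((cxm + r) / dc)))
        r0 = max(0, int(np.floor((cym - r) / dr)))
        r1 = min(rows - 1, int(np.ceil((cym + r) / dr)))
        if c0 > c1 or r0 > r1:
            continue
        dx2 = (xs[c0 : c1 + 1] - cxm) ** 2
        dy2 = (ys[r0 : r1 + 1] - cym) ** 2
        plane_d2 = dy2[:, None] + dx2[None, :]
        for s in range(S):
            dz2 = (s * zt - czm) ** 2
            if dz2 >= r * r:
                continue
            w = 1.0 - (plane_d2 + dz2) / (r * r)
            w[w < 0] = 0.0
            w *= marrow[r0 : r1 + 1, c0 : c1 + 1]
            hit = w > 1e-12
            masks[les.kind][s, r0 : r1 + 1, c0 : c1 + 1] |= hit
            if les.kind == "oedema":
                blk = adc_off[s, r0 : r1 + 1, c0 : c1 + 1]
                np.maximum(blk, les.adc_shift * w, out=blk)
                blk = pdff_oed[s, r0 : r1 + 1, c0 : c1 + 1]
                np.maximum(blk, -les.pdff_shift * w, out=blk)  # magnitude
            else:
                blk = pdff_fat[s, r0 : r1 + 1, c0 : c1 + 1]
                np.maximum(blk, les.pdff_shift * w, out=blk)
    return adc_off, pdff_oed, pdff_fat, masks


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lower: float, upper: float, size,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lower, upper))
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _mean_corrected_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lower: float, upper: float, size,
) -> np.ndarray:
    """Truncated normal whose post-truncation mean equals ``mean``.

    Truncating at a physical bound (ADC >= 0, PDFF in [0, 100]) shifts the
    mean of a plain truncated normal; here the location parameter is solved
    by fixed-point iteration so that the generated marrow distribution has
    exactly the configured mean.
    """
    if sd == 0:
        return np.full(size, np.clip(mean, lower, upper))
    loc = mean
    for _ in range(50):
        a = (lower - loc) / sd
        b = (upper - loc) / sd
        current = sps.truncnorm.mean(a, b, loc=loc, scale=sd)
        err = mean - current
        if abs(err) < 1e-10:
            break
        loc += err
    a = (lower - loc) / sd
    b = (upper - loc) / sd
    return sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _build_maps(
    cfg: SyntheticConfig,
    truth: GroundTruth,
    timepoint: str,
    rng: np.random.Generator,
    marrow: np.ndarray,
) -> tuple[QuantitativeMap, QuantitativeMap, dict[str, np.ndarray]]:
    shape = (cfg.n_slices, *cfg.grid_shape)
    lesions = truth.lesions_at(timepoint, cfg.treatment_effect)
    adc_off, pdff_oed, pdff_fat, masks = _lesion_fields(cfg, truth, lesions, marrow)
    # baseline marrow: truncation keeps ADC >= 0 and PDFF in range while the
    # mean correction preserves the configured marrow mean
    adc_base = _mean_corrected_truncated_normal(
        rng, cfg.adc_marrow_mean, cfg.adc_marrow_sd, 0.0, np.inf, shape
    )
    pdff_base = _mean_corrected_truncated_normal(
        rng, cfg.pdff_marrow_mean, cfg.pdff_marrow_sd, 0.0, 100.0, shape
    )
    adc = adc_base + adc_off
    pdff = np.clip(pdff_base - pdff_oed + pdff_fat, 0.0, 100.0)
    adc_map = QuantitativeMap(adc, "ADC", cfg.pixel_spacing_mm, cfg.slice_thickness_mm)
    pdff_map = QuantitativeMap(pdff, "PDFF", cfg.pixel_spacing_mm, cfg.slice_thickness_mm)
    return adc_map, pdff_map, masks


# ---------------------------------------------------------------------------
# clinical scores


def generate_clinical_pair(
    effects: dict[str, ClinicalEffect], rng: np.random.Generator
) -> tuple[ClinicalVisit, ClinicalVisit]:
    """Draw one patient's paired visits.

    The change score (pre minus post) is drawn exactly from the configured
    Normal(change_mean, change_sd); the baseline is then drawn from a normal
    truncated to the interval that keeps both visits inside the instrument
    range, so planted treatment effects are recovered without truncation
    bias on the change distribution.
    """
    pre_vals: dict[str, float] = {}
    post_vals: dict[str, float] = {}
    for name, eff in effects.items():
        span = eff.upper - eff.lower
        if math.isfinite(span):
            change = float(
                _truncated_normal(rng, eff.change_mean, eff.change_sd, -span, span, ())
            )
        else:
            change = float(rng.normal(eff.change_mean, eff.change_sd))
        lo = max(eff.lower, eff.lower + change)
        hi = min(eff.upper, eff.upper + change)
        pre = float(_truncated_normal(rng, eff.pre_mean, eff.pre_sd, lo, hi, ()))
        pre_vals[name] = pre
        post_vals[name] = pre - change
    fields = ("basdai", "spinal_vas", "asdas_crp", "asdas_esr", "crp", "esr")
    pre_visit = ClinicalVisit(**{f: pre_vals.get(f, math.nan) for f in fields}, timepoint="pre")
    post_visit = ClinicalVisit(**{f: post_vals.get(f, math.nan) for f in fields}, timepoint="post")
    pre_visit.validate()
    post_visit.validate()
    return pre_visit, post_visit


def generate_clinical_cohort(cfg: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Clinical visits only (no imaging), as a long table
    (patient, score, pre, post).  Fast path for responsiveness simulations."""
    seed = cfg.seed if seed is None else seed
    rows = []
    for i in range(cfg.n_patients):
        rng = _rng(seed, i, _S_CLINICAL)
        pre, post = generate_clinical_pair(cfg.clinical_effects, rng)
        for name in cfg.clinical_effects:
            rows.append(
                {
                    "patient": f"P{i:03d}",
                    "score": name,
                    "pre": getattr(pre, name),
                    "post": getattr(post, name),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers and raters


def simulate_reader_delineation(
    truth: GroundTruth,
    jitter_sd: float,
    seed_or_rng: int | np.random.Generator,
    usable_depth_mm: float | None = 10.0,
) -> dict[tuple[int, str], JointDelineation]:
    """One reader's delineations of every synovial slice of both joints.

    Vertex positions are the true polyline vertices plus isotropic Gaussian
    noise of scale ``jitter_sd`` (independent per slice, emulating slice-by-
    slice drawing); anchor angles are perturbed proportionally.  A draw that
    bends the polyline too sharply to support perpendicular offsetting to
    ``usable_depth_mm`` is redrawn, as a reader would redraw an unusable
    delineation; pass None to disable the check.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out: dict[tuple[int, str], JointDelineation] = {}
    angle_sd = jitter_sd / ANCHOR_LENGTH_MM  # radians, proportional to jitter
    for slice_idx in truth.synovial_slices:
        for joint in JOINTS:
            poly = truth.polylines[joint]
            a0, a1 = truth.anchors[joint]
            for attempt in range(60):
                scale = jitter_sd if attempt < 50 else 0.0  # give up on noise
                noisy = poly + rng.normal(0.0, scale, poly.shape)
                new_anchors = []
                for anchor, end in ((a0, 0), (a1, -1)):
                    d = anchor[1] - anchor[0]
                    d = d / np.hypot(*d)
                    d = _rotate(d, rng.normal(0.0, angle_sd)) if scale > 0 else d
                    p = noisy[end]
                    new_anchors.append(
                        np.array([p - d * ANCHOR_LENGTH_MM / 2, p + d * ANCHOR_LENGTH_MM / 2])
                    )
                from .roi import DelineationError, OffsetError, propagate_rois

                try:
                    delin = JointDelineation(
                        slice_index=slice_idx,
                        joint_side=joint,
                        polyline=noisy,
                        anchor_start=new_anchors[0],
                        anchor_end=new_anchors[1],
                    )
                    if usable_depth_mm is not None and jitter_sd > 0:
                        propagate_rois(delin, usable_depth_mm)
                except (DelineationError, OffsetError):
                    continue
                break
            out[(slice_idx, joint)] = delin
    return out


def simulate_visual_rater(
    truth: GroundTruth,
    sensitivity: float,
    specificity: float,
    seed_or_rng: int | np.random.Generator,
    timepoint: str = "pre",
    sparcc_config: SPARCCConfig | None = None,
    treatment_effect: float = 0.0,
) -> SPARCCAnnotation:
    """An imperfect rater: flips the ideal annotation's quadrant calls.

    Each truly positive quadrant is called present with probability
    ``sensitivity``; each truly negative one with probability
    ``1 - specificity``.  Depth/intensity increments are carried over from
    the truth only when the rater called at least one quadrant of that
    joint-slice present (keeping the annotation internally consistent).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    key = (timepoint, sparcc_config.n_slices if sparcc_config else 6)
    cache = truth.quadrant_tables
    if key not in cache:
        cache[key] = annotate_from_truth(
            truth, sparcc_config, timepoint, treatment_effect
        )
    ideal: SPARCCAnnotation = cache[key]

    def _flip(flags: np.ndarray) -> np.ndarray:
        u = rng.random(flags.shape)
        called = np.where(flags == 1, u < sensitivity, u < 1.0 - specificity)
        return called.astype(np.int8)

    bme = _flip(ideal.bme)
    fat = _flip(ideal.fat)
    present = bme.any(axis=2)
    ann = SPARCCAnnotation(
        bme=bme,
        depth=ideal.depth * present,
        intensity=ideal.intensity * present,
        fat=fat,
        config=ideal.config,
    )
    ann.validate()
    return ann


def expected_bme_score(
    ideal: SPARCCAnnotation, sensitivity: float, specificity: float
) -> float:
    """Closed-form expectation of the noisy rater's BME score.

    Quadrant calls are independent Bernoulli draws; the depth/intensity
    increments contribute their true value times the probability that at
    least one quadrant of the joint-slice is called present.
    """
    p_call = np.where(ideal.bme == 1, sensitivity, 1.0 - specificity)
    expect = p_call.sum()
    p_any = 1.0 - np.prod(1.0 - p_call, axis=2)
    expect += ((ideal.depth + ideal.intensity) * p_any).sum()
    return float(expect)


# ---------------------------------------------------------------------------
# cohort assembly


def generate_patient(cfg: SyntheticConfig, index: int, seed: int | None = None) -> Patient:
    seed = cfg.seed if seed is None else seed
    truth = _make_geometry(cfg, _rng(seed, index, _S_GEOMETRY))
    truth.lesions = _place_lesions(cfg, truth, _rng(seed, index, _S_LESIONS))
    marrow = _marrow_mask(cfg, truth)
    maps: dict[tuple[str, str], QuantitativeMap] = {}
    for ti, timepoint in enumerate(("pre", "post")):
        adc, pdff, masks = _build_maps(
            cfg, truth, timepoint, _rng(seed, index, _S_MAP, ti), marrow
        )
        maps[("ADC", timepoint)] = adc
        maps[("PDFF", timepoint)] = pdff
        for kind in ("oedema", "fat"):
            truth.lesion_masks.setdefault(kind, {})[timepoint] = masks[kind]
    rng_clin = _rng(seed, index, _S_CLINICAL)
    pre, post = generate_clinical_pair(cfg.clinical_effects, rng_clin)
    return Patient(
        patient_id=f"P{index:03d}",
        maps=maps,
        truth=truth,
        clinical={"pre": pre, "post": post},
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate the full synthetic cohort (deterministic for a fixed seed)."""
    config.validate()
    patients = [generate_patient(config, i) for i in range(config.n_patients)]
    return Cohort(patients=patients, config=config)


def reader_rng(cfg: SyntheticConfig, patient_index: int, reader: int, timepoint: str) -> np.random.Generator:
    """Substream for one reader's delineation of one patient/timepoint."""
    ti = 0 if timepoint == "pre" else 1
    return _rng(cfg.seed, patient_index, _S_READER, reader, ti)


def rater_rng(cfg: SyntheticConfig, patient_index: int, rater: int, timepoint: str) -> np.random.Generator:
    ti = 0 if timepoint == "pre" else 1
    return _rng(cfg.seed, patient_index, _S_RATER, rater, ti)
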