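"""Data containers for a (synthetic or ingested) sacroiliac-joint cohort."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

JOINTS = ("left", "right")
LESION_KINDS = ("oedema", "fat")
TIMEPOINTS = ("pre", "post")


@dataclass
class Lesion:
    """A focal spherical marrow lesion.

    ``kind`` is 'oedema' (raises ADC, lowers PDFF) or 'fat' (fat metaplasia,
    raises PDFF).  ``centre_mm`` is (x, y, z) with z along the slice axis.
    ``csf_intense`` marks oedema lesions whose signal would match
    cerebrospinal fluid on conventional images (drives the SPARCC intensity
    increment).  Shifts are the peak intensity offsets at the lesion centre.
    """

    kind: str
    joint: str
    centre_mm: tuple[float, float, float]
    radius_mm: float
    adc_shift: float = 0.0
    pdff_shift: float = 0.0
    csf_intense: bool = False

    def attenuated(self, treatment_effect: float) -> "Lesion":
        """Post-treatment version: oedema intensity and extent scaled by
        (1 - treatment_effect); fat lesions are unchanged."""
        if self.kind != "oedema":
            return self
        f = 1.0 - treatment_effect
        return Lesion(
            kind=self.kind,
            joint=self.joint,
            centre_mm=self.centre_mm,
            radius_mm=self.radius_mm * f,
            adc_shift=self.adc_shift * f,
            pdff_shift=self.pdff_shift * f,
            csf_intense=self.csf_intense,
        )


@dataclass
class GroundTruth:
    """Generator-side truth for one patient: joint geometry, lesions, masks.

    ``polylines``/``anchors`` hold the true joint delineation per joint (the
    same polyline applies to every slice of the small through-plane extent
    simulated here).  ``lesion_masks[kind][timepoint]`` is a boolean
    (slice, row, col) volume.  ``quadrant_tables`` holds the ideal
    (noise-free) SPARCC annotation per timepoint, filled in by
    :func:`beach_sij.sparcc.annotate_from_truth`.
    """

    polylines: dict[str, np.ndarray]
    anchors: dict[str, tuple[np.ndarray, np.ndarray]]
    synovial_slices: list[int]
    scoring_slices: list[int]
    lesions: list[Lesion]
    lesion_masks: dict[str, dict[str, np.ndarray]]
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    grid_shape: tuple[int, int]
    quadrant_tables: dict = field(default_factory=dict)

    def lesions_at(self, timepoint: str, treatment_effect: float) -> list[Lesion]:
        if timepoint == "pre":
            return list(self.lesions)
        return [l.attenuated(treatment_effect) for l in self.lesions]


@dataclass
class ClinicalVisit:
    """Clinical disease-activity scores recorded at one visit.

    BASDAI and spinal VAS are 0-10 scales; ASDAS composites are unbounded
    above; CRP is mg/L, ESR mm/h.  Missing components are NaN.
    """

    basdai: float
    spinal_vas: float
    asdas_crp: float
    asdas_esr: float
    crp: float
    esr: float
    timepoint: str

    def validate(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError("timepoint must be 'pre' or 'post'")
        for name in ("basdai", "spinal_vas", "asdas_crp", "asdas_esr", "crp", "esr"):
            v = getattr(self, name)
            if math.isnan(v):
                continue
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
            if name in ("basdai", "spinal_vas") and v > 10:
                raise ValueError(f"{name} must be <= 10")


@dataclass
class Patient:
    """One simulated patient: paired maps, ground truth, paired clinical visits."""

    patient_id: str
    maps: dict[tuple[str, str], object]  # (kind, timepoint) -> QuantitativeMap
    truth: Optional[GroundTruth]
    clinical: dict[str, ClinicalVisit]


@dataclass
class Cohort:
    patients: list[Patient]
    config: object

    def __len__(self) -> int:
        return len(self.patients)
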