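"""File formats: delineation JSON, cohort serialization, mask export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import JOINTS, ClinicalVisit, Cohort
from .maps import save_label_volume, save_map
from .roi import JointDelineation

CLINICAL_FIELDS = ("basdai", "spinal_vas", "asdas_crp", "asdas_esr", "crp", "esr")


def delineations_to_json(delineations: dict[tuple[int, str], JointDelineation]) -> list[dict]:
    """JSON-safe form: per-slice arrays of [x_mm, y_mm] plus anchor segments."""
    out = []
    for (slice_idx, joint), d in sorted(delineations.items()):
        out.append(
            {
                "slice_index": int(slice_idx),
                "joint_side": joint,
                "polyline": np.asarray(d.polyline).tolist(),
                "anchor_start": np.asarray(d.anchor_start).tolist(),
                "anchor_end": np.asarray(d.anchor_end).tolist(),
            }
        )
    return out


def save_delineations(delineations, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(delineations_to_json(delineations), fh, indent=1)


def load_delineations(path: str | Path) -> dict[tuple[int, str], JointDelineation]:
    with open(path) as fh:
        records = json.load(fh)
    out: dict[tuple[int, str], JointDelineation] = {}
    for rec in records:
        d = JointDelineation(
            slice_index=int(rec["slice_index"]),
            joint_side=rec["joint_side"],
            polyline=np.asarray(rec["polyline"], dtype=float),
            anchor_start=np.asarray(rec["anchor_start"], dtype=float),
            anchor_end=np.asarray(rec["anchor_end"], dtype=float),
        )
        out[(d.slice_index, d.joint_side)] = d
    return out


def clinical_table(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for patient in cohort.patients:
        for name in CLINICAL_FIELDS:
            rows.append(
                {
                    "patient": patient.patient_id,
                    "score": name,
                    "pre": getattr(patient.clinical["pre"], name),
                    "post": getattr(patient.clinical["post"], name),
                }
            )
    return pd.DataFrame(rows)


def clinical_visits_from_table(table: pd.DataFrame) -> dict[str, tuple[ClinicalVisit, ClinicalVisit]]:
    """Rebuild per-patient visit pairs from a long clinical table."""
    out: dict[str, tuple[ClinicalVisit, ClinicalVisit]] = {}
    for patient, grp in table.groupby("patient"):
        vals = grp.set_index("score")
        kw_pre = {f: float(vals["pre"].get(f, np.nan)) for f in CLINICAL_FIELDS}
        kw_post = {f: float(vals["post"].get(f, np.nan)) for f in CLINICAL_FIELDS}
        out[str(patient)] = (
            ClinicalVisit(**kw_pre, timepoint="pre"),
            ClinicalVisit(**kw_post, timepoint="post"),
        )
    return out


def save_cohort(cohort: Cohort, out_dir: str | Path, include_masks: bool = False) -> None:
    """Serialize a synthetic cohort: NIfTI maps per patient/timepoint/kind,
    true delineations as JSON, ground-truth quadrant tables and clinical
    scores as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for patient in cohort.patients:
        pdir = out / patient.patient_id
        pdir.mkdir(exist_ok=True)
        for (kind, timepoint), qmap in patient.maps.items():
            save_map(qmap, pdir / f"{kind.lower()}_{timepoint}.nii.gz")
        truth = patient.truth
        if truth is not None:
            truth_delins = {}
            for slice_idx in truth.synovial_slices:
                for joint in JOINTS:
                    a0, a1 = truth.anchors[joint]
                    truth_delins[(slice_idx, joint)] = JointDelineation(
                        slice_index=slice_idx,
                        joint_side=joint,
                        polyline=truth.polylines[joint],
                        anchor_start=a0,
                        anchor_end=a1,
                    )
            save_delineations(truth_delins, pdir / "true_delineations.json")
            if include_masks:
                for kind, per_tp in truth.lesion_masks.items():
                    for timepoint, mask in per_tp.items():
                        save_label_volume(
                            mask,
                            truth.pixel_spacing_mm,
                            truth.slice_thickness_mm,
                            pdir / f"mask_{kind}_{timepoint}.nii.gz",
                        )
    clinical_table(cohort).to_csv(out / "clinical.csv", index=False)
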