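"""Configuration objects for the synthetic cohort generator and the pipeline.

All lengths are in millimetres, ADC in 10^-6 mm^2/s, PDFF in percent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class ClinicalEffect:
    """Generating distribution for one paired clinical score.

    ``change`` is pre minus post, so a positive mean is an improvement. The
    change score is drawn exactly from Normal(change_mean, change_sd); the
    baseline is then drawn conditionally so both visits respect the
    instrument's range [lower, upper].
    """

    pre_mean: float
    pre_sd: float
    change_mean: float
    change_sd: float
    lower: float = 0.0
    upper: float = math.inf

    def validate(self) -> None:
        if self.pre_sd < 0 or self.change_sd < 0:
            raise ConfigurationError("clinical SDs must be >= 0")
        if not self.lower < self.upper:
            raise ConfigurationError("clinical score bounds must satisfy lower < upper")


def default_clinical_effects() -> dict[str, ClinicalEffect]:
    """Paired clinical score distributions for a biologic-therapy axSpA cohort.

    Baseline means and mean/SD of change match the published 30-patient cohort
    summary shipped with the package (change SDs are reconstructed from the
    printed 95% CIs under the paired-t model); baseline SDs, for which no
    value is published, are set to plausible clinic magnitudes.
    """
    return {
        "basdai": ClinicalEffect(6.88, 1.4, 1.97, 2.44, 0.0, 10.0),
        "spinal_vas": ClinicalEffect(6.90, 1.5, 2.14, 2.52, 0.0, 10.0),
        "asdas_crp": ClinicalEffect(3.32, 0.8, 0.92, 1.06, 0.0, math.inf),
        "asdas_esr": ClinicalEffect(3.19, 0.8, 0.90, 0.91, 0.0, math.inf),
        "crp": ClinicalEffect(5.35, 4.0, 3.36, 7.44, 0.0, math.inf),
        "esr": ClinicalEffect(18.0, 10.0, 4.0, 8.0, 0.0, math.inf),
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic sacroiliac-joint cohort.

    Defaults reproduce the magnitudes of the published cohort: subchondral
    marrow ADC centred near 195 x 10^-6 mm^2/s and PDFF near 57%, focal
    oedema lesions that raise ADC and lower PDFF, fat-metaplasia lesions that
    raise PDFF, a multiplicative post-treatment attenuation of oedema, two
    noisy readers and two imperfect visual raters, and paired clinical scores.
    """

    n_patients: int = 30
    n_slices: int = 8
    grid_shape: tuple[int, int] = (128, 128)
    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)
    slice_thickness_mm: float = 3.0

    adc_marrow_mean: float = 195.0
    adc_marrow_sd: float = 120.0
    pdff_marrow_mean: float = 57.0
    pdff_marrow_sd: float = 12.0

    oedema_adc_shift: float = 400.0
    oedema_pdff_shift: float = -25.0
    fat_lesion_pdff_shift: float = 20.0
    lesion_count_range: tuple[int, int] = (1, 4)
    fat_lesion_count_range: tuple[int, int] = (0, 3)
    lesion_radius_range_mm: tuple[float, float] = (3.0, 8.0)
    csf_intense_prob: float = 0.3

    treatment_effect: float = 0.5

    reader_jitter_sd_mm: float = 1.0
    rater_sensitivity: float = 0.9
    rater_specificity: float = 0.95

    clinical_effects: dict[str, ClinicalEffect] = field(
        default_factory=default_clinical_effects
    )
    seed: int = 0

    # geometry of the two joints (not usually touched)
    joint_separation_mm: float = 60.0
    joint_length_mm: float = 44.0
    marrow_band_mm: float = 20.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        for sd in (
            self.adc_marrow_sd,
            self.pdff_marrow_sd,
            self.reader_jitter_sd_mm,
        ):
            if sd < 0:
                raise ConfigurationError("standard deviations must be >= 0")
        for p in (self.rater_sensitivity, self.rater_specificity, self.csf_intense_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.treatment_effect <= 1.0:
            raise ConfigurationError("treatment_effect must lie in [0, 1]")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("lesion_count_range must be 0 <= lo <= hi")
        rlo, rhi = self.lesion_radius_range_mm
        if rlo <= 0 or rhi < rlo:
            raise ConfigurationError("lesion_radius_range_mm must be 0 < lo <= hi")
        for eff in self.clinical_effects.values():
            eff.validate()
        # both joints plus a 10 mm subchondral margin either side must fit
        rows, cols = self.grid_shape
        dr, dc = self.pixel_spacing_mm
        if dr <= 0 or dc <= 0:
            raise ConfigurationError("pixel spacing must be > 0")
        width_mm = (cols - 1) * dc
        height_mm = (rows - 1) * dr
        needed_w = self.joint_separation_mm + 2 * (self.marrow_band_mm + 10.0)
        needed_h = self.joint_length_mm + 2 * (self.marrow_band_mm + 10.0)
        if width_mm < needed_w or height_mm < needed_h:
            raise ConfigurationError(
                f"grid {rows}x{cols} at spacing {dr}x{dc} mm is too small: needs "
                f">= {needed_h:.0f} x {needed_w:.0f} mm to hold both joints plus margins"
            )


@dataclass
class SPARCCConfig:
    """Slice/joint/quadrant layout of the SPARCC scores.

    The bone-marrow-oedema score runs over 6 consecutive slices, 2 joints and
    4 quadrants, with per-joint-slice depth and intensity increments (maximum
    6 x 2 x (4 + 1 + 1) = 72).  The structural fat score counts fat quadrants
    over its own slice set; the default maximum is 6 x 2 x 4 = 48 and is
    deliberately configurable.
    """

    n_slices: int = 6
    n_joints: int = 2
    n_quadrants: int = 4
    fat_n_slices: int = 6

    @property
    def bme_max(self) -> int:
        return self.n_slices * self.n_joints * (self.n_quadrants + 2)

    @property
    def fat_max(self) -> int:
        return self.fat_n_slices * self.n_joints * self.n_quadrants


@dataclass
class RunConfig:
    """End-to-end pipeline configuration. Exactly one data mode is active:
    synthetic generation (``synthetic``) or file ingestion (``data_dir``)."""

    synthetic: Optional[SyntheticConfig] = field(default_factory=SyntheticConfig)
    data_dir: Optional[str] = None
    depth_mm: float = 10.0
    percentile_method: str = "linear"
    sparcc: SPARCCConfig = field(default_factory=SPARCCConfig)
    loa_multiplier: float = 1.96
    icc_model: str = "ICC2"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.data_dir is None):
            raise ConfigurationError(
                "exactly one data mode must be active: synthetic or data_dir"
            )
        if self.depth_mm < 0:
            raise ConfigurationError("depth_mm must be >= 0")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ConfigurationError(f"data_dir does not exist: {self.data_dir}")
        if self.synthetic is not None:
            self.synthetic.validate()


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return obj


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def config_hash(cfg) -> str:
    """Stable sha256 of a config's canonical JSON form."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _effect_from_dict(d: dict) -> ClinicalEffect:
    d = dict(d)
    if d.get("upper") in ("inf", None):
        d["upper"] = math.inf
    return ClinicalEffect(**d)


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    syn = d.get("synthetic")
    if syn is not None:
        syn = dict(syn)
        if "clinical_effects" in syn:
            syn["clinical_effects"] = {
                k: _effect_from_dict(v) for k, v in syn["clinical_effects"].items()
            }
        for key in ("grid_shape", "pixel_spacing_mm", "lesion_count_range",
                    "fat_lesion_count_range", "lesion_radius_range_mm"):
            if key in syn and syn[key] is not None:
                syn[key] = tuple(syn[key])
        d["synthetic"] = SyntheticConfig(**syn)
    if d.get("sparcc") is not None:
        d["sparcc"] = SPARCCConfig(**d["sparcc"])
    cfg = RunConfig(**d)
    cfg.validate()
    return cfg


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return run_config_from_dict(payload or {})


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
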