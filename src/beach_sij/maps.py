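"""Quantitative parameter maps (ADC, PDFF) and their NIfTI serialization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: recognised map kinds, upper case
MAP_KINDS = ("ADC", "PDFF")


@dataclass
class QuantitativeMap:
    """A 3-D quantitative parameter volume.

    ``values`` is indexed (slice, row, col).  ADC is in 10^-6 mm^2/s and must
    be non-negative; PDFF is in percent and must lie in [0, 100].  The
    in-plane coordinate convention places the centre of pixel (r, c) at
    (x, y) = (c * col_spacing, r * row_spacing) mm, with the first pixel
    centre at the origin.
    """

    values: np.ndarray
    kind: str
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.kind = self.kind.upper()
        if self.values.ndim != 3:
            raise ValueError("map values must be 3-D (slice, row, col)")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}, got {self.kind!r}")
        dr, dc = self.pixel_spacing_mm
        if dr <= 0 or dc <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be > 0")
        if self.kind == "PDFF":
            if self.values.min() < 0 or self.values.max() > 100:
                raise ValueError("PDFF values must lie in [0, 100]")
        elif self.values.min() < 0:
            raise ValueError("ADC values must be >= 0")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


def save_map(qmap: QuantitativeMap, path: str | Path) -> None:
    """Write a map as NIfTI; voxel sizes encode (row, col, slice) spacing."""
    dr, dc = qmap.pixel_spacing_mm
    # store as (row, col, slice) so in-plane axes come first
    data = np.transpose(qmap.values, (1, 2, 0))
    affine = np.diag([dr, dc, qmap.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header["descrip"] = qmap.kind.encode()
    nib.save(img, str(path))


def load_map(path: str | Path, kind: str | None = None) -> QuantitativeMap:
    """Read a NIfTI parameter map written by :func:`save_map` (or compatible)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if kind is None:
        kind = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "ADC"
    values = np.transpose(data, (2, 0, 1))
    return QuantitativeMap(
        values=values,
        kind=kind,
        pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
        slice_thickness_mm=float(zooms[2]),
    )


def save_label_volume(
    mask: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    slice_thickness_mm: float,
    path: str | Path,
) -> None:
    """Export a (slice, row, col) integer/boolean mask as a NIfTI label volume."""
    dr, dc = pixel_spacing_mm
    data = np.transpose(np.asarray(mask, dtype=np.uint8), (1, 2, 0))
    affine = np.diag([dr, dc, slice_thickness_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
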