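"""Histographic biomarkers of pooled subchondral pixel values.

The quantitative imaging biomarkers are the arithmetic mean and the 25th,
50th, 75th and 90th percentiles of the pooled pixel distribution (ADC_25,
ADC_median, ADC_75, ADC_90 and the PDFF analogues).  Percentiles use linear
interpolation of the empirical quantile function by default; the convention
is configurable because it shifts values on small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import PixelSample

#: default histogram ranges per map kind, covering the observed magnitudes
DEFAULT_HIST_RANGE = {"ADC": (0.0, 1200.0), "PDFF": (0.0, 100.0)}
DEFAULT_HIST_BINS = 64


@dataclass
class HistogramMetrics:
    """Mean and quartile/90th-percentile summaries of one pixel sample."""

    mean: float
    p25: float
    p50: float
    p75: float
    p90: float
    n_pixels: int
    kind: str

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
            "p90": self.p90,
            "n_pixels": self.n_pixels,
        }


def compute_metrics(sample: PixelSample, method: str = "linear") -> HistogramMetrics:
    """Histographic summary of a pooled pixel sample.

    ``method`` is the percentile interpolation convention passed through to
    :func:`numpy.percentile` ("linear" is the common type-7 definition).
    """
    values = sample.values
    if values.size == 0:
        raise ValueError("cannot compute histogram metrics of an empty pixel sample")
    p25, p50, p75, p90 = np.percentile(values, [25, 50, 75, 90], method=method)
    return HistogramMetrics(
        mean=float(values.mean()),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        p90=float(p90),
        n_pixels=int(values.size),
        kind=sample.kind,
    )


def export_histogram(
    sample: PixelSample,
    n_bins: int = DEFAULT_HIST_BINS,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram table (bin edges, counts) of a pixel sample.

    Values outside ``value_range`` are counted in the first/last bin, so the
    counts always sum to ``n_pixels``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if value_range is None:
        value_range = DEFAULT_HIST_RANGE.get(sample.kind, None)
    if value_range is None:
        lo, hi = float(sample.values.min()), float(sample.values.max())
        if lo == hi:
            hi = lo + 1.0
        value_range = (lo, hi)
    lo, hi = value_range
    if not hi > lo:
        raise ValueError("histogram range width must be positive")
    edges = np.linspace(lo, hi, n_bins + 1)
    clipped = np.clip(sample.values, lo, hi)
    counts, _ = np.histogram(clipped, bins=edges)
    return edges, counts
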