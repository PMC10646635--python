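"""Responsiveness and agreement statistics for paired cohort measurements.

Implements the study battery: reader averaging, paired t tests with 95% CIs,
the standardized response mean (SRM = mean change / SD of change, sample SD
with n-1 denominator) with its effect-size bands, SRM reconstruction from
printed summary statistics under the paired-t model, Pearson correlation,
Bland-Altman limits of agreement (bias +/- 1.96 SD), a two-way random-effects
absolute-agreement single-measure ICC, single-predictor binary logistic
regression, and the four clinical response classifiers.

Sign convention: change = pre - post, so positive change is improvement for
BASDAI, spinal VAS, ASDAS, CRP, ADC and SPARCC BME; PDFF (which rises with
treatment) is reported as post - pre where noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ClinicalVisit

SRM_BANDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "moderate"))


class DegenerateDataError(ValueError):
    """The input has no variance (or is otherwise degenerate) for this statistic."""


class SeparationError(ValueError):
    """Logistic regression outcome is perfectly separated by the predictor."""


@dataclass
class ResponseStats:
    metric: str
    mean_change: float
    sd_change: float
    srm: float
    srm_band: str
    t_stat: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float


@dataclass
class AgreementStats:
    bias: float
    loa_low: float
    loa_high: float
    icc: Optional[float] = None


@dataclass
class ClinicalResponse:
    """Binary clinical response flags (None where a component is missing)."""

    nice_response: Optional[bool]
    basdai50: Optional[bool]
    cii_asdas: Optional[bool]
    asdas_id: Optional[bool]


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def average_readers(table: pd.DataFrame) -> pd.DataFrame:
    """Average pre/post values over readers: one row per patient x metric."""
    required = {"patient", "metric", "reader", "pre", "post"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("cohort table is empty")
    out = (
        table.groupby(["patient", "metric"], as_index=False)[["pre", "post"]]
        .mean()
        .sort_values(["patient", "metric"], ignore_index=True)
    )
    return out


def paired_t(pre, post) -> tuple[float, int, float, float, float]:
    """Two-sided paired t test on pre - post; returns (t, df, p, ci_low, ci_high).

    The 95% CI is mean_change +/- t(0.975, n-1) * SE.
    """
    pre = _as_array(pre, "pre")
    post = _as_array(post, "post")
    if pre.size != post.size:
        raise ValueError("pre and post must be paired (equal length)")
    n = pre.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = pre - post
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero variance of change scores")
    res = sps.ttest_rel(pre, post)
    se = sd / math.sqrt(n)
    tq = sps.t.ppf(0.975, n - 1)
    m = d.mean()
    return float(res.statistic), n - 1, float(res.pvalue), m - tq * se, m + tq * se


def srm_band(value: float) -> str:
    """Effect-size band of an SRM magnitude: <0.2 negligible, 0.2-0.5 small,
    0.5-0.8 moderate, >=0.8 large (half-open upward)."""
    a = abs(value)
    for bound, name in SRM_BANDS:
        if a < bound:
            return name
    return "large"


def srm(changes) -> tuple[float, str]:
    """Standardized response mean of a sample of change scores."""
    d = _as_array(changes, "changes")
    if d.size < 2:
        raise ValueError("SRM needs at least 2 change scores")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero SD of change scores")
    value = float(d.mean() / sd)
    return value, srm_band(value)


def srm_from_summary(
    mean_pre: float, mean_post: float, ci_low: float, ci_high: float, n: int
) -> float:
    """Reconstruct the SRM from printed summary statistics.

    Inverts the paired-t 95% CI: SE = (ci_high - ci_low) / (2 t(0.975, n-1)),
    SD of change = SE * sqrt(n), SRM = (mean_pre - mean_post) / SD.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    width = ci_high - ci_low
    if width <= 0:
        raise ValueError("CI width must be positive")
    tq = sps.t.ppf(0.975, n - 1)
    se = width / (2.0 * tq)
    sd = se * math.sqrt(n)
    return float((mean_pre - mean_post) / sd)


def response_stats(metric: str, pre, post) -> ResponseStats:
    """Full responsiveness summary of one paired metric."""
    pre = _as_array(pre, "pre")
    post = _as_array(post, "post")
    t_stat, df, p, lo, hi = paired_t(pre, post)
    d = pre - post
    value, band = srm(d)
    return ResponseStats(
        metric=metric,
        mean_change=float(d.mean()),
        sd_change=float(d.std(ddof=1)),
        srm=value,
        srm_band=band,
        t_stat=t_stat,
        df=df,
        p_value=p,
        ci_low=lo,
        ci_high=hi,
    )


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson r needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero variance input to Pearson r")
    return float(sps.pearsonr(x, y).statistic)


def bland_altman(reader1, reader2, loa_multiplier: float = 1.96) -> AgreementStats:
    """Bland-Altman agreement: bias and limits bias +/- 1.96 SD of differences.

    The multiplier is the conventional normal 95% factor, not a t quantile.
    """
    r1 = _as_array(reader1, "reader1")
    r2 = _as_array(reader2, "reader2")
    if r1.size != r2.size:
        raise ValueError("reader value lists must be paired")
    if r1.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = r1 - r2
    bias = float(d.mean())
    spread = float(loa_multiplier * d.std(ddof=1))
    return AgreementStats(bias=bias, loa_low=bias - spread, loa_high=bias + spread)


def icc(ratings) -> float:
    """Two-way random-effects, absolute-agreement, single-measure ICC (ICC2).

    ``ratings`` is a complete (patients x readers) matrix.  The model choice
    is a documented package default; reliability studies rarely name one.
    """
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("ratings must be a (>=2 patients, >=2 readers) matrix")
    if np.isnan(mat).any():
        raise ValueError("ratings matrix must be complete (no NaN)")
    n, k = mat.shape
    if n * k < 5:
        raise ValueError("ICC needs at least 5 ratings in total")
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "rating": mat.ravel(),
        }
    )
    import pingouin as pg

    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="rating"
        )
    # absolute-agreement single-measure row: labelled ICC2 (Shrout-Fleiss) or
    # ICC(A,1) (McGraw-Wong) depending on the pingouin version
    hit = table["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(table.loc[hit, "ICC"].iloc[0])


def logistic_response(outcome, predictor) -> tuple[float, float]:
    """Single-predictor binary logistic regression: (odds ratio, Wald p).

    The odds ratio is per unit of the predictor.  Perfect separation is
    detected and raised rather than returning a meaningless estimate.
    """
    y = _as_array(outcome, "outcome")
    x = _as_array(predictor, "predictor")
    if y.size != x.size:
        raise ValueError("outcome and predictor must have equal length")
    if y.size < 10:
        raise ValueError("logistic regression needs at least 10 observations")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("outcome must contain both classes, coded 0/1")
    if x[y == 0].max() < x[y == 1].min() or x[y == 1].max() < x[y == 0].min():
        raise SeparationError("predictor perfectly separates the outcome classes")

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = sm.add_constant(x)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except PerfectSeparationError as exc:  # pragma: no cover - backend dependent
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False) or abs(res.params[1]) > 50:
        raise SeparationError("logistic fit did not converge (quasi-separation)")
    return float(math.exp(res.params[1])), float(res.pvalues[1])


def _delta(pre: float, post: float) -> float:
    return pre - post


def classify_clinical_response(pre: ClinicalVisit, post: ClinicalVisit) -> ClinicalResponse:
    """Apply the four clinical response criteria to one patient's visit pair.

    Improvement is pre - post.  Criteria: NICE response (BASDAI improvement
    >= 1.2 AND spinal VAS improvement >= 1), BASDAI 50 (>= 50% BASDAI
    reduction), clinically important ASDAS improvement (change > 1.1, strict)
    and ASDAS inactive disease (post ASDAS < 1.3, strict).  A criterion whose
    component scores are missing is returned as None.
    """
    if pre.timepoint != "pre" or post.timepoint != "post":
        raise ValueError("visits must be a (pre, post) pair")

    def have(*vals: float) -> bool:
        return not any(math.isnan(v) for v in vals)

    nice = None
    if have(pre.basdai, post.basdai, pre.spinal_vas, post.spinal_vas):
        nice = (_delta(pre.basdai, post.basdai) >= 1.2) and (
            _delta(pre.spinal_vas, post.spinal_vas) >= 1.0
        )
    basdai50 = None
    if have(pre.basdai, post.basdai) and pre.basdai > 0:
        basdai50 = _delta(pre.basdai, post.basdai) >= 0.5 * pre.basdai
    cii = None
    if have(pre.asdas_crp, post.asdas_crp):
        cii = _delta(pre.asdas_crp, post.asdas_crp) > 1.1
    asdas_id = None
    if have(post.asdas_crp):
        asdas_id = post.asdas_crp < 1.3
    return ClinicalResponse(
        nice_response=nice, basdai50=basdai50, cii_asdas=cii, asdas_id=asdas_id
    )
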