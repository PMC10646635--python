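"""End-to-end orchestration: generate -> delineate -> propagate -> pool ->
metrics -> score -> statistics, with deterministic outputs and a run manifest.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Patient, TIMEPOINTS
from .config import RunConfig, config_hash, config_to_dict
from .histogram import compute_metrics
from .io import clinical_table, clinical_visits_from_table, load_delineations
from .maps import MAP_KINDS, load_map
from .roi import pool_pixels, propagate_rois, select_slices
from .sparcc import score_bme, score_sss_fat
from .stats import (
    DegenerateDataError,
    SeparationError,
    average_readers,
    bland_altman,
    classify_clinical_response,
    icc,
    logistic_response,
    pearson_r,
    response_stats,
    srm_from_summary,
)
from .synthetic import (
    generate_cohort,
    rater_rng,
    reader_rng,
    simulate_reader_delineation,
    simulate_visual_rater,
)

logger = logging.getLogger("beach_sij")

QIB_METRICS = [
    f"{kind.lower()}_{stat}"
    for kind in MAP_KINDS
    for stat in ("mean", "p25", "median", "p75", "p90")
]
#: metrics whose improvement convention is post - pre (they rise with treatment)
POST_MINUS_PRE = {m for m in QIB_METRICS if m.startswith("pdff_")} | {"sparcc_sss_fat"}

_STAT_COLUMNS = {"mean": "mean", "p25": "p25", "median": "p50", "p75": "p75", "p90": "p90"}


def load_published_summary() -> pd.DataFrame:
    """The packaged printed-summary fixture (pre/post means, CIs, SRMs, n=30)."""
    ref = importlib.resources.files("beach_sij").joinpath(
        "data/published_cohort_summary.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def reconstruct_published_srm(summary: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Audit the printed summaries: reconstruct each metric's SRM from its
    printed means and 95% CI under the paired-t model and report the absolute
    deviation from the printed SRM.  Malformed rows are skipped with a warning.
    """
    if summary is None:
        summary = load_published_summary()
    rows = []
    for _, rec in summary.iterrows():
        try:
            pre, post = float(rec["mean_pre"]), float(rec["mean_post"])
            if str(rec.get("change_sign", "pre_minus_post")) == "post_minus_pre":
                pre, post = post, pre
            value = srm_from_summary(
                pre, post, float(rec["ci_low"]), float(rec["ci_high"]), int(rec["n"])
            )
        except (ValueError, KeyError, TypeError) as exc:
            logger.warning("skipping malformed summary row %r: %s", rec.get("metric"), exc)
            continue
        printed = float(rec["srm_printed"])
        rows.append(
            {
                "metric": rec["metric"],
                "srm_printed": printed,
                "srm_reconstructed": value,
                "abs_deviation": abs(value - printed),
                "note": rec.get("note", ""),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage implementations


def _patient_metrics_rows(
    patient: Patient, cfg: RunConfig, patient_index: int
) -> list[dict]:
    truth = patient.truth
    syn = cfg.synthetic
    rows = []
    for timepoint in TIMEPOINTS:
        for reader in (1, 2):
            rng = reader_rng(syn, patient_index, reader, timepoint)
            delins = simulate_reader_delineation(truth, syn.reader_jitter_sd_mm, rng)
            rows.extend(
                metrics_rows_from_delineations(
                    patient.maps, delins, truth.synovial_slices, cfg.depth_mm,
                    cfg.percentile_method, patient.patient_id, timepoint, reader,
                )
            )
    return rows


def metrics_rows_from_delineations(
    maps: dict,
    delineations: dict,
    synovial_slices: list[int],
    depth_mm: float,
    percentile_method: str,
    patient_id: str,
    timepoint: str,
    reader: int,
) -> list[dict]:
    """Propagate ROIs from one reader's delineations and summarise each map."""
    roi_sets: dict[int, list] = {}
    for (slice_idx, _joint), delin in delineations.items():
        roi_sets.setdefault(slice_idx, []).append(propagate_rois(delin, depth_mm))
    rows = []
    for kind in MAP_KINDS:
        qmap = maps.get((kind, timepoint))
        if qmap is None:
            continue
        slices = select_slices(kind, synovial_slices)
        sample = pool_pixels(qmap, roi_sets, slices, patient_id=patient_id)
        hm = compute_metrics(sample, method=percentile_method)
        row = {
            "patient": patient_id,
            "timepoint": timepoint,
            "reader": reader,
            "kind": kind,
            **hm.as_dict(),
        }
        rows.append(row)
    return rows


def _sparcc_rows(patient: Patient, cfg: RunConfig, patient_index: int) -> list[dict]:
    syn = cfg.synthetic
    rows = []
    for timepoint in TIMEPOINTS:
        for rater in (1, 2):
            rng = rater_rng(syn, patient_index, rater, timepoint)
            ann = simulate_visual_rater(
                patient.truth,
                syn.rater_sensitivity,
                syn.rater_specificity,
                rng,
                timepoint=timepoint,
                sparcc_config=cfg.sparcc,
                treatment_effect=syn.treatment_effect,
            )
            rows.append(
                {
                    "patient": patient.patient_id,
                    "timepoint": timepoint,
                    "rater": rater,
                    "sparcc_bme": score_bme(ann),
                    "sparcc_sss_fat": score_sss_fat(ann),
                }
            )
    return rows


def _reader_level_table(metrics: pd.DataFrame, sparcc: pd.DataFrame) -> pd.DataFrame:
    """Long (patient, metric, reader, pre, post) table across QIBs and scores."""
    frames = []
    if not metrics.empty:
        for stat, col in _STAT_COLUMNS.items():
            sub = metrics.pivot_table(
                index=["patient", "reader", "kind"],
                columns="timepoint",
                values=col,
            ).reset_index()
            sub["metric"] = sub["kind"].str.lower() + "_" + stat
            frames.append(sub[["patient", "metric", "reader", "pre", "post"]])
    if not sparcc.empty:
        for score_col in ("sparcc_bme", "sparcc_sss_fat"):
            sub = sparcc.pivot_table(
                index=["patient", "rater"], columns="timepoint", values=score_col
            ).reset_index()
            sub = sub.rename(columns={"rater": "reader"})
            sub["metric"] = score_col
            frames.append(sub[["patient", "metric", "reader", "pre", "post"]])
    if not frames:
        raise ValueError("no reader-level measurements to analyse")
    return pd.concat(frames, ignore_index=True)


def _responsiveness_table(table: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-metric paired t + SRM over the reader-averaged cohort table plus
    the clinical scores."""
    rows = []
    combined = pd.concat(
        [
            table[["patient", "metric", "pre", "post"]],
            clinical.rename(columns={"score": "metric"})[
                ["patient", "metric", "pre", "post"]
            ],
        ],
        ignore_index=True,
    )
    for metric, grp in combined.groupby("metric", sort=True):
        pre = grp["pre"].to_numpy()
        post = grp["post"].to_numpy()
        if metric in POST_MINUS_PRE:
            pre, post = post, pre
        try:
            rs = response_stats(metric, pre, post)
        except (DegenerateDataError, ValueError) as exc:
            rows.append({"metric": metric, "n": len(grp), "note": str(exc)})
            continue
        rows.append(
            {
                "metric": metric,
                "n": len(grp),
                "mean_pre": float(grp["pre"].mean()),
                "mean_post": float(grp["post"].mean()),
                "mean_change": rs.mean_change,
                "sd_change": rs.sd_change,
                "t_stat": rs.t_stat,
                "df": rs.df,
                "p_value": rs.p_value,
                "ci_low": rs.ci_low,
                "ci_high": rs.ci_high,
                "srm": rs.srm,
                "srm_band": rs.srm_band,
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def _correlation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline Pearson correlations of each QIB with the visual scores."""
    wide = table.pivot_table(index="patient", columns="metric", values="pre")
    rows = []
    for qib in QIB_METRICS:
        if qib not in wide.columns:
            continue
        for score_col in ("sparcc_bme", "sparcc_sss_fat"):
            if score_col not in wide.columns:
                continue
            try:
                r = pearson_r(wide[qib], wide[score_col])
            except (DegenerateDataError, ValueError):
                r = np.nan
            rows.append({"qib": qib, "score": score_col, "pearson_r": r})
    return pd.DataFrame(rows)


def _agreement_table(reader_table: pd.DataFrame, loa_multiplier: float) -> pd.DataFrame:
    """Inter-reader Bland-Altman + ICC per metric for baseline, repeat and
    change measurements."""
    rows = []
    for metric, grp in reader_table.groupby("metric", sort=True):
        wide_pre = grp.pivot_table(index="patient", columns="reader", values="pre")
        wide_post = grp.pivot_table(index="patient", columns="reader", values="post")
        if wide_pre.shape[1] < 2:
            continue
        r1, r2 = wide_pre.columns[:2]
        for label, w in (
            ("baseline", wide_pre),
            ("repeat", wide_post),
            ("change", wide_pre - wide_post),
        ):
            w = w.dropna()
            try:
                ba = bland_altman(w[r1], w[r2], loa_multiplier)
                icc_val = icc(w[[r1, r2]].to_numpy())
            except (ValueError, DegenerateDataError):
                continue
            rows.append(
                {
                    "metric": metric,
                    "measurement": label,
                    "bias": ba.bias,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "icc": icc_val,
                }
            )
    return pd.DataFrame(rows)


def _response_tables(
    clinical: pd.DataFrame, table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient clinical response flags and the logistic association of the
    NICE response with baseline / change in reader-averaged ADC median."""
    visits = clinical_visits_from_table(clinical)
    resp_rows = []
    for patient, (pre, post) in sorted(visits.items()):
        flags = classify_clinical_response(pre, post)
        resp_rows.append(
            {
                "patient": patient,
                "nice_response": flags.nice_response,
                "basdai50": flags.basdai50,
                "cii_asdas": flags.cii_asdas,
                "asdas_id": flags.asdas_id,
            }
        )
    responses = pd.DataFrame(resp_rows)

    adc = table[table["metric"] == "adc_median"].set_index("patient")
    merged = responses.set_index("patient").join(adc[["pre", "post"]], how="inner")
    merged["change"] = merged["pre"] - merged["post"]
    logit_rows = []
    for predictor, col in (("baseline_adc_median", "pre"), ("change_adc_median", "change")):
        sub = merged.dropna(subset=["nice_response", col])
        outcome = sub["nice_response"].astype(float)
        try:
            or_, p = logistic_response(outcome, sub[col])
            logit_rows.append(
                {"outcome": "nice_response", "predictor": predictor,
                 "odds_ratio": or_, "p_value": p, "note": ""}
            )
        except (SeparationError, ValueError) as exc:
            logit_rows.append(
                {"outcome": "nice_response", "predictor": predictor,
                 "odds_ratio": np.nan, "p_value": np.nan, "note": str(exc)}
            )
    return responses, pd.DataFrame(logit_rows)


# ---------------------------------------------------------------------------
# files-mode ingestion


def _load_files_cohort(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ingest NIfTI maps + delineation JSON (+ optional sparcc/clinical CSV)
    from a data directory laid out like :func:`beach_sij.io.save_cohort`."""
    root = Path(cfg.data_dir)
    metrics_rows: list[dict] = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        patient_id = pdir.name
        maps = {}
        for kind in MAP_KINDS:
            for timepoint in TIMEPOINTS:
                path = pdir / f"{kind.lower()}_{timepoint}.nii.gz"
                if path.exists():
                    maps[(kind, timepoint)] = load_map(path, kind)
        if not maps:
            continue
        for reader in (1, 2):
            for timepoint in TIMEPOINTS:
                cand = [
                    pdir / f"delineations_reader{reader}_{timepoint}.json",
                    pdir / "true_delineations.json",
                ]
                path = next((p for p in cand if p.exists()), None)
                if path is None:
                    raise FileNotFoundError(
                        f"no delineations for {patient_id} reader {reader} {timepoint}"
                    )
                delins = load_delineations(path)
                synovial = sorted({s for s, _ in delins})
                metrics_rows.extend(
                    metrics_rows_from_delineations(
                        maps, delins, synovial, cfg.depth_mm, cfg.percentile_method,
                        patient_id, timepoint, reader,
                    )
                )
    metrics = pd.DataFrame(metrics_rows)
    sparcc_path = root / "sparcc.csv"
    sparcc = pd.read_csv(sparcc_path) if sparcc_path.exists() else pd.DataFrame(
        columns=["patient", "timepoint", "rater", "sparcc_bme", "sparcc_sss_fat"]
    )
    clin_path = root / "clinical.csv"
    clinical = pd.read_csv(clin_path) if clin_path.exists() else pd.DataFrame(
        columns=["patient", "score", "pre", "post"]
    )
    return metrics, sparcc, clinical


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full analysis; writes CSV reports and a manifest into
    ``out_dir`` and returns the manifest dict."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        syn = config.synthetic
        if config.seed != syn.seed:
            syn.seed = config.seed
        logger.info("stage 1/4: generating synthetic cohort (n=%d)", syn.n_patients)
        cohort = generate_cohort(syn)
        logger.info("stage 2/4: delineation, ROI propagation and pooling")
        metrics_rows: list[dict] = []
        sparcc_rows: list[dict] = []
        for i, patient in enumerate(cohort.patients):
            logger.debug("  patient %s", patient.patient_id)
            metrics_rows.extend(_patient_metrics_rows(patient, config, i))
            sparcc_rows.extend(_sparcc_rows(patient, config, i))
        metrics = pd.DataFrame(metrics_rows)
        sparcc = pd.DataFrame(sparcc_rows)
        clinical = clinical_table(cohort)
    else:
        logger.info("stage 1-2/4: ingesting data from %s", config.data_dir)
        metrics, sparcc, clinical = _load_files_cohort(config)

    logger.info("stage 3/4: reader averaging")
    reader_table = _reader_level_table(metrics, sparcc)
    averaged = average_readers(reader_table)

    logger.info("stage 4/4: statistics")
    responsiveness = _responsiveness_table(averaged, clinical)
    correlations = _correlation_table(averaged)
    agreement = _agreement_table(reader_table, config.loa_multiplier)
    if not clinical.empty:
        responses, logistic = _response_tables(clinical, averaged)
    else:
        responses = pd.DataFrame()
        logistic = pd.DataFrame()
    audit = reconstruct_published_srm()

    outputs = {
        "metrics.csv": metrics,
        "sparcc.csv": sparcc,
        "clinical.csv": clinical,
        "cohort_table.csv": averaged,
        "responsiveness.csv": responsiveness,
        "correlations.csv": correlations,
        "agreement.csv": agreement,
        "responses.csv": responses,
        "logistic.csv": logistic,
        "published_srm_audit.csv": audit,
    }
    for name, frame in outputs.items():
        frame.to_csv(out / name, index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config_to_dict(config),
        "outputs": sorted(outputs),
        "n_patients": int(metrics["patient"].nunique()) if not metrics.empty else 0,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("run complete: %s", out)
    return manifest
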