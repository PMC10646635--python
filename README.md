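# beach-sij

Quantitative imaging biomarkers (QIBs) of sacroiliitis for axial
spondyloarthritis (axSpA), built around the BEACH-style semi-automated
workflow: an observer draws the line of each sacroiliac joint as an open
polyline with anchor lines, the software propagates polygonal regions of
interest (ROIs) into the subchondral bone to a 10 mm depth on both sides of
the joint, and the pooled ADC (apparent diffusion coefficient, 10⁻⁶ mm²/s)
and PDFF (proton density fat fraction, %) pixel values are summarised
histographically. The package also implements SPARCC visual-score
arithmetic, the responsiveness and agreement statistics used to evaluate
such biomarkers, and a synthetic sacroiliac-joint cohort generator so the
entire analysis runs end-to-end without patient data.

Intended users: imaging scientists and rheumatology researchers who want a
tested, reproducible implementation of the ROI-propagation + histogram
pipeline and its statistical evaluation.

## The method

**ROI propagation.** A joint delineation is an ordered polyline
(vertices in mm) with an anchor segment at each end giving the joint/cortex
angle. Each side's ROI is the strip swept by offsetting the polyline
perpendicular by a depth *d* (default 10 mm), with mitered joins (bevelled
beyond a miter limit of 2*d*) and end edges parallel to the anchor lines.
Masks contain every pixel whose centre lies inside the polygon (boundary
inclusive). ADC maps use all slices where the synovial joint is visible;
PDFF maps use alternate slices.

**Histographic QIBs.** For the pooled pixel multiset of one
patient/timepoint/map: the mean and the 25th, 50th, 75th and 90th
percentiles (ADC₂₅, ADC_median, ADC₇₅, ADC₉₀ and PDFF analogues), with
type-7 linear interpolation.

**SPARCC scores.** Bone marrow oedema over 6 consecutive slices × 2 joints
× 4 quadrants, plus per-joint-slice increments for oedema deeper than 10 mm
and for CSF-like intensity (maximum 6×2×(4+1+1) = 72). The structural fat
score counts fat-metaplasia quadrants (default maximum 48, configurable).

**Statistics.** Reader-averaged paired t tests with 95% CIs; the
standardized response mean SRM = mean(Δ)/SD(Δ) (sample SD, n−1) with bands
small 0.2–0.5, moderate 0.5–0.8, large ≥0.8; reconstruction of an SRM from
printed summaries via SE = (CI_high − CI_low)/(2·t₀.₉₇₅,ₙ₋₁),
SD = SE·√n; Pearson r; Bland-Altman limits of agreement bias ± 1.96·SD of
inter-reader differences; ICC(2,1) (two-way random effects, absolute
agreement, single measure); single-predictor binary logistic regression;
and the clinical response rules (ΔBASDAI ≥ 1.2 & Δspinal VAS ≥ 1; BASDAI 50;
ΔASDAS > 1.1; post ASDAS < 1.3).

## Worked example

```python
from beach_sij.config import RunConfig, SyntheticConfig
from beach_sij.pipeline import run_pipeline

cfg = RunConfig(synthetic=SyntheticConfig(n_patients=30), seed=1)
run_pipeline(cfg, "demo30")
```

or equivalently `beach-sij run --seed 1 --out demo30`. This simulates 30
patients (paired pre/post-biologic ADC and PDFF volumes with oedema and
fat-metaplasia lesions, two noisy readers, two visual raters, paired
clinical scores), runs delineation → ROI propagation → pooling → metrics →
scoring → statistics, and writes CSV reports plus a manifest. Selected rows
of `demo30/responsiveness.csv` from that exact run:

```
        metric  mean_pre  mean_post  p_value    srm   srm_band
    adc_median   194.008    189.252    0.000  0.966      large
    sparcc_bme    16.800      7.467    0.000  1.414      large
sparcc_sss_fat     9.183      8.900    0.412 -0.152 negligible
    spinal_vas     6.991      4.986    0.000  0.789   moderate
```

ADC median falls with treatment and SPARCC BME drops sharply, while the
structural fat score is unchanged — the post-treatment pattern the
generator plants (oedema attenuated, fat metaplasia persistent). Baseline
ADC median (~194) sits at the magnitude reported for real axSpA subchondral
bone. `agreement.csv` holds the inter-reader Bland-Altman bias/limits and
ICC per metric (e.g. baseline ADC median: bias −0.10, LoA −1.96 to 1.76,
ICC 0.98 under the default 1 mm reader jitter), and `responses.csv` the
per-patient clinical response flags.

`beach-sij reproduce-summary --out audit.csv` reconstructs, for each metric
of the published 30-patient cohort summary shipped in
`src/beach_sij/data/published_cohort_summary.csv`, the SRM implied by its
printed means and 95% CI under the paired-t model, alongside the printed
SRM and the absolute deviation (e.g. spinal VAS 0.850 vs printed 0.85;
SPARCC BME 0.524 vs 0.52). Rows whose printed numbers are internally
inconsistent are flagged in the `note` column.

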