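# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a software methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## ROI propagation geometry

A joint delineation is an open polyline of 2+ vertices in continuous mm
coordinates, with an anchor segment attached at each end. The coordinate
convention places the centre of pixel (r, c) at (x, y) = (c·Δc, r·Δr), with
the first pixel centre at the origin; this makes the raster/vector mapping
unambiguous and platform independent.

Each subchondral ROI is built by offsetting every polyline segment
perpendicular by the depth (10 mm default, exposed as a parameter) toward
one side and joining the offset lines:

- **Interior joins** are mitered (intersection of adjacent offset lines).
  When the miter point lies farther than 2× depth from the vertex the join
  falls back to a bevel, which bounds the polygon's excursion at sharp
  bends.
- **End caps** follow the anchor-line direction: the offset chain ends at
  the intersection of the terminal offset line with the line through the
  polyline endpoint along its anchor. The ROI ends are therefore angled,
  matching the joint/cortex angle the observer indicated, rather than
  squared off. This parallel-end-edge reading of the anchor construction is
  an implementation choice; the original tool documents it only
  pictorially.
- **Failure mode**: if the local curvature radius is smaller than the
  depth, an offset segment reverses direction; this raises an error naming
  the offending vertex instead of silently producing a self-intersecting
  polygon.
- Residual overlap between the two side polygons (possible after noisy
  offsetting) is clipped by set difference so the pair never double-counts
  pixels.

Rasterization includes a pixel iff its centre is covered by the polygon;
centres exactly on the boundary count as inside (ties resolved toward
inclusion, for determinism). Tests verify mask equality against an
independently coded exhaustive point-in-polygon classifier.

Slice selection: ADC maps include all slices where the synovial joint is
visible; PDFF maps use alternate slices starting at the **first** synovial
slice. The alternate-slice phase is not specified by the source workflow;
first-slice start is the documented, configurable default. Only synovial
segments are delineated, so ligamentous portions of the joint contribute no
pixels by construction.

## Histographic metrics

Percentiles use the type-7 (linear interpolation) empirical quantile. No
convention is canonical for this workflow and the choice shifts values on
small samples, so it is exposed as a parameter and the default documented.
Histograms default to 64 bins over [0, 1200] ×10⁻⁶ mm²/s for ADC and
[0, 100] % for PDFF; out-of-range values are counted in the end bins so
counts always sum to the pixel count.

## SPARCC arithmetic

The oedema score runs over 6 consecutive slices × 2 joints × 4 quadrants
(quadrants split by the joint line and by the normal through the polyline
midpoint). The depth (>10 mm) and CSF-intensity increments are applied per
joint per slice, giving the canonical maximum 6×2×(4+1+1) = 72; a strictly
per-quadrant increment cannot reach that maximum, which is why the
per-joint-slice rule is used. An increment without at least one flagged
quadrant in the same joint-slice is a validation error.

The structural fat score counts fat-metaplasia quadrant flags over its own
slice set. The default layout (6 slices × 2 joints × 4 quadrants, maximum
48) is configurable because the published maximum for this component does
not decompose into any slices×joints×quadrants product; the package does
not guess an undocumented decomposition.

## Statistics

- Sample SDs use the n−1 denominator throughout, consistent with the paired
  t test.
- SRM bands are half-open upward: <0.2 negligible, [0.2, 0.5) small,
  [0.5, 0.8) moderate, ≥0.8 large; banding uses the magnitude.
- `srm_from_summary` inverts the paired-t 95% CI
  (SE = width/(2·t₀.₉₇₅,ₙ₋₁), SD = SE·√n) and is the engine of the
  published-summary audit. It satisfies an exact round-trip identity with
  `srm` on any sample's own mean/CI/n (tested to 1e-9).
- Bland-Altman limits use the fixed 1.96 normal multiplier (not a t
  quantile), matching standard practice for 95% limits of agreement.
- The ICC is the two-way random-effects, absolute-agreement, single-measure
  ICC(2,1), computed via pingouin and cross-checked against a hand-coded
  ANOVA decomposition. Reliability reports often omit the variant; this
  default is a declared package choice.
- Logistic regression is a single-predictor ML logit fit (statsmodels);
  perfect separation is detected (class ranges disjoint, or non-convergent
  /exploding coefficient) and raised rather than reported.
- Clinical response rules follow the stated inequalities exactly: the NICE
  rule is boundary-inclusive (≥1.2 and ≥1), ASDAS clinically important
  improvement is strict (>1.1) and ASDAS inactive disease is strict (<1.3).
  Missing components yield a null flag, not false.
- No multiple-testing correction is applied, mirroring the analysis this
  package reproduces; interpret the per-metric p values accordingly.
- Improvement is pre − post for scores that fall with effective treatment
  (BASDAI, VAS, ASDAS, CRP, ADC, SPARCC BME) and post − pre for PDFF and
  the structural fat score, which rise.

## Published-summary audit

`data/published_cohort_summary.csv` transcribes the printed per-metric
pre/post means, 95% CIs and SRMs of a 30-patient biologic-therapy axSpA
cohort. Several printed lower CI bounds carry signs inconsistent with their
own row's means and SRM; where exactly one sign reading reproduces the
printed SRM under the paired-t model, that reading is stored and the `note`
column records the printed form. Four rows (BASDAI, structural fat, ADC 90,
PDFF 90) are internally inconsistent under either reading; they are kept as
printed, flagged, and excluded from numeric reconstruction checks. The
audit reports the reconstructed SRM and absolute deviation for every row so
the inconsistencies stay visible rather than being silently resolved.

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes, not the
physics that produces it (no diffusion or fat–water signal modelling, no
DICOM, no conventional-sequence synthesis):

- **Geometry**: two gently curved, roughly vertical joints per coronal
  slice (3–6 polyline vertices, ~60 mm apart, ~44 mm long), constant
  through the small simulated stack; anchor lines near-perpendicular with
  angular noise. Default grid 128×128 at 1.5×1.5 mm, 8 slices of 3 mm; the
  central slices are synovial and the first six form the SPARCC stack.
- **Marrow**: per-pixel ADC and PDFF draws from truncated normals (ADC ≥ 0,
  PDFF in [0, 100]) whose location is solved so the post-truncation mean
  equals the configured marrow mean (195 ×10⁻⁶ mm²/s and 57 %, the
  published baseline magnitudes). The marrow dispersions (SD 120 and 12)
  are calibration choices, not published values; they place the pooled
  baseline ADC median near 195. The extreme low tail of real ADC
  distributions (published ADC₂₅ ≈ 9) would need a zero-inflation component
  and is deliberately not modelled.
- **Lesions**: spheres with parabolic radial intensity profiles, centred
  2–7 mm from a joint line within the scoring slices. Oedema raises ADC
  (peak +400 by default, ±30% per-lesion scatter) and lowers PDFF (−25);
  fat metaplasia raises PDFF (+20). Overlapping same-kind lesions combine
  by maximum, and PDFF is clipped to [0, 100], so intensities saturate
  instead of summing beyond physical bounds. Oedema lesions carry a
  Bernoulli CSF-intensity attribute (p = 0.3) driving the SPARCC intensity
  increment.
- **Treatment**: post-treatment oedema offsets and radii are multiplied by
  (1 − treatment_effect), default 0.5; fat lesions are unchanged, so the
  structural fat score shows no planted pre/post difference.
- **Readers**: vertex positions get isotropic Gaussian jitter (default
  1 mm SD, independent per slice) and anchor angles proportional noise. A
  draw too jagged to offset to the working depth is redrawn, as a human
  reader would redraw an unusable delineation; the redraw conditions the
  jitter distribution slightly at large SDs.
- **Raters**: each truly involved quadrant is called with probability
  `sensitivity` (0.9), each uninvolved one with 1 − `specificity` (0.05);
  increments carry over only where the rater called the joint-slice
  present, keeping annotations valid.
- **Clinical scores**: the change score (pre − post) is drawn exactly from
  the configured normal — defaults taken from the published cohort's mean
  changes with SDs reconstructed from its CIs (e.g. spinal VAS 2.14 ± 2.52)
  — and the baseline is then drawn from a normal truncated to the interval
  that keeps both visits inside the instrument range. This conditioning
  preserves the planted change distribution un-truncated, so SRM recovery
  experiments converge to mean/SD; baseline SDs are plausible clinic
  magnitudes (unpublished). Imaging–clinical correlations default to zero.
- **Randomness**: one integer seed; every patient/stage/reader/rater draws
  from a `SeedSequence` substream with a fixed spawn key, so cohorts are
  bit-identical across runs and any single patient is reproducible in
  isolation.

What passing tests on this generator do **not** show: performance on real
marrow texture (spatially correlated noise, zero-inflated ADC tails,
through-slice anatomy changes), real reader behaviour (systematic rather
than isotropic disagreement), or true lesion morphology (non-spherical,
confluent). The synthetic treatment effect is also cleaner than biologic
response in patients, so synthetic SRMs for imaging metrics run higher than
published ones; the generator is an oracle for correctness and calibration
of the machinery, not a clinical simulator.

## Problem sizes used in tests

Unit tests use compact cohorts (1–8 patients, 96×96 grids, 4–6 slices);
the planted-effect recovery experiment uses 200 clinical cohorts of n = 30,
and the reader-jitter agreement experiment 200 patients at three jitter
levels on 4-slice volumes. These sizes give stable Monte-Carlo estimates
for the tolerances tested while keeping the default suite fast.

## Known limitations

- Files mode ingests NIfTI maps plus delineation JSON (and optional
  SPARCC/clinical CSVs); it does not read DICOM and performs no
  registration or joint detection.
- The SPARCC erosion, backfill and ankylosis components are out of scope.
- BASDAI/ASDAS are consumed as numbers; they are never computed from
  questionnaire items.
- Plot rendering is out of scope; the agreement and histogram tables are
  written as CSV plot data.
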