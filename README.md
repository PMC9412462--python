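# vimshrv

Cardiac-activity pipeline for assessing visually induced motion sickness
(VIMS) from single-lead ECG: preprocessing and R-peak detection, HRV feature
extraction, autonomic-balance zoning, Simulator Sickness Questionnaire (SSQ)
scoring, covariate-adjusted cohort statistics, and a permutation-validated
binary motion-sickness classifier — plus a synthetic cohort generator that
emulates a within-subject 2D-vs-VR viewing experiment so the whole pipeline
is testable without any recorded human data.

## Pipeline

1. **`ecg_processing`** — 5–15 Hz zero-phase Butterworth band-pass, adaptive
   dual-threshold QRS detection (derivative → squaring → 150 ms moving-window
   integration → dual thresholds with 200 ms refractory period and
   search-back), RR intervals, and NN filtering to the 600–1200 ms window.
2. **`hrv_features`** — heart rate, SDNN, pNN50; cubic-spline resampling of
   the NN tachogram at 4 Hz, full-segment Hann periodogram, VLF
   (0.0033–0.04 Hz) and HF (0.15–0.4 Hz) band powers, ln-normalized features
   (ln VLF, ln HF, ln VLF/ln HF), and the nine-zone autonomic-balance map on
   the (ln VLF, ln HF) plane.
3. **`ssq_scoring`** — 16-item SSQ into Nausea/Oculomotor/Disorientation
   subscales (weights 9.54 / 7.58 / 13.92) and total ((N+O+D) × 3.74).
4. **`cohort_stats`** — ANCOVA of post-viewing outcomes with the pre-viewing
   baseline as covariate, Bonferroni-corrected families (α = 0.0125 for 4 SSQ
   outcomes, α ≈ 0.0083 for 6 cardiac features), partial eta-squared, and
   partial correlations between total SSQ and each cardiac feature.
5. **`ms_classifier`** — LDA, KNN (k = 28, Euclidean), decision tree
   (deviance-reduction splits, max 2), and linear SVM (C = 0.0706) on the five
   informative features (heart rate excluded); stratified 10-fold CV with
   fold-internal standardization; accuracy/recall/precision/F1/ROC-AUC; and a
   label-permutation test of the cross-validated accuracy.
6. **`realtime_monitor`** — sliding-window (default 300 s / 10 s stride)
   feature extraction + per-window MS/normal decision from a trained
   classifier; failed windows are logged as invalid, never dropped.
7. **`synthetic_data`** — RR series with exact analytic band power (additive
   VLF/HF sinusoids, a²/2 per tone), sum-of-Gaussians ECG with baseline
   wander / 60 Hz / white noise and ground-truth R times, ordinal SSQ
   responses, and full cohorts with programmed VR-post effects
   (SDNN↓, pNN50↓, ln HF↓, ln VLF↑).

## CLI

```sh
vims simulate --n-subjects 28 --seed 3 --effect-scale 1.5 --out run/
vims stats    run/cohort.tsv --out run/stats/
vims classify run/cohort.tsv --n-perm 10000 --out run/classifiers.json
vims features ecg.csv --out features.tsv          # ECG CSV + JSON fs sidecar
vims ssq      ratings.csv --out scores.tsv        # 16 item columns, 0–3
vims monitor  ecg.csv run/cohort.tsv --out log.tsv
```

ECG files are two-column CSV (`time_s,voltage_mV`) with a JSON sidecar
(`{"fs": 500}`); cohorts and results are TSV/JSON.

## Notes

- Zone thresholds have no canonical numeric values; `ZoneConfig` is mandatory
  and `ZoneConfig.from_reference` derives stand-in thresholds as the
  25th/75th percentiles of a reference cohort.
- The ln VLF/ln HF ratio feature is the quotient of the logs (per its name);
  `ln_features(..., ratio_mode="log-of-ratio")` gives ln(VLF/HF) instead.
- The original participant recordings are not public, so cohort-level results
  here are properties of the synthetic generator, not reproductions of the
  human data.
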