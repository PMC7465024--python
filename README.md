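# radpt

Peri-tumoral + intra-tumoral radiomics risk stratification on bi-parametric
prostate MRI, exercised end-to-end on synthetic phantom cohorts.

The package implements the full analysis chain:

1. **`radpt.simdata`** — synthetic bi-parametric (T2W + ADC) multi-slice
   phantoms: elliptical prostate, blob lesions, class-dependent Gaussian
   random-field texture and intensity effects expressed inside the lesion
   and, with separately controllable per-3-mm-band effect sizes, in the
   0–12 mm shell around it; noisy monotone PI-RADS assignment; NIfTI +
   CSV-manifest output.
2. **`radpt.preprocess`** — resampling to a uniform in-plane pixel size
   (default 0.5 mm), slice interpolation to 3 mm, intensity
   standardisation (z-score within the prostate, or histogram-landmark
   alignment), ROI cropping with 2 mm physical padding.
3. **`radpt.rings`** — exact 2D Euclidean distance transform from the
   lesion and 4 annular peri-tumoral ring masks of 3 mm each out to
   12 mm, clipped to the prostate and excluding all lesions.
4. **`radpt.features`** — the 150-feature-per-sequence-per-ROI 2D texture
   battery: signal intensity (1), first-order windowed statistics (9),
   Gabor bank of 4 wavelengths x 19 orientations (76), Haralick
   co-occurrence statistics for 3 window sizes x 13 statistics (39), and
   the 25 Laws kernels — 150 x 2 sequences x (1 IT + 4 PT rings) = 1500
   columns per lesion.  A 13-map CoLlAGe (gradient-orientation
   co-occurrence) extension set is available but off by default so the
   150/300/1200 column contract holds.
5. **`radpt.selection`** — two-sided Wilcoxon rank-sum prefilter
   (unadjusted p < 0.01) followed by greedy MRMR (mutual-information
   difference scheme) ranking of the top 10 features.
6. **`radpt.classify`** — QDA with trace-scaled covariance shrinkage,
   100-run 3-fold cross-validation stratified by class at the patient
   level (all lesions of a patient share a fold), and independent
   hold-out scoring with train-only normalisation.
7. **`radpt.evaluate`** — ROC/AUC (trapezoid == Mann–Whitney U with tie
   half-credit), PI-RADS binarization (1–2 low / 3–5 high), and the
   risk-stratification cross-table with per-class and overall
   accuracies.
8. **`radpt.pipeline` / `radpt.cli`** — orchestration with a
   patient-level D1/D2 split, a leakage guard on the hold-out table, and
   the pool x sequence x setting x cohort AUC report.

## CLI

```bash
radpt simulate --config phantom.yaml --out cohort/        # NIfTI + manifest
radpt preprocess --in cohort/ --out pre/ --spacing 0.5 --std zscore_in_prostate
radpt rings --lesion pre/P0000/les0.nii.gz --prostate pre/P0000/prostate.nii.gz --out P0000
radpt extract --in pre/ --out features.csv
radpt select --features features.csv --setting L_vs_H --pool IT+PT --out top10.csv
radpt evaluate --features features.csv --selection top10.csv --out cv.csv
radpt run --config run.yaml --out rundir/                 # full pipeline
```

`run.yaml` nests `phantom:`, `preprocess:` and `battery:` sections plus
top-level split/selection/CV settings; see `RunConfig` in
`radpt/pipeline.py` for all fields.

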