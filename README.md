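# chdstack

Two-step stacking ensemble for screening coronary heart disease (CHD)
from speckle-tracking echocardiography feature tables.

## What this is

Angiography is the gold standard for diagnosing coronary stenosis, but it
is invasive and expensive; 2D speckle-tracking echocardiography (2D-STE)
is cheap and safe, and ischemia measurably degrades myocardial strain
before other signs appear. `chdstack` implements a screening pipeline
over 2D-STE-derived feature tables: 71 predictors per subject (peak
systolic strain, systolic strain rate and time-to-peak over the AHA
17-segment model; radial global strain at 3 levels × 3 layers;
layer-specific global longitudinal peak strain; time-to-peak dispersion;
age and six binary risk factors) and a binary CHD label.

The core estimator is **two-step stacking**. With L base classifiers
producing votes `c_1 … c_L`, majority voting classifies positive when
`(1/L) Σ c_l ≥ 0.5` and weighted voting when `Σ w_l c_l ≥ 0.5`; stacking
learns the combination on a held-out validation set. The two-step variant
repeats first-step stacking on K resampled train/validation splits

    c*_k = 1( Σ_l w_l^(k) c_l^(k) ≥ 0.5 ),   k = 1…K

and stacks the K results through second-step weights trained on a
separate validation set:

    c_stacking = 1( Σ_k w*_k c*_k ≥ 0.5 ).

Both layers of "weights" are random-forest meta-learners (score =
fraction of trees voting positive); resampling the first step reduces the
damage from unlucky model aggregation. Defaults follow the canonical
design: L = 14 base classifiers (selected from a 19-method registry by a
≥ 60% accuracy screen), K = 10, and a stratified 64 / 72 / 288 split of
424 subjects with (230, 58) first-step pairs.

The package also provides the 71-feature schema with CSV I/O and
validation, Welch t-test feature screening, block-wise PCA (17-segment
blocks → 3/3/2 components), the replicated mean ± SD evaluation protocol
(accuracy, sensitivity, specificity, ROC/AUC), a GLPS-only ablation, and
a synthetic cohort generator that emulates the study conditions so the
whole pipeline is testable without any clinical data.

## Worked example

```python
from chdstack import default_params, generate_cohort, summarize_cohort

table = generate_cohort(default_params(seed=42))
summary = summarize_cohort(table)
```

prints (via `examples/01_generate_cohort.py`):

```
cohort: 424 subjects, 217 CHD positive
age:   CHD+ 64.2 +/- 9.7   CHD- 64.0 +/- 9.8
smoke: CHD+ 51.2%   CHD- 27.1%
```

— the fixed case/control design, age balanced between classes, smoking
strongly enriched among cases. Screening and reduction
(`examples/02_screen_and_reduce.py`):

```
31/65 features flagged at alpha = 0.05
            t       p  flagged
PSS    3.2153  0.0014     True
SSR    4.7782  0.0000     True
TP     0.5509  0.5820    False
GS_MV -0.3594  0.7195    False
GS_PM  1.4628  0.1443    False
GS_AP -0.8506  0.3955    False
GLPS   5.4049  0.0000     True
PSD    0.2489  0.8035    False
predictors before/after PCA: 71 -> 28
```

— the longitudinal measures (PSS, SSR, GLPS) separate the classes, the
radial sections and time-to-peak do not, and block PCA shrinks the three
17-segment blocks to 3+3+2 components. `examples/03_two_step_stacking.py`
trains the full L=14, K=10 model and scores its held-out 64-subject test
set; `examples/04_method_comparison.py` runs the replicated comparison of
two-step stacking, traditional stacking and weighted voting plus the
GLPS-only ablation.

A thin CLI wraps the same functions:

```bash
chdstack generate --n 424 --seed 0 --out cohort.csv
chdstack preprocess --data cohort.csv --out reduced.csv
chdstack evaluate --data cohort.csv --replicates 5 --report report.json
chdstack run --out-dir run1        # full pipeline + manifest
```

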