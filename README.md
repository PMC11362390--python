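# lsci — laser speckle perfusion analysis

Intraoperative laser speckle contrast imaging (LSCI) maps bowel perfusion
without dyes: moving red blood cells blur the laser speckle pattern, so the
local spatial contrast `K = σ/μ` of a time-integrated image falls as flow
rises. During colorectal surgery this is used to find the *watershed* — the
boundary between well-perfused and ischemic bowel — when choosing where to
construct an anastomosis, since poor perfusion drives anastomotic leakage.

This package is a tested re-implementation of that analysis workflow for a
porcine ischemic small-bowel-loop model, built for researchers who want to
study the quantification chain itself (contrast windowing, perfusion-unit
conventions, cut-off derivation, observer variability) without access to
proprietary hardware or the original animal data. It provides:

- **a speckle simulator** — time-integrated dynamic speckle stacks of a
  bowel-loop flow phantom with per-pixel decorrelation times, validated
  against the closed form `K²(x) = β(e^(−2x) − 1 + 2x)/(2x²)`, `x = T/τc`;
- **perfusion mapping** — sliding-window `σ/μ` contrast (7 × 7) and the
  speckle flow index `LSPU = min(1/K², 200)` in arbitrary units (AU);
- **ROI statistics** — middle-96-frame selection, 60 × 60 px regions over
  the well-perfused / watershed / ischemic zones, normality-gated group
  tests (Welch t or Mann–Whitney U);
- **cut-off statistics** — a Youden-index threshold scan
  (`J = sensitivity + specificity − 1`, ties to the smallest threshold),
  exposed as a scikit-learn classifier, plus logarithmic curve estimation
  `lactate = b0 + b1 ln(LSPU)` against local capillary lactate;
- **a study emulator** — the full experimental design (4 animals, 18 loops,
  4 ROIs, 4 timepoints, 167 scheduled lactate records) with per-zone
  truncated-normal distributions set to the published means ± SDs;
- **observer agreement** — signed along-midline placement distances,
  within-1-cm fractions, and Cohen's kappa with a bootstrap CI.

## Worked example

```python
from lsci import (amplified_cohort, generate_study, labeled_values,
                  optimal_cutoff, log_curve_fit)
from lsci.study import paired_lspu_lactate

# large synthetic cohort from the published per-zone distributions,
# pooling ischemic vs well-perfused cells across T0/T60/T120
cohort = amplified_cohort(n_per_cell=2000, seed=0, link_mode="marginal")

values, labels = labeled_values(cohort, "lspu")
res = optimal_cutoff((values, labels), "below_positive")
print(f"LSPU cut-off: {res.threshold:.1f} AU  "
      f"(sens {res.sensitivity:.2f}, spec {res.specificity:.2f}, J {res.youden_j:.2f})")

values, labels = labeled_values(cohort, "lactate")
res = optimal_cutoff((values, labels), "above_positive")
print(f"lactate cut-off: {res.threshold:.2f} mmol/L  "
      f"(sens {res.sensitivity:.2f}, spec {res.specificity:.2f}, J {res.youden_j:.2f})")

# one realisation of the actual 167-record study with the log lactate link
study = generate_study(seed=0, link_mode="linked")
paired = paired_lspu_lactate(study)
fit = log_curve_fit(paired["lspu"], paired["lactate"])
print(f"lactate = {fit.b0:.1f} + {fit.b1:.1f} ln(LSPU),  R^2 = {fit.r_squared:.2f}  "
      f"(n = {len(paired)})")
```

prints

```
LSPU cut-off: 71.1 AU  (sens 0.84, spec 0.90, J 0.73)
lactate cut-off: 4.05 mmol/L  (sens 0.96, spec 0.99, J 0.95)
lactate = 58.7 + -12.2 ln(LSPU),  R^2 = 0.53  (n = 167)
```

The LSPU threshold separates tissue classified ischemic (below) from
well-perfused (at or above); ~71 AU and ~4 mmol/L sit where the generating
per-zone distributions place the optimal operating points, and the R² of the
log calibration reflects the configured link noise. Values move within
sampling error for other seeds.

The same stages run from the shell — `lsci simulate`, `contrast`, `roi`,
`cutoff`, `study-sim`, `agreement`, `report`, or end-to-end:

```bash
lsci run --out demo_run --seed 1   # writes maps, tables, and manifest.json
```

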