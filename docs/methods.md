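# Methods

This note documents the models, conventions and numerical choices behind the
package, in the spirit of the methods documentation of simulation-backed
analysis libraries.

## Problem setting

Laser speckle contrast imaging (LSCI) infers tissue perfusion from the
blurring of a laser speckle pattern by moving red blood cells: the faster the
flow, the shorter the speckle decorrelation time τc and the lower the
spatial contrast K of a time-integrated image. In the surgical application
addressed here, a laparoscopic speckle imager views an extracorporeal small
bowel loop whose central mesenteric arteries have been ligated, producing —
left to right along the loop — well-perfused tissue, a watershed transition,
an ischemic centre, a second watershed, and well-perfused tissue again.
The analysis pipeline quantifies perfusion in laser speckle perfusion units
(LSPU, arbitrary units), derives a diagnostic LSPU cut-off separating
ischemic from well-perfused tissue by the Youden index, calibrates LSPU
against local capillary lactate by logarithmic curve estimation, and
quantifies how reproducibly different observers place the watershed boundary.

Because the original recordings and tables are not deposited, every stage is
exercised against synthetic data whose generating parameters are the study's
published summary statistics. What a passing test shows is therefore that
*the estimators recover the parameters of the generating model*, not that
they reproduce the original data; distributional features the published
summaries do not constrain (skewness, within-loop correlation, the empirical
ROC shape) are not emulated.

## Speckle simulation

`lsci.speckle` draws a spatially band-limited circular complex Gaussian
field (fully developed speckle) and evolves it with a per-pixel AR(1) phasor
update,

    E ← ρ E + sqrt(1 − ρ²) E_new,   ρ = exp(−Δt / τc),

which realises a negative-exponential field correlation
g₁(t) = exp(−t/τc). A frame is the mean of |E|² over the sub-steps spanning
one exposure T — a discrete model of camera time integration. For a uniform
region this converges to the standard time-integrated speckle relation

    K²(x) = β (e^(−2x) − 1 + 2x) / (2x²),   x = T / τc,

which `expected_contrast` evaluates in closed form (with a two-term series
below x = 10⁻³ where the closed form cancels numerically). The tests require
the measured global σ/μ of uniform phantoms to track this curve within 10 %
over x ∈ [0.1, 100]; in practice it tracks within ~2 %.

Numerical choices:

- **Adaptive sub-stepping.** A fixed sub-step count cannot follow the time
  integral when τc ≪ Δt (at x = 100 a 25-step discretisation doubles K).
  The simulator raises the sub-step count so that Δt/τc ≤ 0.2 for the
  fastest decorrelation in the scene (floor `sub_steps`, cap 4000).
- **Speckle grain.** The field is band-limited by a circular frequency
  pupil with cutoff 0.5/`grain_radius` cycles/px; the default
  `grain_radius = 1.0` px gives an intensity correlation length of ~1.2 px.
  Because the simulator point-samples the field at pixel centres, sub-2 px
  grains lose no contrast here, and a fine grain gives the 7 × 7 contrast
  window more independent speckle cells, keeping the small-window estimation
  bias of the perfusion maps a few per cent. A real sensor integrates over
  pixel area and would attenuate such fine speckle; this divergence from
  camera physics is a deliberate simulator-side simplification.
- **Coherence factor.** β ∈ (0, 1] is realised by adding an incoherent
  constant background b = 1/√β − 1, which yields exactly K² = β K²_ideal.
- **Quantization.** Output is 16-bit by default at a mean level of 100
  counts. An 8-bit clip at 255 would truncate the exponential intensity tail
  of slow/static speckle and visibly depress the measured contrast (to
  ~0.84 for static speckle); 8-bit output remains available.
- **Determinism.** One master seed; per-frame sub-streams are spawned from a
  `SeedSequence`, so stacks are bit-identical across runs.
- τc is piecewise constant per pixel; no peristalsis or lateral motion is
  simulated, and no motion-compensation stage exists.

## Phantom and perfusion mapping

`make_loop_phantom` lays out the five-zone loop band and assigns
τc = T / LSPU_target per zone; watershed zones interpolate x = T/τc linearly
between their neighbours. Under the default perfusion convention this makes
the target recoverable end-to-end: `contrast_map` computes the windowed
σ/μ (population SD, 7 × 7 window, border invalid, zero-mean windows
invalid), and `lspu_map` applies the speckle flow index

    LSPU = min(1 / K², cap),   cap = 200 AU,

for which 1/K²(x) ≈ x + 1/2 at large x. The raw-contrast mapping is kept as
a diagnostic. The instrument's true contrast→LSPU transfer function is not
public; the inverse-square form is the field's standard flow-index
convention, not a reconstruction, and the end-to-end tests require zone
recovery within 15 % (measured: within ~4 % for zone means, ~8 % for
windowed 60 × 60 ROI means).

Per-frame LSPU maps are averaged pixel-wise over the selected frames
(masks conjoined). ROI statistics follow the study conventions: the middle
96 frames (start = ⌊(N − 96)/2⌋), 60 × 60 px ROIs, per-frame ROI means over
valid pixels, and an across-frame mean ± sample SD as the headline summary
(the within-ROI pixel SD is also emitted, since a published SD could have
either basis).

## Study emulation

`lsci.study` regenerates the experiment's bookkeeping — 4 animals with
(5, 5, 4, 4) loops, 4 ROIs per loop, timepoints T−1/T0/T60/T120 — and draws
LSPU and lactate per (zone, timepoint) cell from normal distributions
truncated at 0, parameterised by the published means ± SDs. The lactate
schedule reproduces the published missingness (T0 watershed/ischemic lactate
in 3 loops only; one loop absent at T120), giving exactly 167 lactate
records. Two cells are not published and are flagged `non_paper` in the
output metadata: watershed LSPU at T60 (interpolated along the published
88.9 → 64.8 AU decline) and watershed lactate at T0 (interpolated,
3.0 ± 1.5 mmol/L).

In linked mode, lactate is generated from the same record's LSPU through

    lactate = b0 + b1 ln(LSPU) + ε,   ε ~ N(0, σε),

with (b0, b1) solved from the two anchor cells well@T0 and ischemic@T60 (the
extreme published operating zones; b1 ≈ −13.6, b0 ≈ 64.1) and σε = 4.0
mmol/L. σε was calibrated so that logarithmic curve estimation on the full
linked cohort reproduces the published R² ≈ 0.56 (measured 0.55 ± 0.06 at
n = 167; ~0.58 on large amplified cohorts); R² is monotone decreasing in σε.
Negative linked draws (rare) are clipped to 0.1 mmol/L.

`amplified_cohort` draws n_per_cell independent samples per (zone,
timepoint) cell, ignoring loop structure, for cut-off recovery at large n.
Note the equal cell weighting: the real design weights ischemic cells
3/18/17 across T0/T60/T120. With equal weights the Youden-optimal LSPU
threshold over the pooled ischemic vs well cells is ~71.5 AU with
sensitivity ~0.85 (the published operating point was 69 AU, 0.94/0.87);
with design-proportional weights it would be ~69 AU and ~0.92. The
published sensitivity is not reachable from the published mean ± SD
summaries under either weighting at the Youden optimum — the summaries do
not encode the empirical ROC — and the acceptance suite records this
honestly rather than adjusting the generator.

## Cut-off estimation

Candidate thresholds are the midpoints between consecutive sorted distinct
values plus one sentinel below the minimum and one above the maximum; the
scan keeps the candidate with the highest J = sensitivity + specificity − 1,
breaking ties toward the smallest threshold (labels less tissue ischemic at
equal J; the comparison uses a 10⁻¹² tolerance so float association noise
cannot flip a tie). Conventions: for LSPU, values strictly *below* the
cut-off are ischemic; for lactate, values strictly *above*; a value exactly
at the cut-off is always classified well-perfused. The estimator is exposed
both as `optimal_cutoff` and as the scikit-learn classifier
`YoudenCutoffClassifier` (fitted attributes `threshold_`, `sensitivity_`,
`specificity_`, `youden_j_`, `roc_`). A brute-force exhaustive scan is kept
in the test suite as an independent oracle.

The logarithmic calibration `log_curve_fit` is OLS of lactate on ln(LSPU)
with intercept (natural log; the base only rescales the slope, leaving R²
unchanged). Zero-variance responses flag R² as undefined rather than
returning a number.

Group comparisons are normality-gated as in the study: Shapiro–Wilk per
group at α = 0.05, Welch's t test when both groups pass, two-sided
Mann–Whitney U otherwise; two identical constant groups return p = 1 with a
warning. Welch rather than pooled variance is a deliberate safer default.

## Observer agreement

Placements are compared by signed distance *along the loop midline*:
each point is projected to its nearest position on the midline polyline
(snap radius 50 px; farther points are data errors), and the arclength
difference is scaled to cm, signed positive toward the ischemic end.
Distances are discretised into right-closed ordinal bins at ±1 cm
(toward_well / within / toward_ischemic; d = +1.0 cm is "within",
d = −1.0 cm is "toward_well"), with a dedicated category for declined
placements, which are excluded pairwise from kappa and reported as a rate.
Cohen's kappa is computed from the contingency table
(κ = (p_o − p_e)/(1 − p_e)) with a stratified bootstrap percentile CI
(2000 resamples stratified by the first rater's label, seeded); κ is
undefined (flagged) when both raters assign a single identical label. The
synthetic observer model shifts each reference mark along the midline by
N(0.6 cm, 0.8 cm) toward ischemia and declines ~3 % of placements,
emulating the reported tendency of observers to mark watershed closer to
the ischemic side; the published kappa values themselves are not
reproducible because the underlying categorisation scheme is not public,
and no attempt is made to match them.

## Pipeline and problem sizes

`run_pipeline` executes simulate → contrast → roi → study → cutoff →
agreement from one JSON-serialisable config (defaults: 7 × 7 window, middle
96 frames, 60 × 60 ROIs, inverse-square cap 200 AU, Viridis display range
30–110 AU) and writes CSV/TIFF/PNG outputs plus a manifest with a config
hash; reruns with the same seeds are byte-identical. Frame selection happens
inside the roi stage, so a recording shorter than the requested frame count
aborts with that stage's name.

The test and acceptance runs use deliberately desk-scale problem sizes —
single-frame 128² uniform phantoms for the physics checks, 512² phantoms
with a handful of frames for end-to-end recovery, 2000 draws per cell and
five seeds for cut-off recovery — chosen so the full suite completes in a
few minutes while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- The simulator omits sensor-area integration, lens aberrations, rolling
  shutter, motion artifacts and any proprietary motion compensation.
- Exposure time, frame rate and bit depth of the clinical device are not
  public; the defaults (5 ms, contiguous frames, 16-bit) are simulator
  choices surfaced in the config.
- The emulated cohort has no inter-animal or within-loop correlation
  structure (the study itself could not estimate inter-animal effects), so
  mixed-model analyses on the exported tables will find no random-effect
  variance beyond sampling noise.
- Systemic lactate is not emulated; the published systemic range is
  internally inconsistent with normal physiology and is left alone.
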