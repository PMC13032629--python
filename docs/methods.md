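# Methods

## Measurement model

All reflectometry operates on 8-bit single-channel rasters (rows = axial
depth, row 0 toward the vitreous; columns = lateral position). RGB input is
reduced with BT.601 luma weights (0.299, 0.587, 0.114) — the default
RGB→8-bit conversion of common image tooling — rounded half-to-even and
clamped to [0, 255]; the weights are configurable.

A measurement line is a straight segment rasterized Bresenham-style: one
sample per pixel of the major axis, the minor coordinate being the nearest
pixel to the ideal line with exact half-pixel ties rounded away from the
start. This rule is fully specified so that a brute-force pixel walk can
verify the sampler exactly; interpolated ("thick") sampling is available via
`width_px > 1`, which averages across perpendicular integer offsets before
taking the min/mean/max of the profile. Profile statistics are computed on
integer intensities; all index ratios are floating point.

The five indices derive from four profiles (central hyperreflective,
paracentral hyporeflective left and right, normal RPE). The two paracentral
sides are aggregated conservatively: the minimum statistic takes the minimum
across both sides, the mean statistic the arithmetic mean of the two side
means. Both conventions are implemented in one place (`compute_indices`) so a
per-side variant is a local change. By construction MHRI × PCRI-Min =
CRI-Max whenever all three come from one measurement; this identity is
asserted in tests and in the result dataclasses.

Region placement is manual (explicit segments, or a CSV of endpoints) or
automatic. The automatic locator detects the RPE band as the per-column
maximum of the Gaussian-smoothed image, computes a per-column band
brightness, and takes the central region as the contiguous above-median run
of columns at the hole base, with the paracentral regions as the below-median
runs immediately flanking it. The normal-RPE reference is a 200 µm segment
placed ≥ 1500 µm from the hole centre — a convention, since clinical practice
leaves the reference location to the grader; it is far enough to clear the
hole base of any plausible hole (MLD < ~900 µm at default scales) while
staying inside a standard 5–6 mm scan. Detected runs are shrunk by one
column so samples stay interior to their regions.

The MLD is measured on the tissue mask above the band (threshold = midpoint
of the 10th/90th intensity percentiles after a 3×3 median filter; a global
Otsu threshold is unreliable because the dark vitreous dominates the
histogram). For each row with tissue on both sides of the hole the gap width
is computed; the MLD is the minimum gap × lateral scale. Edge-annotated input
is supported directly (`mld_from_edges`), with the convention that the two
annotated columns are the first gap column and the first right-edge column,
so MLD = (right − left) × scale.

## Phantoms

`synthetic_oct` renders one B-scan per phantom: a bright RPE/Bruch band
(9 px thick), inner retina with a full-thickness defect whose inner edges are
elevated (the narrowest separation — the MLD — sits `edge_elevation_px` above
the band and the gap widens above and below it), and at the hole base a
central hyperreflective plateau flanked by hyporeflective paracentral
plateaus extending under the overhanging edges. Default intensities
(RPE 180, central 210, paracentral 120, retina 90, background 20) give
MHRI = 1.75, CRI-Max ≈ 1.17 and PCRI-Min ≈ 0.67 — within the clinically
reported range. Default pixel scales are 10 µm laterally and ~4 µm axially
(typical SD-OCT); both are explicit metadata, never hard-coded downstream.

Speckle is multiplicative: a unit-mean Gamma field with standard deviation
`speckle_level` (shape 1/level²), smoothed by a Gaussian of
`speckle_grain_sigma_px` (default 1.5 px) before being applied. The smoothing
models the finite speckle grain of frame-averaged clinical scans (raw
i.i.d. per-pixel noise would make extreme-value statistics like a profile
maximum biased upward by ~2 standard deviations regardless of acquisition
quality, which is not how averaged clinical B-scans behave). Noise-free
structure is never blurred, so truth recovery on noise-free phantoms is exact
to 8-bit quantization; identical (config, seed) pairs are bit-identical.

What the phantoms do **not** emulate: the full retinal layer stack, vascular
shadowing, curvature of the RPE, raster geometry of a clinical volume, or
operator variability in line placement. Passing the recovery tests therefore
shows that the measurement chain is correct and robust to residual speckle —
not that automatic placement would work on arbitrary clinical scans.

## Cohort simulator

One eye = one record. Closure failure is Bernoulli (default 3/48). Within
each closure group, (MHRI, MLD) are drawn from a bivariate Gaussian with the
group means/SDs observed in the 48-eye case series (success 1.42 ± 0.16 and
300.4 ± 71.8 µm; failure 2.24 ± 0.69 and 433.3 ± 21.3 µm), correlation 0.45
(near the observed r = 0.447), truncated to positive values by resampling.
Post-operative logMAR VA is linear in MHRI, MLD and pre-operative VA with a
Gaussian residual, floored at 0:

    postVA = −1.65 + 0.58·MHRI + 0.003·MLD + 0.20·preVA + N(0, 0.10)

The coefficients are **calibration choices**, not observed quantities: the
source analysis reports only adjusted coefficients for MHRI (0.581) and MLD
(0.003) plus rank correlations, so the intercept, pre-VA weight and residual
scale were set once so that the simulated success-group post-VA mean (~0.3),
its visual-success share (~58%), and the Spearman correlations with MLD
(~0.86) and pre-VA (~0.2–0.3) sit near the reported magnitudes. The reported
rank correlation for MHRI is printed with a negative sign in the source's
correlation table, which contradicts its own positive adjusted coefficient
and narrative; the simulator follows the regression signs. Age, sex, lens
status and surgery type are drawn independently at the cohort's marginal
frequencies (no associations were reported for them). Rater 1/2 MHRI values
are the true index plus independent Gaussian noise (default SD 0.02, giving
ICC ≈ 0.98, as observed).

Because a 48-eye cohort contains ~3 failures, single-cohort anatomical ROC
results are intrinsically unstable; `closure_failure_prob` is exposed so
stochastic tests can inflate the failure rate, and the acceptance script also
reports a Monte-Carlo mean AUC across repeated cohorts.

## Statistics

- **ROC / cutoffs.** AUC is the normalized Mann-Whitney statistic (ties 0.5).
  Cutoff candidates are midpoints between consecutive distinct scores (the
  reported cutoffs such as 313.5/404.5 µm are exactly such midpoints); the
  Youden-maximal candidate wins, ties broken toward higher specificity, then
  the lower threshold. Orientation is auto-resolved so AUC ≥ 0.5: MHRI and
  MLD are higher in failure, so the positive-class ("success") rule is
  reported as *score < cutoff* with `direction = "lower"`. The AUC CI is a
  seeded stratified bootstrap (2000 replicates, percentile) by default;
  DeLong is available. An all-tied score vector yields a degenerate result
  (AUC 0.5, no cutoff) rather than an error. The ROC p-value is the
  two-sided Mann-Whitney test between classes.
- **Group tests.** Shapiro-Wilk on each group at α = 0.05 dispatches to
  Student's t (both normal) or Mann-Whitney U, which is exact when
  min(n) ≤ 8 with no ties and otherwise uses the tie-corrected normal
  approximation — a repo convention; at n = 3 vs 45 the exact two-sided
  minimum attainable p is 2/C(48,3) ≈ 1.16 × 10⁻⁴, so "p < 0.0001" claims at
  those sizes imply a normal approximation. 2×2 categorical tables use
  Fisher's exact test; pre/post VA the paired t-test. No multiple-testing
  correction is applied (matching the source analysis); every table reports
  which test produced each p.
- **Agreement.** ICC(2,1) — two-way random effects, absolute agreement,
  single measurement — from the two-way ANOVA mean squares (the variant label
  is always attached, since "ICC" alone is ambiguous); cross-checked against
  pingouin in tests. Bland-Altman: bias = mean(r1 − r2), LOA = bias ± 1.96 ×
  sample SD (ddof 1).
- **Regression.** OLS of post-VA on MHRI, MLD, age, pre-VA and surgery type
  (0/1), restricted to closed eyes, with both indices entered jointly (their
  VIFs are reported together in the source, implying one model). VIFs come
  from auxiliary regressions with the intercept included; tolerance = 1/VIF.
  Rank-deficient designs error and name the collinear columns.
- **Outcomes.** Visual success is post-VA ≤ 0.3 logMAR, boundary inclusive,
  defined only among closed eyes; closure failures never enter a visual
  denominator, while anatomical analyses always use all eyes.

## Problem sizes and numerical conventions

Stochastic suites run at: 200 speckle replicates for the 5%-recovery check,
5000 null replicates for Mann-Whitney size, 1000 simulated rater pairs
(n = 200) for LOA coverage, n = 2000 cohorts for regression recovery, and
100 random instances for each exact-oracle equivalence (AUC vs pairwise
enumeration, line profiles vs pixel walk, Fisher vs hypergeometric
summation). Coordinates are 0-based (row, col) with half-open column
intervals. Intensities are integers after conversion; indices are floats;
report tables round indices and J to 2 decimals and percentages to 1,
matching the source's presentation.

## Known limitations

- Automatic region placement is validated on phantoms only; clinical scans
  with drusen, RPE atrophy or heavy shadowing would need manual segments
  (supported via CSV).
- The cohort simulator reproduces marginals, one correlation and a linear VA
  model — not the full joint distribution of a real case series; tests
  passing on it validate the statistical machinery, not clinical effect
  sizes.
- The exact Mann-Whitney path is limited to min(n) ≤ 8 without ties; larger
  exact enumeration is out of scope.
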