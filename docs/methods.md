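# Methods

## Two-sample plasma clearance

The late plasma concentration of Tc-99m-DTPA after the distribution phase
is modelled as mono-exponential, `P(t) = P0·e^(−kt)`.  With injected dose
`D` (same counting calibration as the plasma samples) and samples
`(P1, T1)`, `(P2, T2)` in minutes, the slope-intercept clearance is

    tGFR = D·ln(P1/P2)/(T2−T1) · exp[(T1·lnP2 − T2·lnP1)/(T2−T1)]
         = D·k/P0                        (for the exact mono-exponential)

Implementation note: the exponent `(T1·lnP2 − T2·lnP1)/(T2−T1)` suffers
catastrophic cancellation (it equals `−ln P0`, a small difference of two
large products), so the code evaluates the algebraically identical form
`D·(L/Δt)·e^(−T1·L/Δt)/P1` with `L = ln(P1/P2)`.  The residual error of
the reconstruction is then a few ULP under realistic conditions; it grows
like `ε/(k·Δt)` as the two samples approach each other, which is a
conditioning property of the two-sample design itself, not of the code.

No Brøchner-Mortensen (single-compartment overestimation) correction is
applied by default — the uncorrected slope-intercept value is the method's
reference tGFR; a correction hook exists.  Plasma counts are not
decay-corrected by default (both samples are assumed counted in one
session); `decay_correct_counts` with half-life 6.0058 h covers split
sessions.

BSA normalisation uses DuBois (`0.007184·W^0.425·H^0.725`) by default,
Haycock as an option, scaling to the 1.73 m² reference.  Whether the tGFR
fed into the split combination is BSA-normalised is configurable
(`pgfr_uses_bsa_tgfr`, default on, matching the standard reporting unit
mL·min⁻¹·(1.73 m²)⁻¹); the split fraction itself is scale-free, so the
choice does not affect the ratio or the concordance conclusions.

## Gates processing

Per kidney: counts in the uptake window 120–180 s post-injection (frames
weighted by fractional overlap), minus the predicted background
(conventional variant only: mean background-ROI counts per pixel × kidney
pixel count, per side), divided by the attenuation factor `e^(−μ·depth)`
and by the injected-dose equivalent `net dose rate × window length`.
Total uptake (percent) maps to GFR through the Gates regression
`GFR = 9.8127·U% − 6.82519`, clamped at zero; per-kidney values split the
total in proportion to corrected counts.  Constants and their sources
(Gates 1982 regression; Tønnesen depth `13.2·W/H + 0.7` left,
`13.3·W/H + 0.7` right; μ = 0.153 cm⁻¹ for 140 keV in soft tissue) live in
one `ToolConfig` block and are overridable.

Choices where the field's practice varies:

* **Uptake window** defaults to the classic 2–3 min interval
  ([120, 180) s), configurable.
* **Posterior view only** by default; a geometric-mean
  `√(anterior·posterior)` mode exists but is off, since classic Gates
  processing is posterior-view.
* **Negative background-subtracted counts clamp to zero** with a warning —
  degenerate but plausible with noisy data; an error would make batch
  processing brittle.
* Syringe-count decay correction is off by default, with a flag for
  acquisitions where the full-syringe counting happens long before
  injection.

The blank-background variant (gGFR') simply omits the subtraction, so
gGFR' ≥ gGFR always; its purpose here is not an unbiased absolute GFR but
a left:right ratio untouched by the single most rater-dependent input.

## Precise split combination

`pGFR_s = gGFR'_s/(gGFR'_L + gGFR'_R) · tGFR`.  The right kidney is
computed as `tGFR − pGFR_left`, making the conservation
`pGFR_L + pGFR_R = tGFR` exact in floating point (the quotient form agrees
to rounding).  Zero summed uptake is an error (nothing to apportion).

## Concordance statistics

Kendall's W with average ranks for ties and the standard tie correction:
`W = 12S/(m²(n³−n) − m·ΣT)`, `S = Σ(R_i − R̄)²`, `T = Σ(t³−t)` per rater;
`χ² = m(n−1)W` with `n−1` df for the p-value (an exact permutation p is
available for small tie-free tables).  A constant table leaves W undefined
and raises.  For per-kidney measures, left and right kidneys are stacked
as separate concordance subjects (n = 2 × patients) by default, since a
single W per method over split-kidney values is the standard summary; a
per-kidney mode exists.  Pearson correlation (with `r² = r·r ≥ 0`) is
delegated to scipy.

## The phantom

What it emulates: the standard acquisition (30 × 2 s + 20 × 60 s frames,
64 × 64 matrix, posterior view), two elliptical kidneys with per-subject
geometry variation, a biexponential blood pool whose slow rate is the
subject's clearance over a ~15 L distribution volume, renal accumulation
proportional to the time-integral of the blood pool and calibrated so that
the window-mean renal content corresponds (through the Gates regression)
to the true total GFR, attenuation by true Tønnesen depths, a spatially
uniform tissue background (8% of the dose rate spread over the image),
a Gaussian detector PSF (σ = 1.2 px), Poisson counting noise everywhere
(images, syringe counts, plasma counts), and plasma samples at 120/240 min
drawn from the mono-exponential late component.

Truth distributions are the study conditions: total GFR ~ Normal(89.62,
46.57²) mL/min truncated above 5, split fraction ~ Uniform(0.2, 0.8).
Biometrics are drawn from adult ranges (height 167 ± 8 cm, weight
68 ± 12 kg, clipped).

Rater variability: each of the (default five) raters gets kidney masks
shifted by ±1 px and dilated/eroded by ±1 px, and background rings
independently shifted by ±3 px.  No published inter-rater magnitudes
exist for this, so these are synthetic calibration values chosen once to
make background placement the dominant disagreement channel — the causal
mechanism under study, since it perturbs only the conventional variant.
Under these defaults the five-rater concordance of pGFR exceeds that of
conventional gGFR in every tested cohort (~0.97 vs ~0.92 at n = 30), i.e.
the qualitative ordering, not any particular pair of W values.

What it does **not** emulate — and hence what passing tests do not show
about real data: anatomical realism (no pelvicalyceal retention, no liver
or spleen uptake, no patient motion), scatter and septal penetration,
dead-time, non-uniform background (the uniform background makes
conventional subtraction *too* easy, so real-world conventional W is
likely worse, not better, than simulated), and systematic inter-observer
styles (jitter is unbiased noise, real raters have biases).  The phantom
is deliberately self-consistent with the configured Gates regression, so
absolute-GFR accuracy of the Gates chain is not a claim being tested —
ratio recovery and rater-agreement behaviour are.

## Numerical and degenerate-input choices

* Frame counts are non-negative reals: acquisitions are integer counts,
  expectation-mode (noise-free) phantoms are not rounded, so formula-level
  checks are exact.
* Window weighting uses fractional frame overlap; a window outside the
  acquisition span is an error.
* Erosion that would empty a jittered rater mask falls back to the
  unjittered mask; jittered kidney masks are kept disjoint and background
  rings are clipped away from kidney pixels, so every generated ROI set
  passes study validation.
* Seeds: one top-level cohort seed; per-subject and per-rater generators
  are spawned from it (`SeedSequence([seed, subject])`,
  `SeedSequence([rater_seed, subject, rater])`), so cohorts are bit-
  reproducible and subjects are independent.

## Problem sizes

Default validation cohorts are 30 subjects × 5 raters; the concordance
ordering is additionally checked over 20 independent cohorts, and
formula-level oracles run at 1000 random draws.  These sizes give stable
statistics (the ordering reproduces in 20/20 cohorts) while a full test +
acceptance run stays in the tens of seconds on one CPU.

## Known limitations

* The blank-background ratio is biased toward 50/50 by whatever true
  background lies under the kidney ROIs; at the default background level
  this contributes most of the ~0.04 mean absolute split-fraction error.
* The Gates regression's absolute calibration is built into the phantom
  (see above), so cross-calibration against an independent reference is
  out of scope.
* Exact permutation p-values are limited to small tie-free tables; large
  tables use the chi-square approximation, which is what the intended
  cohort sizes need anyway.
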