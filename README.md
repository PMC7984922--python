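# splitgfr

Precise quantification of **split (per-kidney) glomerular filtration rate**
by combining Tc-99m-DTPA dynamic renal scintigraphy with two-sample plasma
clearance — plus a compartmental phantom simulator so the whole chain can be
validated with known ground truth.

## The problem

Camera-based (Gates-method) renography is the only routine way to measure
*per-kidney* function, but its absolute numbers are fragile: they depend on
how each physician outlines the kidney and background regions of interest,
on the depth/attenuation correction, and on the net-dose measurement.  The
two-sample plasma clearance (slope-intercept) method gives an accurate
*total* GFR (tGFR) but says nothing about the left/right split.  This
package implements the combination: use blank-background Gates processing
only for the left:right ratio, and anchor the absolute scale to the plasma
tGFR,

```
pGFR_left  = gGFR'_left  / (gGFR'_left + gGFR'_right) · tGFR
pGFR_right = gGFR'_right / (gGFR'_left + gGFR'_right) · tGFR
```

where gGFR' is the per-kidney Gates GFR computed *without* background
subtraction (the background ROI being a dominant source of inter-rater
disagreement).  Agreement between raters is quantified with Kendall's
coefficient of concordance W.

## What is implemented

* **Two-sample plasma clearance** (`splitgfr.plasma`):
  `GFR = D·ln(P1/P2)/(T2−T1) · exp[(T1·lnP2 − T2·lnP1)/(T2−T1)]` for a
  mono-exponential late plasma phase; DuBois/Haycock body-surface-area
  normalisation to 1.73 m².
* **Gates processing** (`splitgfr.gates`): ROI time-activity curves, net
  injected dose from syringe counting, renal uptake in the 120–180 s
  window, Tønnesen depth estimate with `e^(−μd)` attenuation correction
  (μ = 0.153 cm⁻¹), the Gates uptake→GFR regression, and both the
  conventional (background-subtracted, gGFR) and blank-background (gGFR')
  variants.
* **Split combination and statistics** (`splitgfr.stats`): the pGFR
  formula with exact left+right = total conservation; tie-corrected
  Kendall's W with chi-square (or exact permutation) p-values; Pearson
  correlation.
* **Phantom simulator** (`splitgfr.phantom`): dynamic 64×64 renograms
  (30 frames × 2 s + 20 frames × 60 s), two-compartment kinetics with known
  total GFR and split fraction, Poisson counting noise, plasma samples at
  2 h/4 h, and five simulated raters with jittered ROIs.
* **I/O and CLI** (`splitgfr.io`, `splitgfr.cli`): a single-archive study
  container, DICOM NM multi-frame reading/writing, CSV tables, and the
  `splitgfr` command with `simulate`, `gates`, `plasma`, `pgfr`,
  `concordance` and `full` subcommands.

## Worked example

Combine per-kidney blank-background Gates values with a plasma tGFR:

```
$ splitgfr pgfr --left 38.5 --right 51.2 --tgfr 84.3
{
  "pgfr_left": 36.18227424749164,
  "pgfr_right": 48.117725752508356,
  "tgfr": 84.3,
  "split_fraction_left": 0.42920847268673357
}
```

The left kidney contributes 42.9% of the gGFR' total, so it is assigned
42.9% of the 84.3 mL/min plasma tGFR (36.2 mL/min); the two kidneys sum
back to the total exactly.

An end-to-end simulated study (5 subjects, 5 raters):

```
$ splitgfr full --n 5 --raters 5 --seed 42 --out demo/
{
  "w_pgfr": 0.9815757575757575,
  "w_ggfr_conventional": 0.9563636363636364,
  "p_pgfr": 1.3126733850521233e-06,
  "p_ggfr_conventional": 2.122730027772529e-06,
  "split_fraction_mae": 0.04784214386475962,
  "tgfr_mean_abs_rel_error": 0.013833018067740043,
  "n_subjects": 5,
  "n_raters": 5,
  "seed": 42
}
```

`w_pgfr > w_ggfr_conventional`: the five simulated raters agree more
closely on the precise split values than on conventional Gates values,
because the background-ROI placement they disagree about most does not
enter the pGFR chain.  The split fraction is recovered to ~0.05 mean
absolute error and the plasma total to ~1.4% under the default noise
model.  `demo/per_patient.csv` holds the per-rater gGFR, gGFR', tGFR and
pGFR values behind the summary.

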