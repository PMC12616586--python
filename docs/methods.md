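# Methods

## Overview

`renoximetry` implements whole-organ renal oximetry from quantitative MRI.
The measurement chain is: a T2-prepared magnitude image series at increasing
effective echo times yields blood-water T2 at a renal vessel; a calibration
model converts T2 to venous oxygen saturation (SvO2); phase-contrast velocity
maps at the same slice yield blood flow rate (BFR); and Fick's Principle
combines these with arterial saturation (SaO2, from pulse oximetry),
hematocrit and kidney mass into the renal metabolic rate of oxygen (rMRO2).
Because no subject-level source data is publicly available, the package ships
a forward simulator that generates cohorts and image-level acquisitions with
the statistical structure of a four-stage graded isocapnic-hypoxia study in
ten healthy adults (baseline, mild hypoxia at target end-tidal O2 62 mmHg,
moderate hypoxia at 52 mmHg, recovery), so every analysis stage is testable
end to end.

## Metabolic model

Unilateral rate for one kidney, in (μmol O2/min)/100 g:

    rMRO2 = CRBC · Hct · BFR · (SaO2 − SvO2) / m_kidney · 100

with CRBC = 19.93 μmol O2/mL RBC, BFR in mL/min, saturations as fractions,
and kidney mass in grams (from segmented volume × tissue density 1.06 g/mL).
Hematocrit derives from hemoglobin by Hct(%) = Hb(g/dL)/0.34.  SaO2 − SvO2 is
the arteriovenous difference in oxygen saturation (AVDO2).

The bilateral rate uses the suprarenal/infrarenal inferior vena cava (IVC)
flow difference, which equals the total renal venous outflow:

    bilateral rMRO2 = CRBC · Hct / m_total · [QVs(SaO2 − SvO2s) − QVi(SaO2 − SvO2i)] · 100

where the combined venous saturation is the flow-weighted average
(QVs·SvO2s − QVi·SvO2i)/(QVs − QVi).  Both the difference form and the
flow-weighted mixing form are implemented and asserted algebraically equal.
Negative rates and out-of-range mixed saturations are returned with warnings,
never clipped: the bilateral estimator is strongly error-amplifying (see
*Sensitivity* below) and silently sanitized values would hide exactly the
behaviour the method comparison is about.

## T2 relaxometry

ROI-mean signal across the effective TEs is fit to S(TE) = S0·exp(−TE/T2).
Default fitter is nonlinear least squares (equal weights) initialized from
the closed-form log-linear solution; the log-linear fitter is available
directly, and S0 can optionally be pinned to the earliest-TE signal.
Non-decaying series and non-positive signals under the log fitter raise
explicit errors rather than clamping.  No Rician-floor offset term is fit:
background suppression keeps the floor small over the venous T2 range
(71–161 ms) at the default TE schedule; the simulated bias study (below)
quantifies the residual effect (median bias < 1% at per-pixel SNR 50).
Fits are per acquisition on ROI means; per-pixel mapping is out of scope.

## T2–SvO2 calibration

The calibration follows the standard Luz–Meiboom-type exchange form,
quadratic in the deoxygenated fraction with hematocrit-dependent
coefficients: R2 = A(Hct) + B(Hct)(1−Y) + C(Hct)(1−Y)², each coefficient a
quadratic polynomial in Hct.  Coefficient sets are named, versioned and
swappable via YAML.  The shipped default (`venous-3t-anchored-v1`,
τ_CPMG 10 ms) uses the literature exchange form C = 247.4·Hct·(1−Hct) s⁻¹
and anchors A (linear in Hct with a ~1 s⁻¹ plasma intercept) and B
(proportional to Hct) to venous reference pairs at Hct 0.42
(T2 159 ms ↔ Y = 0.92 and 100 ms ↔ 0.76, representative renal-vein values at
3 T).  This is a package calibration choice, not a reproduction of any
specific published coefficient table; consistency with renal-vein
observations is asserted only to within ±6 percentage points of saturation.
The inverse solves the quadratic in closed form and returns the root on the
monotone branch; T2 values outside the admissible interval at the given Hct
fail loudly with the interval in the message (clamping would bias AVDO2).

## Flow quantification

Per velocity map, BFR = (ROI-mean signed velocity) × (mask pixel count ×
pixel area) × 60, averaged across the five interleaves of an acquisition —
velocities are averaged within a map, flows across maps, in that order.  ROI
area is mask pixel count × pixel area with no sub-pixel contour integration,
consistent with the simulator's mask rendering.  No phase unwrapping is
implemented; the simulator guarantees |v| < VENC and real-data inputs
exceeding VENC raise a warning.  A shared mask is used across the five maps
of an acquisition.

## Synthetic cohort generator

Demographics, hemoglobin and kidney masses are truncated normal draws with
the healthy-cohort summary statistics (e.g. left kidney 172 ± 29 g, range
124–226 g; Hct 42 ± 4%, range 34–46%, derived from hemoglobin by the 0.34
rule).  Because several reported ranges are asymmetric about the mean (age
30 ± 9, range 23–53), each truncated normal recenters its underlying normal
so the truncated distribution's mean equals the reported mean exactly.

Per-condition physiology (SaO2; SvO2 and BFR at the left renal vein,
suprarenal and infrarenal IVC) uses the reported per-condition means and SDs.
Three structural choices:

* **Within-subject correlation.**  Only marginal means/SDs are reported, but
  repeated-measures inference needs a within-subject structure.  Each
  parameter channel receives a per-subject latent z-score contributing 50% of
  the marginal SD to every condition (configurable); the condition-level
  innovation carries the remaining variance, so marginals are preserved while
  repeated measures correlate at ~0.25.
* **IVC flow coupling.**  Drawing suprarenal and infrarenal flows
  independently and rejecting negative differences would inflate the
  suprarenal mean by ~90 mL/min, because the reported ΔBFR SD (180 mL/min at
  baseline) implies a site correlation near 0.97.  The generator instead
  draws infrarenal flow and the outflow difference ΔBFR from their reported
  distributions and sets suprarenal = infrarenal + ΔBFR.  This makes the
  difference positive by construction, reproduces the ΔBFR row exactly, and
  keeps suprarenal means within the printed tens-rounding of the reported
  values.
* **Venous below arterial.**  SvO2 draws are redrawn until strictly below the
  same condition's SaO2 draw.

Image-level rendering: the vessel is a single ellipse per slice
(partial-volume edge pixels included in the mask; no sub-pixel rendering — a
documented simplification).  T2-prepared vessel pixels decay mono-
exponentially with T2 from the calibration at the subject's hematocrit and
the site's true SvO2; background pixels carry a 2% suppressed signal; Rician
noise (magnitude statistics) applies everywhere, default scale S0/50.
Velocity maps carry a parabolic (Poiseuille) laminar profile scaled so the
discrete ROI mean × area × 60 equals the true BFR exactly, with zero-mean
Gaussian noise (phase statistics), default 0.5 cm/s; rendering refuses
profiles whose peak exceeds VENC.  Effective TEs default to
{0, 40, 80, 160, 240} ms, spanning the venous T2 range; the schedule is
configurable since the exact sequence timing is an acquisition detail.  One
acquisition is five images of each kind; repeat acquisitions per condition
(default five) are averaged downstream at the derived-parameter level.

What the simulator does **not** emulate: k-space sampling and reconstruction,
coil sensitivities, motion, eddy-current/background phase, vessel pulsatility,
segmentation errors (masks are ground truth), and regional (cortex/medulla)
heterogeneity.  Passing closed-loop tests therefore demonstrates correctness
of the analysis chain under the stated noise models, not robustness to those
real-data effects.

## Statistics

One-way repeated-measures ANOVA per parameter × site across the four
conditions, from the standard within-subject sums-of-squares decomposition
(F = MS_condition/MS_error on (k−1, (k−1)(n−1)) df).  Subjects missing any
condition are excluded listwise from inference but kept in descriptive
summaries.  No sphericity correction is applied by default;
Greenhouse–Geisser is available as an option with the epsilon reported.
Post-hoc tests are paired two-sided t-tests over all condition pairs with
Bonferroni adjustment by multiplication (adjusted p = min(1, 6·raw p) for
four conditions); pairs with zero difference variance are reported as
incomparable rather than p = 1.  Reporting-layer rounding: flows and rates to
the nearest ten (half away from zero), saturations to whole percent, T2 to
whole ms; all internal math is full precision, and per-subject rates are
computed before cohort averaging.

## Sensitivity

First-order propagation through the unilateral equation gives
∂rMRO2/∂SvO2 = −rMRO2/AVDO2, so at baseline means (AVDO2 = 7%) a
2-percentage-point SvO2 error produces a 0.02/0.07 ≈ 28.6% relative rate
error, versus 5% from a 5% relative BFR error — the Fick equation is
dominated by venous-saturation error.  A Monte-Carlo propagator (independent
Gaussian draws, ≥1000 samples) cross-checks the linear form; the two agree
within 5% at small input CVs.

## Validation studies and problem sizes

* **Closed loop** — all population SDs and noise set to zero; the full
  simulate → fit → invert → quantify chain returns every generating mean cell
  to < 1e-6 relative (measured ~1e-14).  Note that derived cells (rMRO2,
  AVDO2 at recovery, bilateral rates) are compared against the arithmetic of
  the generating means, which for some cells differs from published rounded
  summary rows computed per subject — e.g. plug-in of means gives a mild-
  hypoxia unilateral rate of 150 where the per-subject cohort average is 180,
  and a near-zero bilateral rate at baseline means, itself an illustration of
  the bilateral estimator's error amplification.
* **Stochastic recovery** — 100 replicate cohorts of n = 10 with one
  acquisition per condition/site on a 48×48 matrix; for every generated
  channel the cohort-mean estimate lands within one population SD of the
  generating mean in ≥ 95% of replicates (measured 99–100%).
* **Desaturation power** — 500 replicates of the baseline-vs-moderate
  renal-vein SvO2 contrast (92 → 76, SD 5, n = 9, within-subject correlation
  as generated): Bonferroni-adjusted p < 0.05 in ≥ 90% of replicates
  (measured 100%).
* **Relaxometry bias** — 1000 replicates per T2 in {71, 100, 130, 161} ms at
  per-pixel SNR 50: median fitted T2 within 2% of truth (measured ≤ 0.7%,
  worst at the short-T2 end where the Rician floor matters most).

These study sizes are the package's defaults; they complete in about a
minute on a single CPU and are rerun from scratch by
`scripts/acceptance.py`.

## Numerical choices and degenerate inputs

Zero-SD distributions return their mean exactly.  The quadratic calibration
inverse falls back to the closed-form linear solution when C = 0.  The decay
fitter requires ≥ 3 points and strictly raises on non-decaying input.  ANOVA
raises a dedicated error on zero within-subject error variance (0/0 F)
instead of propagating NaN.  All generators are pure functions of their
inputs and a seed; the pipeline derives per-stage, per-subject,
per-acquisition seeds from one root seed, so identical configurations
reproduce identical output files byte for byte (images are written as
uncompressed NIfTI partly for this reason).

## Known limitations

Single-ellipse vessel geometry without sub-pixel partial-volume modeling;
no per-subject calibration (one coefficient set for all subjects); no
field-strength or sequence-timing re-derivation of calibration coefficients;
whole-organ rates only; no motion/discard simulation; the subject-level
random effect is a single shared factor per channel rather than a full
covariance model.
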