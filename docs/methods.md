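# Methods

`weanwave` implements a biosignal-variability analysis of spontaneous
breathing trials (SBTs): feature extraction from multichannel ICU
recordings, two-group comparison under rank-indexed multiple-comparison
thresholds, and a prediction study comparing the bedside RSBI rule with
models that add biosignal features. Because real SBT cohorts of this
kind are not publicly distributable, the package ships a synthetic
cohort generator as first-class, tested code; every pipeline stage is
exercised against it.

## Data model and preprocessing

A patient record holds waveform channels (ECG, photoplethysmogram,
respiratory impedance, arterial blood pressure) at ≥ 62.5 Hz, numeric
vitals (HR, RR, mean arterial pressure) at 1 Hz, a per-breath ventilator
series (tidal volume in mL, inspiratory/expiratory times in s) and the
weaning outcome label. Records round-trip through plain-text bundles
(`metadata.json` + one CSV per channel) losslessly: floats are written
with 17 significant digits, so repeated writes are byte-identical.

Waveforms are brought to a common 62.5 Hz by polyphase rational
resampling with a linear-phase FIR low-pass at 0.8× the target Nyquist
(25 Hz) applied before decimation. The long kaiser filter (64 taps per
decimation unit) keeps the passband flat to roughly 0.7× Nyquist, so
band-limited content loses < 1 % energy while aliasing cannot corrupt
the entropy estimates downstream. Analysis uses the **middle window**
of the trial — by default the central 10 min of a 30-min SBT, the
half-open interval `[(D−w)/2, (D+w)/2)` with 0-based indexing, giving
exactly 37,500 samples at 62.5 Hz and 600 at 1 Hz. Samples carry no
per-sample timestamps; time is `start_offset + i/rate`.

## Variability indices

**Poincaré geometry.** For a series `x_1..x_N` the lag-1 return map
`(x_n, x_{n+1})` is summarised by SD1 (spread perpendicular to the
identity line, short-term variability) and SD2 (spread along it,
long-term variability), computed by the closed forms
`SD1² = Var(x_{n+1}−x_n)/2`, `SD2² = Var(x_{n+1}+x_n)/2` with population
variance — exactly the 45°-rotation construction, which the tests
verify to 1e-10. Variances that are pure floating-point cancellation
(constant series with a large offset) are clamped to zero; an SD2 of
zero leaves the ratio flagged undefined rather than raising or emitting
a silent 0. Applied to the per-second HR/RR/MAP series and to the
per-breath tidal-volume, I:E-ratio and inspiratory-time sequences
(their natural sampling).

**Sample entropy.** `SampEn = −log(A/B)` where `B` counts unordered
pairs of length-`m` templates within Chebyshev tolerance `r`
(self-matches excluded; both template sets use the first `N−m` starting
points) and `A` the same at length `m+1`. Defaults `m = 2`,
`r = 0.2 × SD` of the analysis window — the Richman–Moorman convention —
which makes the estimate invariant under affine rescaling. `A = 0` or
`B = 0` yields an undefined (masked) value. The production path counts
pairs by dual-tree traversal on a k-d tree (`cKDTree.count_neighbors`,
Chebyshev metric), which returns *identical* counts to the naive O(N²)
scan (asserted exactly on random series); a `stride` parameter
subsamples long waveforms for desk-scale runs (the cohort-level tests
use stride 4, i.e. an effective 15.6 Hz; stride 1 is the default and
the exact setting).

**Detrended fluctuation analysis.** The mean-centred series is
integrated; for each box size `n` the profile is split into
non-overlapping boxes, each linearly detrended, and `F(n)` is the RMS
residual. The exponents are least-squares slopes of `log F` vs `log n`:
`alpha1` over the short band, `alpha2` over the long band,
`alpha1/alpha2` as their ratio. **Scale-band choice:** first-order DFA
with boxes of 4–16 samples has a well-known upward small-scale bias —
measured here, white noise reads ≈ 0.59 and fractional Gaussian noise
(fGn) overestimates its Hurst index by ≈ +0.07. The package therefore
defaults to log-spaced bands of 10–40 samples (alpha1) and 40–160
samples (alpha2), chosen from a pre-freeze bias scan: with them white
noise reads 0.516 ± 0.016 and fGn recovers H ∈ {0.3, 0.5, 0.7, 0.9}
within ±0.02 in the mean. Both bands are configurable; a constant
input (`F(n) = 0`) is flagged undefined. The minimum series length is
4× the largest box (640 samples at the defaults).

**RSBI** is breaths/min divided by mean tidal volume in litres,
computed over the same middle window (the convention adopted here;
whether the original bedside value is taken at trial start is
protocol-dependent). The classification rule predicts failure at
RSBI ≥ 105.

The per-patient feature vector has 34 variability entries (18 Poincaré,
16 waveform) plus RSBI, with a mask that records absent channels and
undefined ratios; masked values propagate as empty cells, never as 0.

## Group comparison and thresholds

Each feature is compared between outcome groups by a two-sided
Mann-Whitney U test (exact enumeration for combined n ≤ 12 without
ties, otherwise the tie- and continuity-corrected normal
approximation). With `m` testable features, the i-th smallest p-value
receives the threshold `alpha_adj = α·i/m`, `α = 0.1` (a permissive
level chosen to admit more candidate predictors). The default decision
rule is the **literal per-rank rule** — feature `i` is significant iff
`p_(i) < α·i/m` at its own rank. This is deliberately *not* the
Benjamini–Hochberg step-up (available as `mode="step_up"`): the
per-rank rule is what reproduces the published flag pattern, where a
rank-3 p of 0.015 against a threshold of 0.009 is only
"near-significant" although higher ranks pass. Ties in p get ranks in
stable input order. The near-significant tier defaults to `p < 0.05`
(plus an optional explicit include-list), which reproduces the
published starred rows exactly; features with fewer than two unmasked
values in a group are excluded from `m` before thresholds are
computed. Feature selection for modelling = significant +
near-significant + RSBI.

## Prediction and evaluation

The Random Forest uses the study hyperparameters (50 trees, Gini
impurity `G = Σ p(i)(1−p(i))`, min 1 sample per leaf, min 2 to split).
Tree construction is delegated to scikit-learn, but everything the
analysis *claims* is computed by this package from the exported tree
structures: the aggregate prediction is the majority of per-tree votes
(ties toward success), the ranking score is the mean per-tree leaf
success-probability, and feature importances follow the node-importance
formulation `ni_j = w_j G_j − w_left G_left − w_right G_right` with
per-tree `fi_i = Σ_{j splits on i} ni_j / Σ_k ni_k`, averaged over
trees and renormalised (verified against a recursive traversal oracle
and against scikit-learn's own importances). The logistic comparator
is an unregularised main-effects model on standardised inputs.

Weaning **success is the positive class** for
sensitivity/specificity/PPV/NPV, consistent with the high prevalence of
success in these cohorts; F1 is reported for *both* classes
(`f1_success`, `f1_failure`) because at a 75/25 prevalence the two
conventions answer different questions and published F1 columns are
often consistent only with the minority class. AUROC uses the rank
(Mann-Whitney) formulation with midranks for ties.

Evaluation draws `n_iter = 1000` (configurable) stratified 7:3
train/test splits, fits each trainable comparator on the training part
(missing features imputed by training-split medians — rank-preserving
for tree splits) and scores the held-out part; reported numbers are the
per-metric mean and 2.5/97.5 percentile interval. This
"resample-the-experiment" reading of bootstrapping is the default; a
`single_split` mode that bootstraps the held-out predictions of one
fixed split is provided as the alternative reading. One master seed
derives all per-iteration seeds, so reports are bit-reproducible.

**Selection bias caveat.** Selecting features on the full cohort and
then evaluating by resplitting the *same* cohort inflates apparent
performance: on null cohorts (separation 0) the full pipeline reads a
mean AUROC of ≈ 0.62, while the same evaluation with a fixed
(pre-specified) feature panel reads 0.50 as it should. The package
exposes both paths; the null-calibration test uses the fixed panel, and
any real-data application should interpret pipeline AUROCs with this
bias in mind.

## Synthetic cohorts

The generator's defaults are the study conditions: 67 success / 22
failure patients, 30-min trials, 62.5 Hz waveforms.

* **fGn** via Davies-Harte circulant embedding — an exact stationary
  Gaussian sample whose autocovariance matches the closed form (tested
  to 3 SE); it calibrates the DFA estimator and colours the waveform
  noise.
* **Numeric vitals**: slow AR(1) (pole 0.95) plus white noise, with the
  component variances solved from the target Poincaré pair via
  `SD1 = σ√(1−ρ)`, `SD2 = σ√(1+ρ)`; targets are hit within ~7 % in a
  600-sample window. Group targets are the published Poincaré
  ratio/SD2 pairs (e.g. HR SD1/SD2 0.43 vs 0.32).
* **Waveforms**: quasi-periodic template trains (schematic ECG complex,
  pulse, breath and pressure shapes) whose cycle rate is modulated by
  slow fGn and whose additive fGn noise fraction controls sample
  entropy monotonically; the noise Hurst controls the short-scale DFA
  exponent of the mixture. Group noise fractions come from a one-off
  calibration sweep so the extracted SampEn orderings follow the
  published table (ECG ≈ 1.6 vs 2.0, PPG ≈ 0.22 vs 0.38 at stride 4);
  absolute levels are template-dependent and not matched exactly.
* **Breaths**: jittered intervals at a group respiratory rate, with
  tidal-volume and inspiratory-time series generated like the vitals.
  Rate/volume levels (20 /min, 430 mL vs 22 /min, 400 mL) give
  overlapping RSBI distributions, so RSBI alone discriminates weakly —
  mirroring the published comparison — while almost no synthetic
  patient crosses the 105 threshold (the rule's specificity is
  near zero here; only the AUROC ordering is meaningful).
* **Heterogeneity**: patient-level parameters are drawn around the
  group means — truncated Gaussians for bounded quantities, lognormal
  (right-skewed) jitter for scales and noise fractions, ±12 % jitter on
  the base cycle rate — at a default relative level of 0.30. A single
  `separation` scale interpolates every failure parameter toward the
  success value; 0 collapses the groups entirely.

Feature families are generated independently within a patient (the
published analysis gives no joint correlation structure). What passing
tests show, therefore, is that the *estimators* and the *inferential
machinery* behave correctly on signals with known structure — not that
the generator reproduces real ICU physiology: ECG morphology is
schematic, artefacts/arrhythmias are absent, several published
group-mean magnitudes (waveform DFA exponents in particular) are not
matched, and real between-feature correlations are unmodelled. The
published real-data headline (combined AUROC 0.81 vs RSBI 0.58) is
treated as a *direction* to reproduce, not a value: on synthetic
cohorts the combined model separates groups more cleanly than the real
data allowed.

## Problem sizes and numerical choices

Cohort-level tests generate trials at the 600 s analysis-window length
(the window is then the whole trial) and use SampEn stride 4; the
direction-of-effect and parameter-recovery checks use 10 replicate
cohorts of 89 patients, null calibration averages 3 cohorts (a single
cohort's mean AUROC carries sampling noise of ~±0.07), and bootstrap
comparisons use 200 iterations. DFA calibration uses 50 series of
length 4096 — `scripts/acceptance.py` recomputes exactly that. Exact
rank-sum enumeration switches on at combined n ≤ 12 without ties.
Degenerate inputs never raise inside feature extraction: missing
channels, undefined ratios and matchless entropy all propagate as
masked values.

## Known limitations

* The per-rank significance rule is intentionally non-standard; the
  step-up mode should be preferred for new analyses.
* SampEn absolute values depend on the stride (effective sampling
  rate); comparisons are only meaningful at a fixed setting.
* The generator's waveform DFA exponents sit below the published
  group means (the schematic templates are rougher at short scales than
  real monitor waveforms); orderings, not levels, are calibrated, and
  the published ECG alpha1 ordering (success above failure) is not
  reproduced by the default calibration.
* EDF export is not provided; bundles are plain text only.
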