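# weanwave

Biosignal variability analysis for ventilator-weaning prediction.

Deciding when to free an ICU patient from mechanical ventilation is a
high-stakes call: premature extubation forces risky reintubation, while
unnecessary ventilator days raise pneumonia risk and cost. The bedside
standard is the rapid shallow breathing index (RSBI = respiratory rate /
tidal volume, breaths·min⁻¹·L⁻¹; values ≥ 105 predict failure), but it
summarises a single physiological axis at a single moment. `weanwave`
implements an alternative: extract *variability and complexity* markers
from the continuous biosignals recorded during a 30-minute spontaneous
breathing trial (SBT), test which markers separate weaning success from
failure, and ask whether adding them to RSBI improves prediction.

The package is aimed at researchers in physiological signal analysis and
critical-care data science: a Python library first (see `examples/`),
with a thin `weanwave` command-line front end for batch runs.

## The indices and the analysis

For a series *x₁…x_N* from the middle 10 minutes of an SBT:

* **Poincaré plot** — lag-1 return map (*xₙ, xₙ₊₁*);
  SD1² = ½ Var(xₙ₊₁ − xₙ) (short-term variability),
  SD2² = ½ Var(xₙ₊₁ + xₙ) (long-term), and SD1/SD2.
  Applied to 1 Hz vitals (HR, RR, mean ABP) and per-breath ventilator
  series (V_T, I:E ratio, T_insp).
* **Sample entropy** — SampEn = −log(A/B), with B the number of
  length-*m* template pairs within Chebyshev tolerance *r* (self-matches
  excluded) and A the same at length *m*+1; defaults *m* = 2,
  *r* = 0.2·SD. Applied to the 62.5 Hz ECG, PPG, respiratory-impedance
  and arterial-pressure waveforms.
* **Detrended fluctuation analysis** — integrate the centred series,
  detrend per box, regress log F(n) on log n; α ≈ 0.5 for uncorrelated
  data, α > 0.5 for fractal correlation. α1 = short scales, α2 = long.

The 34 resulting features are compared between outcome groups with
Mann–Whitney tests under rank-indexed thresholds α_adj = α·i/m
(α = 0.1): the i-th smallest p-value is significant iff p < α·i/m at
its own rank. Significant + near-significant features + RSBI feed a
50-tree Gini Random Forest (feature importances computed from the
node-importance formula ni_j = w_j G_j − w_left G_left − w_right G_right)
and an unregularised logistic model, evaluated against the RSBI≥105
rule over 1000 stratified 7:3 train/test splits (mean and 95%
percentile CI of sensitivity, specificity, accuracy, PPV, NPV, F1,
AUROC).

Real cohorts of this kind are not publicly available, so the package
includes a tested synthetic SBT cohort generator (67 success / 22
failure by default) whose group profiles emulate the published feature
table; see `docs/methods.md` for what it does and does not reproduce.

## Worked example

```sh
python examples/train_and_evaluate.py
```

generates a 26-patient synthetic cohort, extracts features, selects the
discriminative ones and evaluates the three comparators:

```
features in the model: ['ecg_sampen', 'ecg_alpha2', 'ecg_alpha_ratio', 'ppg_sampen', 'rsbi']

AUROC rsbi       0.757  (95% CI 0.432-1.000)
AUROC forest     0.992  (95% CI 0.867-1.000)
AUROC logistic   0.991  (95% CI 0.933-1.000)

forest feature importances (ni_j/fi_i formulation):
ppg_sampen        0.478
ecg_sampen        0.291
rsbi              0.099
ecg_alpha2        0.070
ecg_alpha_ratio   0.062
```

The selection step has flagged the ECG/PPG entropy features (the
generator makes failure-group waveforms more irregular), both combined
models clearly outperform the RSBI rule alone, and the importance
ranking shows the entropy markers carrying most of the forest's
discrimination — the qualitative pattern the analysis is designed to
detect. Other scripts in `examples/` demonstrate the individual
indices, the cohort generator and the comparison table.

The same stages are available from the shell:

```sh
weanwave simulate --n-success 67 --n-failure 22 --seed 1 --out cohort/
weanwave report --in cohort/ --out results/
```

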