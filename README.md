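# ppgbp — cuffless blood-pressure estimation from photoplethysmography

`ppgbp` is a tested, reusable implementation of a two-stage ("combinatorial")
neural-network approach to estimating blood pressure from a single scalar
photoplethysmography (PPG) signal, together with the blood-pressure
variability index and the full device-validation statistics protocol used to
judge such estimators. It is aimed at researchers in biomedical signal
processing and digital health who want to study this model family, its
training procedure and its validation metrics end to end — without access to
clinical recordings, which the package replaces with calibrated synthetic
generators.

## The model

Oscillometric devices determine systolic and diastolic pressure (SBP, DBP)
from the mean arterial pressure (MAP); by the vascular-unloading principle,
MAP is also the pressure at which an optical (PPG) signal shows maximal
pulsatile response. The estimator therefore cascades two small feed-forward
networks:

1. **Stage 1 (PPG → MAP).** A 1–10–1 network maps one averaged
   light-absorption level (arbitrary units) to MAP (mmHg).
2. **Stage 2 (MAP → SBP, DBP).** A 1–30–2 network maps MAP to systolic and
   diastolic pressure. It is trained on MAP computed from cuff readings via

   MAP = (2·DBP + SBP) / 3

   but at prediction time receives stage 1's *estimated* MAP.

Both networks use tanh hidden units, linear outputs and [−1, 1] min–max
normalization, and are trained by Bayesian-regularization backpropagation:
Levenberg–Marquardt minimization of F = β·E_D + α·E_W (error plus weight
penalty), with α and β re-estimated every epoch from the effective number of
parameters γ = P − 2α·tr(H⁻¹). Training stops at 1000 epochs or after six
consecutive epochs without validation improvement, on a random 70/15/15
train/validation/test split.

Short-term blood-pressure variability of a predicted series is summarized by
the **average real variability** index,

ARV = (1/(N−1)) · Σ |BP_{k+1} − BP_k|,

the mean absolute change between consecutive readings — unlike the SD, it is
sensitive to reading order. Predictions are judged with mean error ± SD,
Pearson/Spearman correlation, percentage accuracy, cumulative percentages of
absolute errors within 5/10/15 mmHg, the AAMI criterion (|ME| ≤ 5 mmHg,
SD ≤ 8 mmHg), BHS grades A–D, and Bland–Altman limits of agreement.

## Synthetic data

Two acquisition protocols are emulated from a known monotone PPG↔MAP ground
truth (`ppgbp.simulate`):

* a cohort of 24-hour ambulatory recordings (15-min daytime / 30-min
  nighttime schedule, 82 scheduled readings, nocturnal dip, AR(1)
  within-subject noise, random invalid readings, strict >70 %-valid quality
  filter), calibrated so the pooled readings hit SBP 131.1 ± 21.4,
  DBP 74.9 ± 14.4 and MAP ≈ 93.6 ± 15.3 mmHg; and
* a seated paired-measurement protocol: 3 participants, three rounds of
  20/20/10 valid records (50 each, 150 total), PPG sampled every 0.6 s over
  30 s with positive samples averaged, the ground truth calibrated so PPG
  summaries match 4100.7 ± 107.7 a.u. over a MAP distribution of
  88.9 ± 16.1 mmHg, and reference-device noise within a ±3 mmHg cuff
  accuracy.

## Worked example

```bash
ppgbp run --seed 1 --out demo_out
```

runs the whole pipeline — simulate the cohort, train stage 2, calibrate the
PPG ground truth, simulate the paired sessions, train stage 1, predict, and
validate — and prints:

```
INFO ppgbp: cohort: 50/50 subjects pass quality filter, 3703 pooled readings (0.05s)
INFO ppgbp: stage 2 (MAP->BP): 13 epochs, stop=validation_failures (0.11s)
INFO ppgbp: protocol: 150 paired records from 3 participants
INFO ppgbp: stage 1 (PPG->MAP): 16 epochs, stop=validation_failures (0.01s)
### Validation report: in_sample

| BP estimate | Error bias (mmHg), mean (SD) | Accuracy (%) | Pearson | Spearman | <=5 mmHg (%) | <=10 mmHg (%) | <=15 mmHg (%) | AAMI | BHS |
|---|---|---|---|---|---|---|---|---|---|
| SBP | 0.05 (2.25) | 98.64 | 0.99 | 0.98 | 97.33 | 100.00 | 100.00 | pass | A |
| DBP | 0.15 (1.72) | 98.20 | 0.99 | 0.97 | 99.33 | 100.00 | 100.00 | pass | A |
```

Reading the table: the error bias is mean(reference − predicted) over the
150 paired records, so 0.05 (2.25) means essentially unbiased SBP prediction
with a 2.25 mmHg error SD; both quantities pass the AAMI bounds and grade A
under BHS because nearly all absolute errors fall within 5 mmHg. (On clean
synthetic data with a learnable ground truth the cascade recovers BP nearly
perfectly; real PPG is far harder — see `docs/methods.md`.) A `held_out`
variant of the same table restricts scoring to stage 1's test split, and the
output directory also contains per-participant summaries, Bland–Altman point
pairs (CSV), each subject's predicted mean BP level and ARV, serialized
models (JSON) and a run manifest. `ppgbp simulate`, `ppgbp train` and
`ppgbp evaluate` expose the same steps individually; `--config` accepts a
YAML/JSON experiment configuration.

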