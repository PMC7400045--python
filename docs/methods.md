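# Methods

## Scope

`ppgbp` implements a two-stage feed-forward estimator of blood pressure (BP)
from a scalar photoplethysmography (PPG) level, the average-real-variability
(ARV) index, the device-validation statistics used to judge BP monitors, and
synthetic generators for the two study designs the analysis needs (a 24-hour
ambulatory cohort for MAP→BP fitting and a paired PPG/cuff protocol for
PPG→MAP fitting). Sensor hardware, wireless transport and any mobile user
interface are out of scope: the package consumes one averaged light-absorption
value per acquisition, as delimited text.

## Estimator

Stage 1 is a 1–10–1 network (PPG → MAP), stage 2 a 1–30–2 network
(MAP → SBP, DBP). Hidden units are hyperbolic tangents; outputs are linear.
Inputs and targets are affinely mapped to [−1, 1] using the training split's
min/max — the convention that keeps tanh units in their active range. Stage 2
is trained on MAP computed from cuff readings by MAP = (2·DBP + SBP)/3 but is
fed stage 1's *estimate* at prediction time; this error-propagation asymmetry
is inherent to the two-stage design and is kept as-is.

### Training

Both stages are trained by Bayesian-regularization backpropagation in the
MacKay / Foresee–Hagan formulation. With E_D the sum of squared normalized
errors, E_W the sum of squared weights, P the number of weights and N the
number of error terms, each epoch takes a Levenberg–Marquardt step on
F = β·E_D + α·E_W: solve (β·JᵀJ + (α+μ)I)Δ = β·Jᵀe − α·w, accept only if F
decreases (μ ×10 on rejection, ×0.1 on acceptance, starting at 0.005,
halting if μ exceeds 1e10). After the first step, each epoch re-estimates the
hyperparameters from the Gauss–Newton Hessian H = 2β·JᵀJ + 2α·I:

    γ = P − 2α·tr(H⁻¹),  α = γ / (2·E_W),  β = (N − γ) / (2·E_D),

with γ clamped to [0, P] against round-off and E_D, E_W floored at 1e−12
before division (noiseless data can drive E_D to machine zero). α starts at
0 and β at 1, so the first step is data-only, after which the evidence
update takes over. The Jacobian is computed analytically (verified against
central finite differences in the tests).

Stopping: 1000 epochs, or six *consecutive* epochs in which the validation
mean-squared error fails to beat the best value seen, or the μ/gradient
floor. The weights from the best validation epoch are restored on exit.
Although the canonical Bayesian-regularization algorithm needs no validation
set, the validation stop is retained here because the estimator's training
protocol prescribes both; with the 70/15/15 split this is also what bounds
the run time of the larger stage-2 fits (typically 10–30 epochs on the
default synthetic cohort).

Data are split 70/15/15 at random: floor(0.70·n) rows train, and the
remainder is divided between validation and test in proportion to their
fractions (validation takes the floor). For n = 43,552 this gives
30,486 / 6,533 / 6,533. Weight initialization is a seeded Nguyen–Widrow-style
scheme (normalized random hidden directions scaled by 0.7·H^(1/I), biases
spread across the input range). Training is deterministic given (data, seed);
the batch objective makes the fit invariant to training-row order up to
floating-point round-off.

## Variability and validation metrics

ARV = (1/(N−1))·Σ|x_{k+1} − x_k| over the N valid readings in timestamp
order, divisor N−1 (the standard form of the index); invalid readings are
skipped without any gap penalty. The SD baseline uses divisor N−1 as well.
Differences are reference − predicted everywhere. "Within t mmHg", the AAMI
bounds (|ME| ≤ 5, SD ≤ 8) and the BHS thresholds (A = 60/85/95,
B = 50/75/90, C = 40/65/85 cumulative % within 5/10/15 mmHg) are all
inclusive comparisons; the BHS table is hard-coded from the standard since
the grading protocol is referenced rather than reprinted in most reports.
Bland–Altman limits use bias ± 1.96·SD (multiplier configurable). The
ambulatory quality filter is strict: a recording passes only if
valid/scheduled > 0.70, so exactly 70 % fails.

## Synthetic generators

### Structural BP model

A latent MAP drives each reading. DBP is affine in MAP plus residual
pulse-pressure scatter ε, and SBP = 3·MAP − 2·DBP exactly, so Eq-2
consistency of every pooled table holds by construction. The coefficients
are solved in closed form from the target pooled moments: with V = Var(MAP),

    b = (9V − (Var(SBP) − 4·Var(DBP))) / (12V),
    Var(ε) = Var(DBP) − b²V,

giving b ≈ 0.882, sd(ε) ≈ 5.0 mmHg at the default targets
(SBP 131.1 ± 21.4, DBP 74.9 ± 14.4, MAP SD 15.3 mmHg). The latent MAP mean
is taken Eq-2-consistent at (2·74.9 + 131.1)/3 = 93.63 mmHg. ε is truncated
so the pulse pressure never drops below 10 mmHg (≈3.7 SD out), which keeps
SBP > DBP everywhere at negligible moment distortion.

### Ambulatory cohort

Default 50 subjects (a desk-scale stand-in for a population cohort of
hundreds; the pooled table is ~3,600 valid readings). Each subject gets one
reading per 15 min in [06:00, 23:00) and per 30 min otherwise — 68 + 14 = 82
scheduled readings; the printed "10:59 PM" daytime bound is read as a
half-open window whose last daytime slot is 22:45. Latent MAP =
subject level × (1 − dip at night) + AR(1) deviations (ρ = 0.6). The daytime
level is calibrated so the day/night slot mix pools to the target MAP mean
despite the 10 % nocturnal dip, and the target MAP variance is decomposed as
dip variance + 65 % between-subject + 35 % within-subject. Subject levels
are drawn once at the cohort level and standardized to the exact
between-subject mean and SD — a variance-reduction choice that keeps the
pooled means on target (±1 mmHg) at modest cohort sizes while leaving all
within-subject structure random. Readings are independently invalid with
probability 0.1; invalid readings keep their values but are excluded from
pooled tables, and subjects failing the >70 % filter are dropped.

### Paired protocol

Three participants, one session each, rounds of 20/20/10 valid records taken
every 5 min. Each participant's true MAP starts at an individual baseline
(Normal, mean 88.9, SD 15 mmHg between participants) and follows a random
walk with 1.2 mmHg steps (≈10 mmHg range across a session, so the 150
records span a learnable BP range). True SBP/DBP sit on the structural
conditional mean (no ε scatter within a seated session); the recorded
reference values add independent Gaussian device noise of SD 1.5 mmHg
(within a ±3 mmHg cuff accuracy), redrawn in the rare case the ordering
SBP > DBP would break, and the paired MAP is Eq 2 applied to the *recorded*
values — exactly how a reference MAP would be computed in practice. Each PPG
record averages floor(30 s / 0.6 s) = 50 raw samples of g(MAP) + noise after
discarding nonpositive samples (a record with no positive samples is
regenerated and counted).

### PPG ground truth

g(MAP) = intercept + slope·(MAP + c·w·tanh((MAP − 90)/w)) with mild
saturation c = 0.3, w = 40 mmHg — the simplest learnable strictly monotone
map, with a positive slope by default (the true direction and shape of the
PPG–MAP relation are not established; both are configurable). Raw-sample
noise SD defaults to 50 a.u. Calibration is closed-form: the shape's moments
over the stated MAP distribution (Normal 88.9 ± 16.1, by Gauss–Hermite
quadrature, or empirical moments of a supplied MAP sample) give the slope
and intercept that hit the target averaged-PPG moments (4100.7 ± 107.7 a.u.),
after subtracting the noise variance left by 50-sample averaging. A
zero-variance MAP distribution is rejected (slope undefined).

## Pipeline

`run_experiment` chains cohort simulation → stage-2 fit → ground-truth
calibration → protocol simulation → stage-1 fit → cascade prediction →
validation reports → per-participant summaries → predicted-series mean and
ARV per participant. The global seed spawns independent sub-seeds
(numpy `SeedSequence`) for the cohort, the protocol and each stage's
training, so every artifact is a deterministic function of (config, seed);
no timestamps are written into artifacts, making repeated runs byte-identical.
Two scoring protocols are reported: `in_sample` over all 150 paired records
(the historical single-session protocol — an acknowledged limitation, since
training data are included) and `held_out` over stage 1's test split only.

## What the synthetic experiments do and do not show

The generators reproduce the *statistical setting* of the two protocols —
sample sizes, schedules, pooled moments, quality filtering, device noise —
under a ground truth in which PPG genuinely determines MAP up to noise, and
BP is tightly coupled to MAP. Passing tests therefore demonstrate that the
pipeline machinery is correct: the trainer minimizes its objective, the
cascade recovers a recoverable relationship (end-to-end error < 0.5 mmHg
noiseless; held-out DBP RMSE within 2 mmHg of the injected device noise
across seeds), and the validation statistics match brute-force oracles. They
do **not** show that BP is recoverable from real wrist PPG: physiological
PPG–MAP coupling is confounded, nonstationary and person-specific, none of
which the scalar ground truth emulates. Accuracy tables on synthetic data
are accordingly far better than anything achievable on clinical recordings.

## Known limitations

- One scalar PPG value per record; no waveform morphology.
- The AR(1) step is applied per reading regardless of the 15/30-min slot
  spacing, so night readings decorrelate slightly faster in wall-clock time.
- The cohort's conditional DBP|MAP scatter (≈5 mmHg) makes stage 2 a
  conditional-mean estimator; per-subject pulse-pressure idiosyncrasies are
  not modeled.
- Correlation P-values and clinical interpretation (dipping status,
  hypertension staging) are out of scope.
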