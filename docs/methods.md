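# Methods

This note documents the models, parameters, and numerical choices behind
`migrasleep`, and what the synthetic experiments do and do not show.

## Signals and preprocessing

The pipeline consumes the Empatica E4 export dialect: 3-axis acceleration
at 32 Hz (raw units of 1/64 g), blood volume pulse at 64 Hz, electrodermal
activity and skin temperature at 4 Hz, heart rate at 1 Hz, and an
inter-beat-interval (IBI) event list. Acceleration is reduced to its
Euclidean magnitude; all regular channels are brought onto the 64 Hz pulse
grid by zero-order hold over the intersection of the channel time spans.
Hold (rather than, say, spline interpolation) is deliberate: it invents no
intra-sample structure in the slow channels, and the downstream statistics
are order statistics and moments for which hold is equivalent to sample
weighting. The irregular IBI events are linearly interpolated onto the
grid as `ibi_interp` for the correlation features only; the raw event list
is carried alongside for the HRV features. When a session exports no IBI
events, `ibi_interp` falls back to 60/HR.

Sleep is detected as the longest interval where the rolling standard
deviation of acceleration magnitude (window **W = 60 s**) stays below
**T = 0.01 g**, with interruptions shorter than **G = 5 min** bridged and
a minimum accepted duration of **3 h** (all configurable; the short-night
test fixtures lower the minimum to 1 h). These are conventional
actigraphy-style values standing in for per-night visual inspection; on
synthetic nights the detected boundaries land within ±10 min of the
generator's ground truth in ≥95% of nights, and since features are
computed over hours-long windows, residual boundary error has little
effect on feature values. One sleep interval is kept per session (naps are
ignored), and a night is labelled with the diary flag of the calendar day
containing its wake time (configurable timezone offset, default UTC) —
the morning-warning use case keys everything to the day the subject wakes
into. Nights whose waking day has no diary entry are dropped with a
logged warning, never imputed.

## The 110 nightly features

Per night: SD and mean of {acceleration magnitude, pulse, temperature,
heart rate, EDA, raw IBI series} (12); minimum of the first four signals
(4 — wrist EDA pins at zero, so its minimum is uninformative); maximum,
median, and 5th/25th/75th/95th percentiles of the five grid signals (30);
the same statistics compared between the last and first sleep quarter
(last − first, 44); Pearson correlations of the 14 retained column pairs
(14); and six time-domain HRV indices (6). Totals: 46 + 44 + 14 + 6 = 110.

Choices worth noting:

- *Quarters* are the first and last ⌊N/4⌋ samples (sample count, not wall
  clock; ties broken by truncation). The last quarter is the closest to a
  morning attack, which motivates the last-minus-first sign; the sign is
  immaterial to discriminant classifiers but fixed for reproducibility.
- *Correlations*: of the 15 unordered pairs among the six grid columns,
  the (heart rate, interpolated IBI) pair is dropped because HR is a
  deterministic transform of the IBI stream (correlation ≈ −1,
  uninformative) — the only principled way to arrive at 14 pairs.
- *"HRV" as a statistics channel* means the raw IBI event series: only
  the irregular beat stream carries heart-rate variability.
- *HRV indices*: RMSSD, mean and SD of successive IBI differences, beat
  count, NN50 (|successive difference| > 50 ms), and total power — the
  Welch periodogram of the IBI series linearly resampled to 4 Hz,
  integrated over 0–2 Hz, in s². With fewer than 3 intervals the
  difference-based indices are reported as 0 with a warning (the beat
  count stays exact).
- Percentiles use linear interpolation between order statistics; SDs are
  ddof = 1; a zero-variance column has correlation 0 by convention.

The registry (name, category, definition) is fixed, versioned, and
exportable as JSON; feature vectors refuse non-finite values.

## Night-comparison augmentation

From `a` pre-migraine and `b` non-migraine nightly vectors the augmented
set contains every migraine−non-migraine difference (labelled migraine
comparison, sign fixed at +1) and every unordered non-migraine pair
computed once with a uniformly random sign (labelled non-migraine
comparison): `a·b + b(b−1)/2` observations. Mirrored non-migraine pairs
would duplicate information up to sign, hence the one-direction rule;
the random sign keeps the class from acquiring an artificial mean.
Migraine-vs-migraine pairs are not generated. Nights are ordered
lexicographically by ID before the sign draws so that seed → matrix is a
pure function. Each observation carries provenance (left/right night IDs,
sign, subject), which the evaluation layer relies on.

## Discriminant models and feature selection

LDA/QDA are implemented directly (numpy/scipy): class means, empirical
priors, and sample covariances — pooled for LDA, per-class for QDA — with
a relative ridge **λ·(tr Σ/d)·I, λ = 10⁻⁶** by default, because
difference features can be nearly collinear. The discriminant score is
δ_c(x) = −½log|Σ_c| − ½(x−μ_c)ᵀΣ_c⁻¹(x−μ_c) + log π_c, evaluated via
Cholesky factors; exact score ties resolve to the non-migraine comparison
class. scikit-learn's discriminant classifiers serve as an independent
cross-check in the test suite (>99.5% decision agreement on Gaussian
toys), never as the implementation, since the ridge form and tie-break
here are part of the contract.

Feature selection is greedy sequential forward selection maximizing
balanced accuracy on the held-out validation fold, stopping when the best
improvement falls below **ε = 0.001** or **15 features** are reached
(QDA covariances must stay estimable from tens of observations). Before
the search the training set is doubled with one noisy copy per
observation — additive Gaussian noise with per-feature SD equal to
**0.1 ×** the feature's training SD — which blunts selection overfitting;
the final model is refit on the clean (un-noised) train+validation data
restricted to the selected features. Whether the refit reuses noise and
includes the validation fold are config flags. Internally the search
computes full-dimensional class statistics once and evaluates each
candidate subset by submatrix slicing, which is algebraically identical
to refitting on the subset (verified by a dual-route test).

## Evaluation protocol

*Personal*: two pre-migraine nights are drawn at random and **all** their
comparison observations enter the test set together, so no test migraine
night is ever seen in training; 20% of the non-migraine comparisons
(rounded to nearest, minimum 1) join them; the rest is partitioned into
five observation-level folds, four training and one validation. A
machine-checked invariant rejects any split in which a test migraine
night's comparisons appear outside the test set. *LOSO*: one subject's
observations are the test set, everyone else's form the folds.
Observation predictions are folded back to nights by majority vote
(migraine comparisons vote on their migraine night, non-migraine
comparisons on both member nights; ties alert). Scores: balanced accuracy,
sensitivity = TPR of non-migraine nights, specificity = TPR of migraine
nights — that orientation matches the empirical pattern that these models
recognise non-migraine nights more reliably. Everything is repeated
(20× by default) with fresh comparison matrices and splits, each
repetition seeded from a master seed; subjects failing the preconditions
(<3 migraine nights, <5 non-migraine comparisons) are recorded as
not-evaluable, never imputed.

### A known limitation: optimistic bias of the personal split at null

The personal protocol quarantines migraine nights but, by design, lets
non-migraine *nights* (not observations) be shared between the test set
and train/validation: a test migraine comparison m_i − n_j reuses a
training-side non-migraine night n_j, and test non-migraine pairs share
member nights with training pairs. A discriminant model can exploit
night-specific mean and covariance information through these shared
nights, and night-level vote aggregation amplifies the per-observation
effect. Consequence: on data with *no class signal at all* (i.i.d.
feature vectors), personal QDA scores per-subject means of roughly
0.52–0.66 (mean ≈ 0.59 over 20 repetitions) rather than 0.50, while the
leakage-free LOSO control on the same vectors sits at chance (≈ 0.47).
The corresponding null-calibration test in `tests/test_acceptance.py`
asserts the ideal chance band and is expected to fail; it is kept as an
honest record of this property of the protocol. Personal-model accuracies
produced by this protocol should therefore be read against a null of
~0.55–0.60, not 0.50; the LOSO numbers carry no such bias.

## Synthetic-data generator

The generator emulates a multi-day wrist-wearable study: per subject, one
session per night (evening → morning) with high-movement wake padding
(0.5 h each side), a low-movement sleep interval with Poisson postural
shift bursts, an AR(1) IBI process (coefficient 0.9 for realistic
short-range correlation) whose innovation SD is set so the stationary
successive-difference SD equals the target RMSSD, a one-pulse-per-beat
waveform resampled to 64 Hz, HR = 60/rolling-10-beat-mean(IBI) at 1 Hz,
and 4 Hz temperature/EDA as level + slow drift + noise. Nightly levels
are drawn per night from subject baselines (defaults: wrist temperature
33.5 ± 0.4 °C, EDA 0.30 ± 0.08 µS, HR 58 ± 2.5 bpm, RMSSD 45 ± 8 ms,
4 ± 1.5 movement bursts/h, sleep onset 23:00 ± 0.5 h, duration
7.5 ± 0.5 h, 10% missing nights — values a wearables researcher would
call typical for nocturnal wrist recordings). Pre-migraine nights shift
these draws by a configurable number of *between-night SDs* per channel
(default signature: temperature +1, EDA +1, HR +0.5, RMSSD −1, movement
+0.5, plus an optional within-night temperature trend expressed as the
last-vs-first-quarter mean difference). Effect magnitudes are free
parameters of the experiments, not claims about migraine physiology. A
zero effect makes the classes identically distributed by construction.
Whole nights go missing at random (device charging, sauna); partial-night
gaps are not simulated. The generator is a pure function of
(profile, effect, seed) — byte-identical output under a fixed seed.

What it does not emulate: circadian structure beyond a nightly drift,
sleep staging, PPG motion artifacts, sensor drift or inter-device
variation, and diary mislabelling. Passing tests therefore demonstrate
that the pipeline recovers the signal it defines, under its own noise
model — not that real pre-ictal physiology is detectable.

## Problem sizes

The cohort-level experiments (null calibration, 2-SD signal recovery,
personal-vs-LOSO ordering) run the full signal pipeline on 7 subjects ×
28 nights (9 migraine days, 10% missing) with shortened nights — 1.5 h
sleep, 15 min wake padding — as the package's chosen desk-scale problem
size; effects are specified in between-night SD units, so class
separability is not driven by night length. Single-subject fixtures use
the same short-night shape. The e4 I/O, augmentation, model, and split
layers are tested at full combinatorial sizes since they are cheap.

## Degenerate inputs and edge rules

Empty IBI stream → HRV difference features 0 with warning; zero-variance
signal → correlations 0, SD features 0; blocks shorter than 4 samples are
rejected; sleep shorter than the minimum → night skipped with a logged
warning; a class with fewer than 2 observations → fit error; splits
failing preconditions raise errors naming the deficit. The 20% test
fraction rounds to nearest with a minimum of 1.
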