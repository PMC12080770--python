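# Methods

This note records the models behind `opfatigue`, the parameters that
matter, the numerical choices made where the design was open, and what
the synthetic cohort does and does not establish about real data.

## The study design being emulated

The package targets graded-exercise-test studies of occupational
fatigue: each subject performs consecutive treadmill stages of fixed
length with stepwise speed increments; after every stage the subject
reports a Borg 6–20 rating of perceived exertion (RPE) and takes a
simple reaction-time (SRT) test, while the stage's ECG-derived
RR intervals are recorded.  The default protocol is 6 subjects ×
7 stages × 4 minutes, 4 km/h start, +1 km/h per stage — 42
subject-stage observations.  A resting baseline recording is not
counted as an observation.

## Synthetic cohort

**Latent fatigue.**  The ground truth for subject *s* at stage *k* is
the fraction of heart-rate reserve in use,
f = (HR − HR_rest)/(HR_max − HR_rest) clipped to [0, 1].  It is simple,
monotone in stage, and physiologically interpretable.  Subject profiles
are drawn once per cohort (resting HR ∈ [55, 75] bpm inside the usual
[50, 90] screening range, HR_max ∈ [185, 195] bpm, peak reserve use at
the final stage ∈ [0.78, 0.92], so HR never saturates within the
protocol).

**Observable channels**, all driven by f:

* HR rises linearly with treadmill speed (slope fixed by the peak
  reserve fraction).
* SDNN falls with both the shortening beat and fatigue:
  SDNN_k = SDNN_base · (HR_rest/HR_k) · (1 − 0.5 f).  The HR-proportional
  factor keeps the modulation inside physiological interval bounds at
  high heart rates and mirrors the well-known shrinkage of absolute HRV
  with heart rate.
* LF/HF rises linearly from 1.5 (balanced, rest-like) to ≈5
  (sympathetic predominance): LF/HF_k = 1.5 + 3.5 f.
* Borg = round(6 + slope·(k−1)) + noise, clipped to [6, 20], with
  slope ∈ [1.9, 2.3] RPE/stage so ratings approach 20 at the final
  stage; monotone non-decreasing at zero noise.
* Reaction time = RT_base · (1 + 0.5 f) + noise, RT_base ∈
  [220, 300] ms — a 50% lengthening at exhaustion.

**RR synthesis.**  RR(t) = 60000/HR + a_LF sin(2π·0.10·t + φ₁)
+ a_HF sin(2π·0.25·t + φ₂) + ε, evaluated at successive beat times.
The carriers sit at the centres of the standard LF/HF bands so band
powers are analytically attributable.  White jitter ε carries a
configurable fraction of the total variance (default 0.1); the tone
variances are solved so that the *expected measured* LF:HF ratio —
including the jitter's flat-spectrum contribution to both bands —
equals the requested ratio.  Total interval SD matches the requested
SDNN; every beat is clamped to [305, 1995] ms so no physiologically
impossible interval is emitted.

**Noise calibration.**  The defaults
`noise_sd = {borg: 0.5 RPE, rt: 8 ms, rr: 0.1}` were calibrated once so
that on the default protocol roughly 7% of the variance of the
composite index F cannot be explained from the HRV features (measured
as the pooled 5-fold-CV R² of a regularized linear readout, 92.9% over
cohort seeds 0–9), and then frozen.  Integer rounding of Borg is itself
part of the observation noise.

**Reproducibility.**  One `SeedSequence` per cohort spawns one stream
per subject (profile first, then one stream per stage), so a subject's
data is unchanged when `n_stages` changes.  Identical configs give
byte-identical CSV output.

**What the simulator does not emulate:** ectopic beats and artefacts,
respiration-driven HF drift, thermal/load stress beyond the speed ramp,
inter-day baseline variation, and any cognitive measure beyond SRT.
Passing tests therefore demonstrate the pipeline's correctness and its
statistical behaviour under the stated generative model — not
performance on field recordings.

## HRV features

Ten features in a fixed canonical order: RRI mean, HR, SDNN, RMSSD, LF,
HF, LF/HF, SD1, SD2, SD2/SD1.

* SDNN is the sample (n−1) standard deviation.  Inside the Poincaré
  identities the population convention is used, so
  SD1² + SD2² = 2·SDNN²_pop holds exactly and SD1 = RMSSD/√2 whenever
  successive differences have zero mean.  SD2 is clamped at 0 against
  floating-point negatives.
* Spectral analysis: cubic-spline interpolation of the interval-vs-beat-time
  tachogram, resampling at 4 Hz, mean removal, Welch PSD with a Hann
  segment of at most half the record (≤512 samples), band integration by
  the trapezoid rule over LF 0.04–0.15 Hz and HF 0.15–0.40 Hz, powers in
  ms².  These are the de facto standard settings for short-term HRV.
  The LF/HF ratio is convention-invariant between absolute and
  normalized units in this two-band setting.
* Preconditions: ≥30 beats for time-domain/Poincaré, ≥120 s for
  spectra.  A guard rejects intervals outside 300–2000 ms; no
  artefact correction is attempted (inputs are assumed clean).
* Undefined ratios (SD2/SD1 of a constant series, LF/HF with zero HF)
  are reported as NaN, never infinity.
* Stages are analysed whole (4-minute windows), no sub-windowing.

## Entropy weight method and the index F

For n samples and feature j: min–max normalize (a constant feature maps
to zeros — the only choice consistent with the downstream formulas,
where it then receives entropy 1 and weight 0), shift all values by
+0.001 so proportions are positive, then

p_ij = x″_ij / Σ_i x″_ij,  e_j = −(1/ln n) Σ_i p_ij ln p_ij,
g_j = 1 − e_j,  w_j = g_j / Σ_j g_j.

Natural logarithms throughout.  If every feature is constant the method
has no information to weight and raises an error.  Weights are keyed by
feature *name* ("rt", "borg"), never by column position, because the
two indicators are easy to transpose.  Both indicators are treated as
positive ("larger = more fatigued") — no direction inversion.

F = w_R·R + w_B·B on normalized components; floating error outside
[0, 1] is clipped only below 1e-9, anything larger is an error.  The
canonical three grades are mild [0, 0.27), moderate [0.27, 0.66),
severe [0.66, 1], half-open with boundaries belonging to the upper
level.  The reference study's recorded weights (0.39, 0.61), five-level
indicator thresholds and grade bands ship as constants; they are
recorded values, not recomputable without that study's raw data.  (Of
the five published F bands, only the middle one equals the weighted
combination of its indicator bounds; the package reproduces that band
exactly and keeps the full published table as metadata.)

## Clustering and grade thresholds

* **K-means**: Lloyd iterations from K distinct data points sampled
  without replacement, ties in assignment broken toward the lowest
  centroid index, empty clusters repaired by reseeding at the point
  farthest from its assigned centroid, at most 100 iterations, best of
  10 seeded restarts by within-cluster sum of squares.  Within-SS is
  asserted non-increasing at every iteration.
* **Silhouette**: s_i = (b_i − a_i)/max(a_i, b_i); members of singleton
  clusters score 0.  K selection scans K = 2…10, scoring the
  best-within-SS replicate of ten per K (best-replicate rather than the
  replicate average; recorded in the output table).
* **Thresholds**: per cluster and indicator, the [min, max] of member
  values; clusters ordered by the mean of their centroid coordinates.
  Adjacent intervals may overlap — that overlap is exactly what the
  consolidation step consumes.
* **F bands**: each level's F interval is the weight-combination of its
  indicator bounds, (Σ w_j·lo_j, Σ w_j·hi_j).
* **Consolidation**: two rules applied repeatedly — (i) adjacent bands
  are always merged when one contains the other or the intersection
  covers ≥50% of the narrower band; (ii) while more than
  `target_levels` (default 3) bands remain, the adjacent overlapping
  pair with the largest overlap fraction is merged, ties to the lower
  pair.  Disjoint bands are never merged.  A pure overlap threshold
  cannot by itself produce the published 5→3 consolidation (the
  published bands' pairwise overlap fractions do not separate the
  merged pairs from the unmerged ones), which is why the target-count
  rule exists; on the published bands the default reproduces the
  {1,2}→mild, {3}→moderate, {4,5}→severe grouping.

The clustering operates on the two normalized indicators (R, B) only,
never on the ten HRV features.

## Predictor

Architecture 10-8-1: y = W₂·tanh(W₁x + b₁) + b₂.  Inputs and target are
mapped feature-wise to [−1, 1] by min/max of the *training split only*
(constant features map to 0); predictions are mapped back.  Defaults
follow the reference regime: learning rate 0.01, at most 1000 epochs,
goal MSE 1e-5 (on the scaled target), 19:2 train:test split (38/4 on 42
samples; 9:1 available via config), weights initialised uniform on
(−0.5, 0.5) from the seeded stream.

The default optimizer is full-batch gradient descent with momentum 0.9,
backtracking and a mildly adaptive rate: any step that would increase
the loss is halved (velocity damped alongside) and retried, so the
recorded history is monotone non-increasing; after an accepted epoch the
rate grows 5%, capped at 100× the base rate.  Plain fixed-rate descent
at 0.01 converges too slowly to be useful at this scale; the
momentum/adaptive variant is the classic remedy and keeps the method
squarely in the backpropagation family.  A Levenberg–Marquardt option
(`TrainConfig(optimizer="lm")`) solves (JᵀJ + μI)δ = Jᵀr with the exact
Jacobian and converges in a handful of iterations on these problem
sizes.  Divergence (MSE > 1e6) raises an error suggesting a smaller
rate.

Evaluation reports MAE, MSE, RMSE (√MSE) and R² = 1 − SS_res/SS_tot
(NaN for zero-variance observations).  Cross-validation uses a seeded
shuffled k-fold partition (default 5); each fold refits its own scaling.
The headline cross-validation metrics are computed on the **pooled
out-of-fold predictions** (all 42 held-out points on the default
cohort) rather than averaged across folds: with 8-point test folds,
per-fold R² is too ill-conditioned to summarise generalization.
Per-fold reports are attached; leave-one-out folds report NaN R².
No regularization or early stopping beyond the MSE goal is implemented,
by design.

Under the default study conditions (42 samples, calibrated noise) the
pooled held-out R² is ≈0.9 on most cohort seeds — consistent with the
~7% noise floor plus a small generalization gap from fitting 97
parameters on ~33 training rows per fold.

## Pipeline and formats

One global seed deterministically derives per-stage seeds (cohort,
grading, training, cross-validation) via `SeedSequence`.  RR series are
one-integer-per-line millisecond text files named
`subj{S}_stage{T}.rr`; tables are UTF-8 comma-separated CSV with
headers; derived artifacts are JSON with sorted keys.  Every artifact
embeds the configuration hash and seed, and a rerun with the same
configuration is byte-identical.  Problem sizes throughout the test
suite are the study's own (42 observations, 240 s stages, K ≤ 10,
1000-epoch training), which keeps any single check in the
sub-second-to-seconds range.

## Known limitations

* The simulator's fatigue dynamics are a single monotone latent; it
  cannot produce non-monotone fatigue (recovery, second wind) or
  dissociation between perceived and physiological strain.
* Grade thresholds derived from 42 points are sensitive to the cluster
  count and seed; the published thresholds are shipped for use when a
  stable scale is needed.
* The predictor is a point estimator with no uncertainty; with n = 42
  its held-out R² varies by several points across cohort seeds.
* No artefact handling: real RR recordings need ectopic-beat correction
  before the feature stage.
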