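# Methods

`gazecca` quantifies which personal characteristics of computer programmers
(age, experience, native language, gender, ...) are associated with
eye-movement markers of cognitive load recorded while they read code. This
note documents the models and procedures the package implements, the choices
made where the design was genuinely open, and what the synthetic studies do
and do not demonstrate.

## Signal model and feature extraction

A gaze recording is a pupil time series sampled at a fixed rate (250 Hz by
default): pupil-center coordinates `(x, y)` in screen pixels and pupil
diameter in pixels. Samples with non-positive or missing diameter (blinks,
tracking loss) are flagged invalid but never dropped, so file row indexing
is preserved.

**Gap policy.** Invalid runs of at most 75 ms are bridged by linear
interpolation (short enough that interpolation cannot fabricate a saccade);
longer runs split the recording into segments processed independently, and
first differences are never taken across a segment boundary.

**Smoothing.** Both coordinates and pupil radius are smoothed per segment
with a Savitzky–Golay filter (least-squares local polynomial fit), window 11
samples (44 ms at 250 Hz), polynomial order 3. The window was chosen short
enough to preserve saccadic steps and long enough to suppress tracker noise;
order 3 reproduces locally cubic signal structure exactly.

**Displacement.** Saccades appear as steps in the coordinates, so the
working signal is the per-sample Euclidean displacement magnitude
`d_i = sqrt((x_i − x_{i−1})² + (y_i − y_{i−1})²)`, a non-negative spike
train: near zero during fixations, peaked at saccades.

**Adaptive z-score peak detection.** The detector is the streaming
lag/threshold/influence smoothed z-score algorithm. A filtered copy of the
signal is maintained; for each sample `i ≥ l`,

    z_i = (d_i − mean_l) / sd_l

with mean and sample SD taken over the previous `l` *filtered* samples. The
sample is flagged when `z_i ≥ ths` (one-sided: displacement is
non-negative). Flagged samples enter the filtered copy attenuated,
`filtered_i = in·d_i + (1−in)·filtered_{i−1}`, so a burst of peak samples
does not immediately inflate the rolling baseline; unflagged samples are
copied through. Defaults `ths = 5`, `l = 5`, `in = 0.5`. Degenerate case: a
window of exactly identical values has SD 0 by definition; a sample strictly
above such a baseline is an infinitely strong peak (flagged), otherwise
`z = 0`. Raising the threshold can never increase the number of flags.

**Eventization.** Consecutive flagged samples merge into one candidate
event; candidates separated by less than 50 ms merge further, since a
saccade lasts tens of milliseconds and inter-saccadic intervals exceed
~100 ms. Each candidate must then also reach the detection threshold on the
*whole-series* z-score of the displacement (global mean/SD, evaluated at the
candidate's local maximum within half a smoothing window). The rolling
detector is deliberately scale-free, which makes it flag a small but
persistent fraction (~1%) of pure-noise samples — the z statistic over a
5-sample window is heavy-tailed — while the global criterion anchors events
to the magnitude scale of the recording, where genuine saccadic steps stand
one to two orders of magnitude above the jitter floor. In the simulation
study (100 recordings at amplitude/jitter = 100×), this two-stage rule
recalls 100% of injected saccades with zero spurious events.

**Features.** Per recording, the four dependent variables are:

| feature | definition | units |
|---|---|---|
| `total_duration` | last − first timestamp | s |
| `sd_pupil_radius_change` | SD of the first difference of the smoothed pupil radius (diameter/2) | px |
| `peak_ratio` | saccadic event count / total duration (per-sample rate behind a flag) | events/s |
| `sd_eye_movement` | SD of the (smoothed) displacement series; raw behind a flag | px |

Features are computed per task and averaged per participant by default; a
per-task mode keeps them separate. Participants missing either task are
excluded (and logged) rather than imputed.

## Linguistic-distance encoding

Native language is categorical; it is converted to a quantitative linguistic
distance from English (higher = closer) using a fixed table: German 2.25,
Italian 2.5, Portuguese 2.5, Spanish 2.25, Finnish 2.00, Turkish 2.00,
Greek 1.75, Thai 2.00, Chinese 1.50. The table is user-extensible for
cohorts spanning more languages. Native English speakers have no defined
distance from their own language; the package assigns a configurable
`english_score`, default 3.0 — strictly closer than the closest listed
language, consistent with the scale's direction. Ordinal survey variables
(expertise, frequency, English level) are encoded 1–5; gender 0/1 with a
configurable reference level.

## Statistical model

Both variable sets — the 10 personal variables X and the 4 eye-movement
features Y — are z-score standardized (sample SD, `n−1` denominator)
before analysis; a constant column is a hard error.

**Correlation screens.** Pairwise Pearson correlations with two-sided
t-test p-values are the default preliminary screen; true partial
correlations (inverse-correlation-matrix method, each pair conditioned on
all remaining variables, df = n − k − 2) are available via `kind="partial"`.
Output headers record which kind was computed. No multiple-testing
correction is applied by default (a Benjamini–Hochberg option exists), and
p-values are reported raw with a p < 0.001 annotation convention in the
rendered tables.

**Canonical correlation analysis.** CCA finds weights `b` (X side) and `a`
(Y side) maximizing `corr(Xb, Ya)`. The solver computes the SVD of
`Cxx^{−1/2} Cxy Cyy^{−1/2}` with a small ridge (default 1e-8) added to the
within-set covariance diagonals for conditioning; weight vectors are
back-transformed, rescaled so every canonical variable has unit sample
variance, and sign-fixed (largest-magnitude X-side entry positive; Y-side
sign chosen so `corr(U_k, V_k) = +R_k`). The canonical correlations are
reported as the realized correlations of the score pairs, which removes the
O(ridge) bias of the singular values. Successive pairs are mutually
uncorrelated; `R` is non-increasing; `R_1` is never below the largest
absolute entry of the cross-correlation matrix; and both `R` and the
percentage attributions are invariant to rescaling any input column.

**Significance.** Wilks' lambda for pairs k..m, `Λ_k = Π_{i≥k} (1 − R_i²)`,
is tested with Bartlett's chi-square approximation,
`χ² = −(n − 1 − (p+q+1)/2)·ln Λ_k`, df = (p−k+1)(q−k+1). `R_i = 1` yields
`Λ = 0` with an explicitly infinite statistic.

**Attribution.** The first canonical pair (highest R, most linear) is
converted to per-side percentage contributions,
`percent_j = |w_j| / Σ|w| × 100`, using weights on standardized variables.
Absolute-value share is the convention under which each side totals 100%.
Standardizing before CCA versus relying on correlation-based internals gives
identical `R`; weights differ by column-SD factors, which is why the
percentages are defined on standardized variables and documented as such.

## Synthetic-data generator

The generator provides ground truth for every downstream stage.

*Gaze traces*: piecewise-constant fixation positions with instantaneous
jumps of fixed amplitude and random direction at the true onsets (saccade
kinematics are not modeled; step events are the minimal structure the
detector is designed to flag), additive white Gaussian jitter on the
coordinates, pupil diameter = baseline + white noise, and optional blink
gaps written as zero-diameter runs. Onsets are kept at least 100 ms apart
(real saccades rarely exceed 4–5 per second). Defaults: 20 s at 250 Hz,
10 saccades of 50 px, jitter SD 0.5 px (amplitude/jitter = 100×), baseline
40 px, diameter noise 0.05 px.

*Cohorts*: a single latent factor `z ~ N(0, latent_sd²)` per participant
drives both sets, `X = z·w_x' + noise`, `Y = z·w_y' + noise`, with unit-norm
planted weight vectors (defaults follow the relative-importance pattern the
package is designed to detect: age and linguistic distance large, gender
near zero on the X side; total duration largest on the Y side). Columns are
then mapped onto realistic marginals — age 26.56 ± 9.28 years, programming
experience 2.26 ± 3.34 years, ordinals discretized into 5 quantile levels,
gender thresholded at a 175:41 split, linguistic distance snapped to the
nearest real language score so the metadata can carry a language name —
which exercises the pipeline's encoding and normalization while keeping the
planted weights recoverable (the monotone transforms attenuate but do not
rotate the latent structure; recovery cosine ≈ 0.97–0.99 at n = 500,
noise/latent = 0.5).

*Dataset writing* derives each participant's gaze-simulation parameters from
their dependent-variable row (duration, diameter-noise SD, saccade count,
saccade amplitude), so features extracted from the written files inherit the
planted cross-set structure: exactly for the metadata side, approximately
and monotonically for the gaze-derived side (saccade counts are discretized,
durations clipped below at 5 s). Files are written at full float precision
and round-trip bit-exactly through the readers.

**What the synthetic studies do not show.** The generator's fixations are
white-jitter steps: no drift, tremor, microsaccades, smooth pursuit, or
amplitude-dependent saccade durations; pupil noise is white rather than
dominated by slow hippus; and the latent structure is a single shared
factor. Passing the recovery and power studies therefore demonstrates the
pipeline's correctness and its behavior under the stated noise model, not
detector performance on real tracker data, where fixational drift raises
the false-event floor and the peak-ratio feature becomes a relative rather
than absolute saccade count.

## Numerical choices and degenerate inputs

- Sample SD (`n−1`) everywhere, matching standard statistical software.
- CCA ridge 1e-8; covariance matrices that remain non-positive-definite or
  have condition number above 1e14 after ridging raise an error reporting
  the condition number.
- Recordings shorter than 50 samples, signals shorter than the smoothing
  window or detector lag, cohorts below 20 participants (CCA on 10 + 4
  variables is underdetermined), and n ≤ p + q all raise typed errors.
- Participant-level failures become logged exclusions; inclusions and
  exclusions always partition the metadata set.
- All generators and the pipeline are deterministic given seeds and config;
  reports are byte-identical across reruns (the manifest records the output
  path itself).

## Problem sizes

The simulation studies use a 216-participant cohort with two ~15 s tasks
per participant for the end-to-end run, 100 recordings for the
detection-power study, and 50 cohorts of n = 500 for weight recovery —
sizes at which every quantity of interest is stable to well within the
tolerances asserted in the tests.

## Known limitations

- The two "particle/partial correlation" screen variants answer different
  questions (marginal vs conditional association); the default is pairwise
  Pearson, and reports label which was used.
- `peak_ratio` depends on the eventization rule (merging window, global
  validation); alternative conventions shift its scale but not its ordering
  across participants.
- The proprietary binary export of the original tracker is not parsed;
  recordings must be converted to the documented TSV dialect first.
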