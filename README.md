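# gazecca

Which personal characteristics of computer programmers drive the cognitive
load they experience while reading code? `gazecca` answers this from
eye-tracking data: it turns raw pupil recordings into saccade and
pupillometry features, relates them to a set of personal variables with
canonical correlation analysis (CCA), and reports each variable's
contribution as a percentage.

The package is aimed at researchers working with cohort-style gaze
recordings (e.g., code-comprehension studies with an SMI-class tracker at
250 Hz) who want a tested, reproducible path from raw TSV exports to a
statistically tested factor-attribution table — plus a synthetic-data
generator with planted ground truth so every stage can be validated without
any real recordings.

## The model

Two variable sets are measured per programmer:

- **X (independent, p = 10)**: age, experience period in the experiment
  language, linguistic distance of the native language from English,
  English level, programming expertise, experiment-language frequency,
  years of programming experience, experiment-language expertise,
  other-language frequency, gender.
- **Y (dependent, q = 4)**: total task duration, SD of pupil-radius change,
  saccadic peak ratio (events/s), SD of eye movement.

Saccades are detected in the per-sample pupil displacement
`d_i = √((x_i−x_{i−1})² + (y_i−y_{i−1})²)` with an adaptive z-score
detector: `z_i = (d_i − mean_l)/sd_l` over the previous `l` filtered
samples, flagging `z_i ≥ ths`, with flagged samples entering the rolling
baseline attenuated by an influence factor (`ths = 5`, `l = 5`,
`in = 0.5`). Coordinates and pupil radius are Savitzky–Golay smoothed.

After z-scoring both sets, CCA finds weight vectors maximizing
`R = corr(Xb, Ya)`; pair significance is tested with Wilks' lambda
`Λ = Π(1 − R_i²)` via Bartlett's χ² approximation, and the first pair's
weights are normalized into per-side percentage contributions
`|w_j| / Σ|w| × 100`. See `docs/methods.md` for the full treatment.

## Worked example

Simulate a 60-programmer cohort with planted structure, run the full
pipeline, and print the fitted model:

```python
import gazecca as g

manifest = g.write_synthetic_dataset("data", g.CohortSimParams(n_participants=60, seed=0))
config = g.RunConfig(data_dir=manifest["gaze_dir"],
                     metadata_path=manifest["metadata_path"],
                     output_dir="out")
report = g.run_pipeline(config)
print(report.cca.summary())
```

```
Canonical Correlation Analysis
n = 60, p = 10, q = 4

pair        R    Wilks       chi2   df          p
   1    0.882    0.107    114.881   40   3.66e-09
   2    0.563    0.482     37.538   27     0.0855
   3    0.454    0.706     17.940   16      0.327
   4    0.332    0.889      6.032    7      0.536

First-pair attribution (percent of |weights| per side):
  X  age                           31.270%
  X  experience_period_exp_lang    11.370%
  X  linguistic_distance           16.717%
  ...
  Y  total_duration                44.290%
  Y  sd_pupil_radius_change        38.561%
  ...
```

Reading this: the first canonical pair correlates at R = 0.882 and is the
only significant one (Wilks Λ = 0.107, χ²(40) = 114.9, p ≈ 4e-9), so the
attribution is computed from it. On the personal side, age (31.3%) and
linguistic distance (16.7%) carry the largest shares of the canonical
cognitive-load relationship — as planted by the simulation — while on the
feature side task duration (44.3%) and pupil-radius variability (38.6%)
dominate. The same run writes `out/` CSV tables (features, correlation
screens, canonical weights), `attribution.json`, and a `manifest.json`
that materializes every parameter of the run.

The same analysis is available from the shell:

```bash
gazecca simulate --n-participants 60 --seed 0 --out data
gazecca run --config config.yaml
gazecca features --data-dir data/gaze --metadata data/metadata.csv --out features.csv
```

For real recordings, provide per-task gaze TSVs
(`time_ms, pupil_x_px, pupil_y_px, pupil_diam_px`, tab-separated, one file
per participant and task named `<participant>_<task>.tsv`) and a metadata
CSV with the ten personal variables plus `native_language`; languages are
encoded via a built-in, user-extensible linguistic-distance table.

As a statsmodels-style library, the stages are also usable directly:
`CanonicalCorrelation(X, Y).fit()` returns a results object with
`corr`, `wilks`, `summary()` and `attribution()`; `extract_features`,
`detect_peaks_zscore`, `correlation_screen` and `wilks_lambda` expose the
individual steps.

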