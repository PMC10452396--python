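"""Synthetic gaze recordings and participant cohorts with known ground truth.

Two generators make every downstream stage testable without the real
eye-tracking download:

* :func:`generate_gaze_recording` emits one pupil trace at a fixed sampling
  rate with saccades injected as instantaneous position steps (the minimal
  event structure the adaptive z-score detector is designed to flag),
  Gaussian fixation jitter, pupil-diameter noise, and optional blink gaps
  encoded as zero-diameter samples. The true saccade-onset indices are
  returned alongside the trace.

* :func:`generate_cohort` plants a single shared latent factor across the
  ten personal variables and the four eye-movement features: X = z w_x' +
  noise, Y = z w_y' + noise, with unit-norm planted weight vectors. Columns
  are then mapped onto realistic marginals (years, 1-5 ordinals, a 0/1
  gender with an imbalanced split, linguistic distance snapped to a real
  language score) so that the pipeline's normalization and encoding steps
  are exercised, and the planted weights remain recoverable by CCA.

:func:`write_synthetic_dataset` ties the two together into the exact on-disk
dialect the readers consume, deriving each participant's gaze-simulation
parameters from their dependent-variable row so the planted cross-set
structure survives end-to-end feature extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .gaze_io import (
    DEFAULT_ENGLISH_SCORE,
    DEFAULT_LINGUISTIC_DISTANCES,
    GAZE_COLUMNS,
    INDEPENDENT_VARIABLES,
    GazeRecording,
)
from .signal import DEPENDENT_VARIABLES

#: Gender split of the emulated cohort (males : females = 175 : 41).
DEFAULT_FEMALE_FRACTION: float = 41.0 / 216.0

#: Minimum spacing between injected saccade onsets, seconds. Real saccades
#: rarely exceed ~4-5 per second, and the detector's rolling window must
#: recover between events.
MIN_SACCADE_SPACING_S: float = 0.1

#: Default planted weight pattern over the ten personal variables (pre-
#: normalization). Age, linguistic distance and gender follow the relative
#: importance pattern the package is designed to detect; the remainder is
#: spread plausibly across the experience/expertise variables.
DEFAULT_PLANTED_X: tuple[float, ...] = (
    0.18047,  # age
    0.14,     # experience_period_exp_lang
    0.15404,  # linguistic_distance
    0.08,     # english_level
    0.07,     # expertise_programming
    0.05,     # frequency_exp_lang
    0.12,     # time_experience_programming
    0.10,     # expertise_exp_lang
    0.04,     # frequency_other_langs
    0.00255,  # gender
)

DEFAULT_PLANTED_Y: tuple[float, ...] = (
    0.35436,  # total_duration
    0.26019,  # sd_pupil_radius_change
    0.209,    # peak_ratio
    0.17544,  # sd_eye_movement
)

#: Target marginal (mean, sd) for each raw cohort column before encoding.
_X_MARGINALS: dict[str, tuple[float, float]] = {
    "age": (26.560, 9.276),
    "experience_period_exp_lang": (2.0, 1.5),
    "linguistic_distance": (2.4, 0.45),
    "time_experience_programming": (2.259, 3.342),
}

_Y_MARGINALS: dict[str, tuple[float, float]] = {
    "total_duration": (15.0, 3.0),         # seconds (desk-scale tasks)
    "sd_pupil_radius_change": (0.05, 0.01),  # px
    "peak_ratio": (0.5, 0.12),             # events / s
    "sd_eye_movement": (5.0, 1.0),         # px
}

_ORDINAL_COLUMNS = (
    "english_level",
    "expertise_programming",
    "frequency_exp_lang",
    "expertise_exp_lang",
    "frequency_other_langs",
)


@dataclass(frozen=True)
class GazeSimParams:
    """Parameters of one synthetic gaze recording."""

    duration_s: float = 20.0
    rate_hz: float = 250.0
    n_saccades: int = 10
    saccade_amplitude_px: float = 50.0
    fixation_jitter_sd_px: float = 0.5
    pupil_baseline_px: float = 40.0
    pupil_noise_sd_px: float = 0.05
    blink_count: int = 0
    blink_duration_ms: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise InvalidParameterError(f"duration_s must be > 0, got {self.duration_s}")
        if not self.rate_hz > 0:
            raise InvalidParameterError(f"rate_hz must be > 0, got {self.rate_hz}")
        if self.n_saccades < 0:
            raise InvalidParameterError("n_saccades must be >= 0")
        if self.blink_count < 0:
            raise InvalidParameterError("blink_count must be >= 0")
        for name in ("saccade_amplitude_px", "fixation_jitter_sd_px", "pupil_noise_sd_px"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of one synthetic participant cohort.

    Planted weight vectors are normalized to unit Euclidean norm on
    construction; a cohort below 20 participants is rejected because CCA on
    a 10 + 4 variable problem is underdetermined there.
    """

    n_participants: int = 216
    planted_weights_x: tuple[float, ...] = DEFAULT_PLANTED_X
    planted_weights_y: tuple[float, ...] = DEFAULT_PLANTED_Y
    latent_sd: float = 1.0
    noise_sd: float = 0.5
    female_fraction: float = DEFAULT_FEMALE_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 20:
            raise InvalidParameterError(
                f"n_participants must be >= 20, got {self.n_participants}"
            )
        if self.latent_sd < 0 or self.noise_sd < 0:
            raise InvalidParameterError("latent_sd and noise_sd must be >= 0")
        for name, expect in (("planted_weights_x", 10), ("planted_weights_y", 4)):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != (expect,):
                raise InvalidParameterError(f"{name} must have length {expect}")
            norm = float(np.linalg.norm(w))
            if norm == 0:
                raise InvalidParameterError(f"{name} must be nonzero")
            object.__setattr__(self, name, tuple(w / norm))
        if not 0.0 < self.female_fraction < 1.0:
            raise InvalidParameterError("female_fraction must be in (0, 1)")

    @property
    def w_x(self) -> np.ndarray:
        return np.asarray(self.planted_weights_x)

    @property
    def w_y(self) -> np.ndarray:
        return np.asarray(self.planted_weights_y)


def _spaced_onsets(
    rng: np.random.Generator, k: int, n: int, min_sep: int, margin: int
) -> np.ndarray:
    """k sorted onset indices in [margin, n - margin) at least min_sep apart."""
    lo, hi = margin, n - margin
    slack = (hi - lo) - (k - 1) * min_sep
    if k > 0 and slack < k:
        raise InvalidParameterError(
            f"cannot place {k} saccades {min_sep} samples apart in {n} samples"
        )
    if k == 0:
        return np.empty(0, dtype=int)
    base = np.sort(rng.choice(slack, size=k, replace=False))
    return lo + base + np.arange(k) * min_sep


def generate_gaze_recording(
    params: GazeSimParams,
    participant_id: str = "sim",
    task_id: str = "rectangle",
) -> tuple[GazeRecording, list[int]]:
    """Simulate one gaze recording; returns (recording, true onset indices).

    Fixation positions are piecewise constant with an instantaneous jump of
    magnitude ``saccade_amplitude_px`` (random direction) at each true onset;
    coordinates carry additive Gaussian jitter; pupil diameter is baseline
    plus Gaussian noise, with ``blink_count`` zero-diameter gaps. The output
    is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    rate = params.rate_hz
    time_s = (np.arange(n) * (1000.0 / rate)) / 1000.0

    min_sep = max(2, int(round(MIN_SACCADE_SPACING_S * rate)))
    margin = max(10, min_sep)
    onsets = _spaced_onsets(rng, params.n_saccades, n, min_sep, margin)

    x = np.full(n, 512.0)
    y = np.full(n, 384.0)
    for idx in onsets:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        x[idx:] += params.saccade_amplitude_px * math.cos(theta)
        y[idx:] += params.saccade_amplitude_px * math.sin(theta)
    if params.fixation_jitter_sd_px > 0:
        x = x + rng.normal(0.0, params.fixation_jitter_sd_px, n)
        y = y + rng.normal(0.0, params.fixation_jitter_sd_px, n)

    diam = np.full(n, params.pupil_baseline_px)
    if params.pupil_noise_sd_px > 0:
        diam = diam + rng.normal(0.0, params.pupil_noise_sd_px, n)

    valid = np.ones(n, dtype=bool)
    if params.blink_count > 0:
        blink_len = max(1, int(round(params.blink_duration_ms / 1000.0 * rate)))
        taken = np.zeros(n, dtype=bool)
        pad = 5
        for idx in onsets:  # keep blinks clear of true events
            taken[max(0, idx - pad) : idx + pad] = True
        placed = 0
        for start in rng.permutation(n - blink_len - 2 * margin) + margin:
            stop = start + blink_len
            if not taken[start - 1 : stop + 1].any():
                diam[start:stop] = 0.0
                valid[start:stop] = False
                taken[max(0, start - blink_len) : stop + blink_len] = True
                placed += 1
                if placed == params.blink_count:
                    break
        if placed < params.blink_count:
            raise InvalidParameterError(
                f"could not place {params.blink_count} non-overlapping blinks"
            )

    rec = GazeRecording(
        participant_id=participant_id,
        task_id=task_id,
        time_s=time_s,
        x_px=x,
        y_px=y,
        diam_px=diam,
        valid=valid,
        rate_hz=rate,
    )
    return rec, [int(i) for i in onsets]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_SCORE_TO_LANGUAGES: dict[float, tuple[str, ...]] = {}
for _lang, _score in DEFAULT_LINGUISTIC_DISTANCES.items():
    _SCORE_TO_LANGUAGES.setdefault(_score, tuple())
    _SCORE_TO_LANGUAGES[_score] = _SCORE_TO_LANGUAGES[_score] + (_lang.capitalize(),)
_SCORE_TO_LANGUAGES[DEFAULT_ENGLISH_SCORE] = ("English",)
_LD_SCORES = np.array(sorted(_SCORE_TO_LANGUAGES))


def _snap_linguistic_distance(values: np.ndarray) -> np.ndarray:
    """Snap continuous scores to the nearest real language score."""
    idx = np.abs(values[:, None] - _LD_SCORES[None, :]).argmin(axis=1)
    return _LD_SCORES[idx]


def _ordinalize(z: np.ndarray) -> np.ndarray:
    """Discretize standardized values into 1..5 by equal-probability bins."""
    from scipy.stats import norm

    edges = norm.ppf([0.2, 0.4, 0.6, 0.8])
    return (np.searchsorted(edges, z) + 1).astype(float)


def generate_cohort(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a participant cohort with a planted cross-set latent factor.

    Returns ``(X, Y, truth)`` where X is the n x 10 independent-variable
    DataFrame (realistic marginals, ordinal and binary encodings applied),
    Y the n x 4 dependent-variable DataFrame, and ``truth`` holds the
    unit-norm planted weight vectors, the latent values, and the language
    names matching X's snapped linguistic-distance column.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    z = rng.normal(0.0, params.latent_sd, n)
    X0 = np.outer(z, params.w_x) + rng.normal(0.0, params.noise_sd, (n, 10))
    Y0 = np.outer(z, params.w_y) + rng.normal(0.0, params.noise_sd, (n, 4))

    # theoretical per-column SD of the raw latent-plus-noise values
    sd_x = np.sqrt(params.w_x**2 * params.latent_sd**2 + params.noise_sd**2)
    sd_y = np.sqrt(params.w_y**2 * params.latent_sd**2 + params.noise_sd**2)
    sd_x[sd_x == 0] = 1.0
    sd_y[sd_y == 0] = 1.0
    Xs = X0 / sd_x
    Ys = Y0 / sd_y

    X = pd.DataFrame(index=pd.RangeIndex(n), columns=list(INDEPENDENT_VARIABLES), dtype=float)
    languages = None
    for j, name in enumerate(INDEPENDENT_VARIABLES):
        col = Xs[:, j]
        if name in _X_MARGINALS:
            mean, sd = _X_MARGINALS[name]
            vals = mean + sd * col
            if name == "linguistic_distance":
                vals = _snap_linguistic_distance(vals)
                languages = [
                    _SCORE_TO_LANGUAGES[v][rng.integers(len(_SCORE_TO_LANGUAGES[v]))]
                    for v in vals
                ]
            X[name] = vals
        elif name in _ORDINAL_COLUMNS:
            X[name] = _ordinalize(col)
        elif name == "gender":
            thresh = np.quantile(col, 1.0 - params.female_fraction)
            X[name] = (col > thresh).astype(float)
        else:  # pragma: no cover - all columns handled above
            X[name] = col

    Y = pd.DataFrame(index=pd.RangeIndex(n), columns=list(DEPENDENT_VARIABLES), dtype=float)
    for j, name in enumerate(DEPENDENT_VARIABLES):
        mean, sd = _Y_MARGINALS[name]
        Y[name] = mean + sd * Ys[:, j]

    X.index = Y.index = [f"P{i:03d}" for i in range(n)]
    truth = {
        "w_x": params.w_x.copy(),
        "w_y": params.w_y.copy(),
        "latent": z,
        "native_language": pd.Series(languages, index=X.index),
    }
    return X, Y, truth


# ---------------------------------------------------------------------------
# dataset writing
# ---------------------------------------------------------------------------

DEFAULT_TASKS: tuple[str, ...] = ("rectangle", "vehicle")


def _participant_gaze_params(
    base: GazeSimParams, y_row: pd.Series, seed: int
) -> GazeSimParams:
    """Derive gaze-simulation parameters from a participant's feature row.

    Duration, pupil-noise SD, saccade count, and saccade amplitude are set
    from the planted dependent variables (clipped into valid, detectable
    ranges) so features extracted from the written files inherit the planted
    cross-set structure.
    """
    duration = float(max(5.0, y_row["total_duration"]))
    peak_ratio = float(max(0.05, y_row["peak_ratio"]))
    max_events = int(duration / MIN_SACCADE_SPACING_S * 0.5)
    n_sacc = int(np.clip(round(peak_ratio * duration), 0, max_events))
    return GazeSimParams(
        duration_s=duration,
        rate_hz=base.rate_hz,
        n_saccades=n_sacc,
        saccade_amplitude_px=float(np.clip(10.0 * y_row["sd_eye_movement"], 20.0, 200.0)),
        fixation_jitter_sd_px=base.fixation_jitter_sd_px,
        pupil_baseline_px=base.pupil_baseline_px,
        pupil_noise_sd_px=float(np.clip(y_row["sd_pupil_radius_change"], 1e-3, 1.0)),
        blink_count=base.blink_count,
        blink_duration_ms=base.blink_duration_ms,
        seed=seed,
    )


def write_gaze_tsv(path: Path, rec: GazeRecording) -> None:
    """Write one recording in the tab-separated gaze dialect, full precision."""
    df = pd.DataFrame(
        {
            "time_ms": rec.time_s * 1000.0,
            "pupil_x_px": rec.x_px,
            "pupil_y_px": rec.y_px,
            "pupil_diam_px": rec.diam_px,
        }
    )
    assert tuple(df.columns) == GAZE_COLUMNS
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_synthetic_dataset(
    out_dir: str | Path,
    cohort: CohortSimParams | None = None,
    base_gaze: GazeSimParams | None = None,
    tasks: tuple[str, ...] = DEFAULT_TASKS,
) -> dict:
    """Emit a full synthetic dataset in the dialect the readers consume.

    Produces ``metadata.csv`` plus ``gaze/<participant>_<task>.tsv`` for each
    participant and task, and returns a manifest holding the file lists, the
    planted truth, and the per-file true saccade onsets. Per-file seeds are
    derived deterministically from the cohort seed.
    """
    out_dir = Path(out_dir)
    if cohort is None:
        cohort = CohortSimParams()
    if base_gaze is None:
        base_gaze = GazeSimParams()

    gaze_dir = out_dir / "gaze"
    gaze_dir.mkdir(parents=True, exist_ok=True)

    X, Y, truth = generate_cohort(cohort)
    meta = X.copy()
    meta.insert(0, "participant_id", X.index)
    meta["native_language"] = truth["native_language"].values
    meta = meta.drop(columns=["linguistic_distance"])
    meta_path = out_dir / "metadata.csv"
    meta.to_csv(meta_path, index=False, float_format="%.17g")

    gaze_files: dict[str, dict[str, str]] = {}
    onsets: dict[str, dict[str, list[int]]] = {}
    for i, pid in enumerate(X.index):
        gaze_files[pid] = {}
        onsets[pid] = {}
        for j, task in enumerate(tasks):
            seed = int(
                np.random.SeedSequence([cohort.seed, i, j]).generate_state(1)[0]
                % (2**31)
            )
            gp = _participant_gaze_params(base_gaze, Y.loc[pid], seed)
            rec, true_onsets = generate_gaze_recording(gp, pid, task)
            path = gaze_dir / f"{pid}_{task}.tsv"
            write_gaze_tsv(path, rec)
            gaze_files[pid][task] = str(path)
            onsets[pid][task] = true_onsets

    return {
        "metadata_path": str(meta_path),
        "gaze_dir": str(gaze_dir),
        "gaze_files": gaze_files,
        "true_onsets": onsets,
        "X": X,
        "Y": Y,
        "truth": truth,
        "tasks": list(tasks),
    }
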