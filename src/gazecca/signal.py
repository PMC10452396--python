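"""Gaze-signal processing: smoothing, saccade detection, feature extraction.

Saccades appear as step discontinuities in the pupil-center coordinates, so
the per-sample Euclidean displacement magnitude is a spike train: near zero
during fixations, with an isolated peak at each saccade. Peaks are flagged
with an adaptive (smoothed) z-score detector governed by three parameters —
lag ``l`` (rolling-window length), threshold ``ths`` (z-score cutoff), and
influence ``in`` (how much a flagged sample is allowed to move the rolling
baseline). Flagged samples enter the baseline attenuated by the influence
factor, so a burst of high samples does not immediately inflate the rolling
mean/SD and mask subsequent peaks.

From each recording four dependent variables are extracted: total task
duration, SD of the pupil-radius first difference, the rate of detected
saccadic events (peak ratio), and the SD of eye-movement displacement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateInputError, InvalidParameterError
from .gaze_io import GazeRecording

logger = logging.getLogger(__name__)

#: Ordered dependent-variable names; downstream weight indices follow this.
DEPENDENT_VARIABLES: tuple[str, ...] = (
    "total_duration",
    "sd_pupil_radius_change",
    "peak_ratio",
    "sd_eye_movement",
)

#: Invalid runs at most this long are bridged by linear interpolation;
#: longer runs (true blinks) split the recording into independent segments.
DEFAULT_MAX_GAP_MS: float = 75.0


@dataclass(frozen=True)
class PeakDetectorParams:
    """Adaptive z-score detector parameters (threshold, lag, influence)."""

    ths: float = 5.0
    lag: int = 5
    influence: float = 0.5

    def __post_init__(self) -> None:
        if not self.ths > 0:
            raise InvalidParameterError(f"ths must be > 0, got {self.ths}")
        if self.lag < 2:
            raise InvalidParameterError(f"lag must be >= 2, got {self.lag}")
        if not 0.0 <= self.influence <= 1.0:
            raise InvalidParameterError(
                f"influence must be in [0, 1], got {self.influence}"
            )


@dataclass(frozen=True)
class SmootherParams:
    """Savitzky-Golay smoothing parameters.

    The default 11-sample window spans 44 ms at 250 Hz: long enough to
    suppress tracker noise, short enough to preserve saccadic steps.
    """

    window: int = 11
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window % 2 != 1 or self.window < 3:
            raise InvalidParameterError(f"window must be odd >= 3, got {self.window}")
        if not 0 <= self.polyorder < self.window:
            raise InvalidParameterError(
                f"polyorder must satisfy 0 <= polyorder < window, got {self.polyorder}"
            )


@dataclass
class ZScoreState:
    """Internal trajectories of the detector, exposed for diagnostics."""

    filtered_signal: np.ndarray
    rolling_mean: np.ndarray
    rolling_sd: np.ndarray
    flags: np.ndarray


@dataclass(frozen=True)
class FeatureVector:
    """The four dependent variables of one participant(-task)."""

    total_duration: float
    sd_pupil_radius_change: float
    peak_ratio: float
    sd_eye_movement: float

    def __post_init__(self) -> None:
        if not self.total_duration > 0:
            raise DegenerateInputError(
                f"total_duration must be > 0, got {self.total_duration}"
            )
        for name in ("sd_pupil_radius_change", "peak_ratio", "sd_eye_movement"):
            if getattr(self, name) < 0:
                raise DegenerateInputError(f"{name} must be >= 0")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in DEPENDENT_VARIABLES], dtype=float
        )


def savgol_smooth(signal: np.ndarray, params: SmootherParams | None = None) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing; length-preserving."""
    if params is None:
        params = SmootherParams()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise InvalidParameterError("savgol_smooth expects a 1-D signal")
    if len(signal) < params.window:
        raise DegenerateInputError(
            f"signal length {len(signal)} < smoothing window {params.window}"
        )
    return savgol_filter(signal, params.window, params.polyorder)


def _interp_short_gaps(rec: GazeRecording, max_gap_ms: float) -> tuple[np.ndarray, ...]:
    """Bridge invalid runs <= max_gap_ms by linear interpolation.

    Returns (x, y, diam, usable) where ``usable`` still excludes long runs.
    """
    x = rec.x_px.copy()
    y = rec.y_px.copy()
    diam = rec.diam_px.copy()
    usable = rec.valid.copy()
    dt_ms = 1000.0 / rec.rate_hz
    for start, stop in rec.invalid_runs():
        gap_ms = (stop - start) * dt_ms
        if gap_ms <= max_gap_ms and start > 0 and stop < rec.n_samples:
            lo, hi = start - 1, stop
            if rec.valid[lo] and rec.valid[hi]:
                t = rec.time_s
                for arr in (x, y, diam):
                    arr[start:stop] = np.interp(
                        t[start:stop], [t[lo], t[hi]], [arr[lo], arr[hi]]
                    )
                usable[start:stop] = True
    return x, y, diam, usable


def _contiguous_segments(usable: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) runs of usable samples."""
    segments = []
    i, n = 0, len(usable)
    while i < n:
        if usable[i]:
            j = i
            while j < n and usable[j]:
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1
    return segments


def displacement_series(
    rec: GazeRecording,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
    smoother: SmootherParams | None = None,
) -> np.ndarray:
    """Per-sample Euclidean pupil-center displacement magnitude.

    d_i = sqrt((x_i - x_{i-1})^2 + (y_i - y_{i-1})^2) over consecutive valid
    samples. Short invalid runs are interpolated; longer gaps split the
    recording and differences are never taken across segment boundaries, so
    the result is the concatenation of per-segment difference series.

    When ``smoother`` is given, coordinates are smoothed per segment first.
    """
    x, y, _, usable = _interp_short_gaps(rec, max_gap_ms)
    if int(usable.sum()) < 2:
        raise DegenerateInputError(
            f"{rec.participant_id}/{rec.task_id}: fewer than 2 valid samples"
        )
    parts = []
    for start, stop in _contiguous_segments(usable):
        if stop - start < 2:
            continue
        xs, ys = x[start:stop], y[start:stop]
        if smoother is not None and stop - start >= smoother.window:
            xs = savgol_smooth(xs, smoother)
            ys = savgol_smooth(ys, smoother)
        parts.append(np.hypot(np.diff(xs), np.diff(ys)))
    if not parts:
        raise DegenerateInputError(
            f"{rec.participant_id}/{rec.task_id}: no segment with >= 2 samples"
        )
    return np.concatenate(parts)


def detect_peaks_zscore(
    signal: np.ndarray,
    params: PeakDetectorParams | None = None,
    full_output: bool = False,
):
    """Streaming adaptive z-score peak detection.

    For each i >= lag, z_i = (s_i - mean) / sd over the previous ``lag``
    *filtered* samples (sample SD, ddof=1); the sample is flagged when
    z_i >= ths (one-sided: displacement is non-negative). A flagged sample
    enters the filtered copy attenuated, filtered_i = in*s_i +
    (1-in)*filtered_{i-1}; unflagged samples are copied through. Consecutive
    flagged samples merge into one event.

    Returns ``(flags, events)`` where flags is a 0/1 array over the signal
    and events is a list of half-open (start, stop) flagged runs; with
    ``full_output=True`` a :class:`ZScoreState` is appended.

    A zero rolling SD (exactly constant window) yields z = +inf for a sample
    strictly above the baseline and z = 0 otherwise; logged once per call.
    """
    if params is None:
        params = PeakDetectorParams()
    s = np.asarray(signal, dtype=float)
    lag = params.lag
    if s.ndim != 1:
        raise InvalidParameterError("detect_peaks_zscore expects a 1-D signal")
    if len(s) <= lag:
        raise DegenerateInputError(f"signal length {len(s)} <= lag {lag}")

    n = len(s)
    flags = np.zeros(n, dtype=np.int8)
    filtered = s[:lag].tolist()
    means = np.full(n, np.nan)
    sds = np.full(n, np.nan)
    infl = params.influence
    warned_zero_sd = False

    for i in range(lag, n):
        window = filtered[i - lag : i]
        m = sum(window) / lag
        if min(window) == max(window):  # exactly constant: sd is 0, not rounding fuzz
            sd = 0.0
        else:
            sd = (sum((v - m) ** 2 for v in window) / (lag - 1)) ** 0.5
        means[i], sds[i] = m, sd
        if sd == 0.0:
            # constant baseline: a sample strictly above it is an infinitely
            # strong peak; at or below it there is no peak
            z = math.inf if s[i] > m else 0.0
            if not warned_zero_sd:
                logger.warning("zero rolling SD at index %d", i)
                warned_zero_sd = True
        else:
            z = (s[i] - m) / sd
        if z >= params.ths:
            flags[i] = 1
            filtered.append(infl * s[i] + (1.0 - infl) * filtered[i - 1])
        else:
            filtered.append(s[i])

    events = _contiguous_segments(flags.astype(bool))
    if full_output:
        state = ZScoreState(
            filtered_signal=np.array(filtered),
            rolling_mean=means,
            rolling_sd=sds,
            flags=flags,
        )
        return flags, events, state
    return flags, events


#: Flagged runs closer than this merge into one saccadic event: a saccade
#: lasts tens of milliseconds and inter-saccadic intervals exceed ~100 ms,
#: so sub-50-ms gaps between flagged runs are one movement, not two.
DEFAULT_EVENT_MERGE_MS: float = 50.0


def merge_close_events(
    events: list[tuple[int, int]], gap: int
) -> list[tuple[int, int]]:
    """Merge half-open index runs separated by at most ``gap`` samples."""
    merged: list[tuple[int, int]] = []
    for a, b in events:
        if merged and a - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def saccade_events(
    signal: np.ndarray,
    params: PeakDetectorParams | None = None,
    rate_hz: float = 250.0,
    merge_ms: float = DEFAULT_EVENT_MERGE_MS,
    peak_halfwidth: int = 5,
) -> list[tuple[int, int]]:
    """Saccadic events: adaptive z-score candidates validated globally.

    Candidate runs come from :func:`detect_peaks_zscore`; runs closer than
    ``merge_ms`` merge into one event; each event must then reach the
    detection threshold on the *whole-series* z-score (z = (x - mean)/SD over
    the full displacement vector), evaluated at the event's local maximum
    within ``peak_halfwidth`` samples. The rolling detector is scale-free and
    occasionally flags fixation noise; the global criterion anchors events to
    the magnitude scale of the recording, where genuine saccadic steps stand
    far above the jitter floor.
    """
    if params is None:
        params = PeakDetectorParams()
    s = np.asarray(signal, dtype=float)
    _, events = detect_peaks_zscore(s, params)
    gap = max(1, int(round(merge_ms / 1000.0 * rate_hz)))
    merged = merge_close_events(events, gap)
    mean = s.mean()
    sd = s.std(ddof=1) if len(s) > 1 else 0.0
    if sd == 0.0:
        return []
    kept = []
    for a, b in merged:
        peak = s[max(0, a - peak_halfwidth) : min(len(s), b + peak_halfwidth)].max()
        if (peak - mean) / sd >= params.ths:
            kept.append((a, b))
    return kept


def extract_features(
    rec: GazeRecording,
    smoother: SmootherParams | None = None,
    detector: PeakDetectorParams | None = None,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
    event_merge_ms: float = DEFAULT_EVENT_MERGE_MS,
    raw_displacement: bool = False,
    peak_rate_per_sample: bool = False,
) -> FeatureVector:
    """Compute the four dependent variables from one gaze recording.

    total_duration is the recorded time span; sd_eye_movement the SD of the
    (smoothed by default) displacement series; peak_ratio the merged saccadic
    event count per second (per valid sample with ``peak_rate_per_sample``);
    sd_pupil_radius_change the SD of the first difference of the smoothed
    pupil radius, never differenced across blink-segment boundaries.
    """
    if smoother is None:
        smoother = SmootherParams()
    if detector is None:
        detector = PeakDetectorParams()
    try:
        total_duration = rec.duration_s
        if total_duration <= 0:
            raise DegenerateInputError("recording spans no time")

        disp = displacement_series(
            rec, max_gap_ms=max_gap_ms, smoother=None if raw_displacement else smoother
        )
        sd_eye_movement = float(np.std(disp, ddof=1)) if len(disp) > 1 else 0.0

        events = saccade_events(
            disp,
            detector,
            rate_hz=rec.rate_hz,
            merge_ms=event_merge_ms,
            peak_halfwidth=(smoother.window // 2) if not raw_displacement else 2,
        )
        denom = len(disp) if peak_rate_per_sample else total_duration
        peak_ratio = len(events) / denom

        _, _, diam, usable = _interp_short_gaps(rec, max_gap_ms)
        radius_diffs = []
        for start, stop in _contiguous_segments(usable):
            if stop - start < 2:
                continue
            r = diam[start:stop] / 2.0
            if stop - start >= smoother.window:
                r = savgol_smooth(r, smoother)
            radius_diffs.append(np.diff(r))
        if not radius_diffs:
            raise DegenerateInputError("no usable pupil-diameter segment")
        rdiff = np.concatenate(radius_diffs)
        sd_pupil = float(np.std(rdiff, ddof=1)) if len(rdiff) > 1 else 0.0

        return FeatureVector(
            total_duration=float(total_duration),
            sd_pupil_radius_change=sd_pupil,
            peak_ratio=float(peak_ratio),
            sd_eye_movement=sd_eye_movement,
        )
    except DegenerateInputError as exc:
        raise DegenerateInputError(
            f"{rec.participant_id}/{rec.task_id}: {exc}"
        ) from exc
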