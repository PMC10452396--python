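"""Gaze-recording and participant-metadata I/O.

Reads the tab-separated gaze dialect (``time_ms, pupil_x_px, pupil_y_px,
pupil_diam_px``) exported per participant and task, and the cohort metadata
CSV carrying the ten personal variables used as the independent set:
age, experience period in the experiment language, linguistic distance,
English level, programming expertise, experiment-language frequency, years of
programming experience, experiment-language expertise, other-language
frequency, and gender.

Native language arrives as a categorical string and is converted to a
quantitative linguistic-distance score (distance of the language from
English on a 0-3.5 scale where *higher* means *closer*); native English
speakers receive a configurable score that sits above every listed language.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    LanguageMappingError,
    TooShortRecordingError,
)

logger = logging.getLogger(__name__)

#: Ordered independent-variable names; downstream weight indices follow this.
INDEPENDENT_VARIABLES: tuple[str, ...] = (
    "age",
    "experience_period_exp_lang",
    "linguistic_distance",
    "english_level",
    "expertise_programming",
    "frequency_exp_lang",
    "time_experience_programming",
    "expertise_exp_lang",
    "frequency_other_langs",
    "gender",
)

GAZE_COLUMNS: tuple[str, ...] = ("time_ms", "pupil_x_px", "pupil_y_px", "pupil_diam_px")

#: Linguistic distance of sample languages from English. Higher = closer.
DEFAULT_LINGUISTIC_DISTANCES: dict[str, float] = {
    "german": 2.25,
    "italian": 2.5,
    "portuguese": 2.5,
    "spanish": 2.25,
    "finnish": 2.00,
    "turkish": 2.00,
    "greek": 1.75,
    "thai": 2.00,
    "chinese": 1.50,
}

#: Score assigned to native English speakers (closer than any listed language).
DEFAULT_ENGLISH_SCORE: float = 3.0

MIN_GAZE_SAMPLES = 50


@dataclass
class LinguisticDistanceTable:
    """Case-insensitive mapping from language name to linguistic distance."""

    scores: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINGUISTIC_DISTANCES)
    )

    def __post_init__(self) -> None:
        self.scores = {k.strip().lower(): float(v) for k, v in self.scores.items()}
        for lang, score in self.scores.items():
            if not 0.0 < score <= 3.5:
                raise ValueError(f"linguistic distance for {lang!r} outside (0, 3.5]: {score}")

    @classmethod
    def default(cls) -> "LinguisticDistanceTable":
        return cls()

    @classmethod
    def from_csv(cls, path: str | Path) -> "LinguisticDistanceTable":
        """Load a user-extensible two-column (language, score) table."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise FormatError(f"{path}: expected columns (language, score)")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))

    def __contains__(self, language: str) -> bool:
        return language.strip().lower() in self.scores

    def lookup(self, language: str) -> float:
        key = language.strip().lower()
        try:
            return self.scores[key]
        except KeyError:
            raise LanguageMappingError(
                f"language {language!r} not in linguistic-distance table; "
                f"known: {sorted(self.scores)}"
            ) from None


def lookup_linguistic_distance(
    language: str, table: LinguisticDistanceTable | Mapping[str, float] | None = None
) -> float:
    """Return the linguistic-distance score of ``language`` (case-insensitive).

    Raises :class:`LanguageMappingError` for unknown languages.
    """
    if table is None:
        table = LinguisticDistanceTable.default()
    elif not isinstance(table, LinguisticDistanceTable):
        table = LinguisticDistanceTable(dict(table))
    return table.lookup(language)


@dataclass
class GazeRecording:
    """One participant-task pupil time series.

    ``valid`` marks samples usable for analysis; samples with non-positive or
    missing pupil diameter (blinks, tracking loss) are retained but flagged
    invalid rather than dropped, so sample indexing matches the source file.
    """

    participant_id: str
    task_id: str
    time_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    diam_px: np.ndarray
    valid: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("x_px", "y_px", "diam_px", "valid"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"{name} length != time length ({n})")
        if n >= 2 and not np.all(np.diff(self.time_s) > 0):
            bad = int(np.argmax(np.diff(self.time_s) <= 0)) + 1
            raise FormatError(f"timestamps not strictly increasing at row {bad}")
        if not self.rate_hz > 0:
            raise FormatError(f"rate_hz must be positive, got {self.rate_hz}")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def invalid_runs(self) -> list[tuple[int, int]]:
        """Half-open ``(start, stop)`` index runs of consecutive invalid samples."""
        runs: list[tuple[int, int]] = []
        inval = ~self.valid
        i = 0
        n = len(inval)
        while i < n:
            if inval[i]:
                j = i
                while j < n and inval[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        return runs


@dataclass
class ParticipantProfile:
    """The ten personal variables of one programmer, in canonical order.

    ``native_language`` is retained for provenance; its quantitative form is
    ``linguistic_distance``.
    """

    participant_id: str
    age: float
    experience_period_exp_lang: float
    linguistic_distance: float
    english_level: float
    expertise_programming: float
    frequency_exp_lang: float
    time_experience_programming: float
    expertise_exp_lang: float
    frequency_other_langs: float
    gender: int
    native_language: str = ""

    def __post_init__(self) -> None:
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise FormatError(
                f"participant {self.participant_id}: non-finite metadata value"
            )
        if self.linguistic_distance <= 0:
            raise FormatError(
                f"participant {self.participant_id}: linguistic_distance must be > 0"
            )
        if self.gender not in (0, 1):
            raise FormatError(
                f"participant {self.participant_id}: gender must be 0 or 1, "
                f"got {self.gender}"
            )

    def to_vector(self) -> np.ndarray:
        """Numeric independent-variable vector in :data:`INDEPENDENT_VARIABLES` order."""
        return np.array(
            [getattr(self, name) for name in INDEPENDENT_VARIABLES], dtype=float
        )


def read_gaze_file(
    path: str | Path, participant_id: str, task_id: str
) -> GazeRecording:
    """Parse one gaze TSV into a validated :class:`GazeRecording`.

    The sampling rate is inferred as ``1 / median(dt)``. Rows with
    unparsable fields or non-positive diameter are marked invalid, never
    dropped, so ``n_input_rows == n_valid + n_invalid``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TooShortRecordingError(f"{path}: empty file") from None
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < MIN_GAZE_SAMPLES:
        raise TooShortRecordingError(
            f"{path}: {len(df)} samples < minimum {MIN_GAZE_SAMPLES}"
        )

    cols = {c: pd.to_numeric(df[c], errors="coerce").to_numpy(float) for c in GAZE_COLUMNS}
    time_s = cols["time_ms"] / 1000.0
    if np.any(~np.isfinite(time_s)):
        bad = int(np.argmax(~np.isfinite(time_s)))
        raise FormatError(f"{path}: unparsable timestamp at row {bad}")
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise FormatError(f"{path}: timestamps not strictly increasing at row {bad}")
    rate_hz = 1.0 / float(np.median(dt))

    diam = cols["pupil_diam_px"]
    x, y = cols["pupil_x_px"], cols["pupil_y_px"]
    valid = np.isfinite(x) & np.isfinite(y) & np.isfinite(diam) & (diam > 0)
    n_invalid = int((~valid).sum())
    logger.info(
        "%s [%s/%s]: %d rows = %d valid + %d invalid, rate %.1f Hz",
        path.name, participant_id, task_id, len(df), len(df) - n_invalid,
        n_invalid, rate_hz,
    )
    return GazeRecording(
        participant_id=participant_id,
        task_id=task_id,
        time_s=time_s,
        x_px=x,
        y_px=y,
        diam_px=diam,
        valid=valid,
        rate_hz=rate_hz,
    )


METADATA_REQUIRED = ("participant_id", "native_language") + tuple(
    v for v in INDEPENDENT_VARIABLES if v != "linguistic_distance"
)


def read_metadata(
    path: str | Path,
    ld_table: LinguisticDistanceTable | None = None,
    english_score: float = DEFAULT_ENGLISH_SCORE,
) -> list[ParticipantProfile]:
    """Read the cohort metadata CSV into :class:`ParticipantProfile` objects.

    ``native_language`` is resolved through ``ld_table`` (case-insensitive);
    native English speakers receive ``english_score``. Unknown languages and
    duplicate participant ids are hard errors.
    """
    if ld_table is None:
        ld_table = LinguisticDistanceTable.default()
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    ids = df["participant_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise FormatError(f"{path}: duplicate participant_id values {dupes}")

    unknown = sorted(
        {
            lang
            for lang in df["native_language"].astype(str)
            if lang.strip().lower() != "english" and lang not in ld_table
        }
    )
    if unknown:
        raise LanguageMappingError(
            f"{path}: native languages not in linguistic-distance table: {unknown}"
        )

    profiles = []
    for _, row in df.iterrows():
        lang = str(row["native_language"])
        ld = english_score if lang.strip().lower() == "english" else ld_table.lookup(lang)
        profiles.append(
            ParticipantProfile(
                participant_id=str(row["participant_id"]),
                age=float(row["age"]),
                experience_period_exp_lang=float(row["experience_period_exp_lang"]),
                linguistic_distance=float(ld),
                english_level=float(row["english_level"]),
                expertise_programming=float(row["expertise_programming"]),
                frequency_exp_lang=float(row["frequency_exp_lang"]),
                time_experience_programming=float(row["time_experience_programming"]),
                expertise_exp_lang=float(row["expertise_exp_lang"]),
                frequency_other_langs=float(row["frequency_other_langs"]),
                gender=int(row["gender"]),
                native_language=lang,
            )
        )
    return profiles


def profiles_to_matrix(profiles: Iterable[ParticipantProfile]) -> pd.DataFrame:
    """Stack profiles into the n x 10 independent-variable DataFrame.

    Column order follows :data:`INDEPENDENT_VARIABLES` so canonical-weight
    indices are stable downstream.
    """
    profiles = list(profiles)
    data = np.vstack([p.to_vector() for p in profiles])
    return pd.DataFrame(
        data,
        columns=list(INDEPENDENT_VARIABLES),
        index=[p.participant_id for p in profiles],
    )
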