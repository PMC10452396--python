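"""End-to-end orchestration: ingest -> features -> statistics -> attribution.

:func:`run_pipeline` reads the participant metadata and per-task gaze
recordings, extracts the four eye-movement features per recording, aggregates
them per participant (mean over the two code-comprehension tasks by
default), z-scores both variable sets, runs the correlation screens and the
canonical correlation analysis, and converts the first canonical pair's
weights into percentage attributions. Participant-level failures (missing
recordings, degenerate signals) become logged exclusions, never fatal;
cohort-level problems (too few participants, constant columns) abort with a
diagnostic.

Every run writes CSV report tables, a JSON attribution file, and a manifest
of all materialized parameters sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateInputError, GazeccaError, InsufficientSampleError
from .gaze_io import (
    DEFAULT_ENGLISH_SCORE,
    INDEPENDENT_VARIABLES,
    LinguisticDistanceTable,
    ParticipantProfile,
    profiles_to_matrix,
    read_gaze_file,
    read_metadata,
)
from .mvstats import (
    AttributionReport,
    CanonicalCorrelation,
    CCAResults,
    CorrelationReport,
    correlation_screen,
    zscore_normalize,
)
from .signal import (
    DEFAULT_MAX_GAP_MS,
    DEPENDENT_VARIABLES,
    PeakDetectorParams,
    SmootherParams,
    extract_features,
)

logger = logging.getLogger(__name__)

MIN_COHORT = 20


@dataclass
class RunConfig:
    """Materialized configuration of one pipeline run."""

    data_dir: str
    metadata_path: str
    output_dir: str
    tasks: tuple[str, ...] = ("rectangle", "vehicle")
    detector: PeakDetectorParams = field(default_factory=PeakDetectorParams)
    smoother: SmootherParams = field(default_factory=SmootherParams)
    english_score: float = DEFAULT_ENGLISH_SCORE
    ld_table_path: str | None = None
    aggregate_tasks: bool = True
    max_gap_ms: float = DEFAULT_MAX_GAP_MS
    corr_kind: str = "pairwise"
    cca_ridge: float = 1e-8
    cca_pair: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        detector = PeakDetectorParams(**raw.pop("detector", {}))
        smoother = SmootherParams(**raw.pop("smoother", {}))
        tasks = tuple(raw.pop("tasks", ("rectangle", "vehicle")))
        return cls(detector=detector, smoother=smoother, tasks=tasks, **raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["tasks"] = list(self.tasks)
        return d


@dataclass
class RunReport:
    """All artifacts of one pipeline run, kept in memory and written to disk."""

    config: RunConfig
    cohort_descriptives: pd.DataFrame
    feature_table: pd.DataFrame
    corr_within_y: CorrelationReport
    corr_within_x: CorrelationReport
    corr_cross: CorrelationReport
    cca: CCAResults
    attribution: AttributionReport
    exclusions: pd.DataFrame
    included_ids: list[str]


def describe_cohort(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    """Descriptive statistics table: gender counts, age and experience mean/SD."""
    if not profiles:
        raise DegenerateInputError("empty profile list")
    ages = np.array([p.age for p in profiles])
    exp = np.array([p.time_experience_programming for p in profiles])
    genders = np.array([p.gender for p in profiles])
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    rows = [
        ("n_gender_0", float((genders == 0).sum())),
        ("n_gender_1", float((genders == 1).sum())),
        ("mean_age", float(ages.mean())),
        ("sd_age", sd(ages)),
        ("mean_time_experience_programming", float(exp.mean())),
        ("sd_time_experience_programming", sd(exp)),
    ]
    return pd.DataFrame(rows, columns=["parameter", "value"]).set_index("parameter")


def _gaze_path(config: RunConfig, pid: str, task: str) -> Path:
    return Path(config.data_dir) / f"{pid}_{task}.tsv"


def compute_feature_table(
    config: RunConfig, profiles: list[ParticipantProfile]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-recording features plus an exclusion table with reasons.

    In aggregate mode a participant missing either task is excluded; in
    per-task mode each available recording stands alone.
    """
    rows = []
    exclusions = []
    for prof in profiles:
        pid = prof.participant_id
        per_task: dict[str, np.ndarray] = {}
        reasons = []
        for task in config.tasks:
            path = _gaze_path(config, pid, task)
            if not path.exists():
                reasons.append(f"missing gaze file {path.name}")
                continue
            try:
                rec = read_gaze_file(path, pid, task)
                fv = extract_features(
                    rec,
                    smoother=config.smoother,
                    detector=config.detector,
                    max_gap_ms=config.max_gap_ms,
                )
            except GazeccaError as exc:
                reasons.append(f"{task}: {exc}")
                continue
            per_task[task] = fv.to_vector()

        if config.aggregate_tasks:
            if len(per_task) < len(config.tasks):
                exclusions.append((pid, "; ".join(reasons) or "missing recordings"))
                continue
            vec = np.mean(list(per_task.values()), axis=0)
            rows.append((pid, "aggregate", *vec))
        else:
            if not per_task:
                exclusions.append((pid, "; ".join(reasons) or "no recordings"))
                continue
            for task, vec in per_task.items():
                rows.append((pid, task, *vec))

    features = pd.DataFrame(
        rows, columns=["participant_id", "task_id", *DEPENDENT_VARIABLES]
    )
    excl = pd.DataFrame(exclusions, columns=["participant_id", "reason"])
    return features, excl


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all report artifacts.

    Deterministic for a fixed config and inputs. Raises
    :class:`InsufficientSampleError` if fewer than 20 participants survive
    feature extraction.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ld_table = (
        LinguisticDistanceTable.from_csv(config.ld_table_path)
        if config.ld_table_path
        else LinguisticDistanceTable.default()
    )
    profiles = read_metadata(
        config.metadata_path, ld_table=ld_table, english_score=config.english_score
    )
    logger.info("read %d participant profiles", len(profiles))

    features, exclusions = compute_feature_table(config, profiles)
    included = sorted(features["participant_id"].unique())
    excluded = set(exclusions["participant_id"])
    # inclusion/exclusion must partition the metadata set
    assert set(included) | excluded == {p.participant_id for p in profiles}

    kept = [p for p in profiles if p.participant_id in set(included)]
    if len(kept) < MIN_COHORT:
        raise InsufficientSampleError(
            f"only {len(kept)} participants with complete data (< {MIN_COHORT})"
        )

    if config.aggregate_tasks:
        ymat = features.set_index("participant_id")[list(DEPENDENT_VARIABLES)]
    else:
        ymat = (
            features.groupby("participant_id")[list(DEPENDENT_VARIABLES)].mean()
        )
    xmat = profiles_to_matrix(kept).loc[ymat.index]

    Xs = zscore_normalize(xmat)
    Ys = zscore_normalize(ymat)
    corr_within_y = correlation_screen(Ys, kind=config.corr_kind)
    corr_within_x = correlation_screen(Xs, kind=config.corr_kind)
    corr_cross = correlation_screen(Xs, Ys, kind=config.corr_kind)

    cca = CanonicalCorrelation(
        xmat, ymat, ridge=config.cca_ridge
    ).fit()
    attribution = cca.attribution(pair=config.cca_pair)
    descriptives = describe_cohort(kept)

    report = RunReport(
        config=config,
        cohort_descriptives=descriptives,
        feature_table=features,
        corr_within_y=corr_within_y,
        corr_within_x=corr_within_x,
        corr_cross=corr_cross,
        cca=cca,
        attribution=attribution,
        exclusions=exclusions,
        included_ids=list(ymat.index),
    )
    _write_report(report, out_dir)
    return report


def _write_report(report: RunReport, out_dir: Path) -> None:
    fmt = "%.10g"
    report.cohort_descriptives.to_csv(out_dir / "cohort_descriptives.csv", float_format=fmt)
    report.feature_table.to_csv(out_dir / "features.csv", index=False, float_format=fmt)
    report.exclusions.to_csv(out_dir / "exclusions.csv", index=False)
    for name, rep in (
        ("corr_dependent", report.corr_within_y),
        ("corr_independent", report.corr_within_x),
        ("corr_cross", report.corr_cross),
    ):
        # header records whether these are pairwise or partial coefficients
        with open(out_dir / f"{name}.csv", "w") as fh:
            fh.write(f"# kind={rep.kind} n={rep.n}\n")
            rep.r.round(3).to_csv(fh)
        rep.p_values.to_csv(out_dir / f"{name}_pvalues.csv", float_format=fmt)
    for name, frame in report.cca.to_frames().items():
        frame.to_csv(out_dir / f"cca_{name}.csv", float_format=fmt)
    with open(out_dir / "cca_summary.txt", "w") as fh:
        fh.write(report.cca.summary() + "\n")
    with open(out_dir / "attribution.json", "w") as fh:
        json.dump(report.attribution.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(report.config.to_manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
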