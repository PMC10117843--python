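"""Cohort file schemas, validation/recode rules, and report formatting.

The interchange format is a pair of CSV files:

``workers.csv`` — one row per worker:
    worker_id, plant, race, sex, pay_type, birth_date, hire_date,
    termination_date, ever_smoker, asbestos_exposed, vital_status,
    death_date, cause  (dates ISO-8601; death_date/cause empty when alive)

``exposures.csv`` — one row per exposure segment, keyed by worker_id:
    worker_id, start_date, end_date, intensity_ppm
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import pandas as pd

from .cohort import WorkerRecord
from .persontime import (AIE_CUTPOINTS, CUMULATIVE_CUTPOINTS, CategorySpec,
                         CohortValidationError, ExposureHistory)

log = logging.getLogger("occohort")

WORKER_COLUMNS = ["worker_id", "plant", "race", "sex", "pay_type", "birth_date",
                  "hire_date", "termination_date", "ever_smoker", "asbestos_exposed",
                  "vital_status", "death_date", "cause"]
EXPOSURE_COLUMNS = ["worker_id", "start_date", "end_date", "intensity_ppm"]


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end analysis pipeline."""

    cohort_path: str | None = None          # workers.csv (None => simulate)
    exposures_path: str | None = None
    rates_paths: dict[str, str] = field(default_factory=dict)  # label -> csv
    follow_up: tuple[date, date] = (date(1942, 1, 1), date(2011, 12, 31))
    lag: float = 10.0
    cumulative_cutpoints: tuple[float, ...] = CUMULATIVE_CUTPOINTS
    aie_cutpoints: tuple[float, ...] = AIE_CUTPOINTS
    causes: tuple[str, ...] = ("lung", "bladder", "mesothelioma", "pneumonitis", "copd")
    exclude_plants: tuple[int, ...] = ()
    suppression_threshold: int = 10
    output_dir: str = "occohort-output"
    n_workers: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        start, end = self.follow_up
        if start < date(1942, 1, 1) or end < start:
            raise ValueError("follow-up must lie within [1942-01-01, study end]")
        if self.suppression_threshold < 0:
            raise ValueError("suppression_threshold must be non-negative")

    @property
    def cumulative_spec(self) -> CategorySpec:
        return CategorySpec("cumulative", self.cumulative_cutpoints, self.lag)

    @property
    def aie_spec(self) -> CategorySpec:
        return CategorySpec("average_intensity", self.aie_cutpoints, self.lag)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["follow_up"] = [self.follow_up[0].isoformat(), self.follow_up[1].isoformat()]
        return d

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        text = Path(path).read_text()
        if path.endswith((".yaml", ".yml")):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "follow_up" in raw:
            raw["follow_up"] = tuple(date.fromisoformat(d) for d in raw["follow_up"])
        for key in ("cumulative_cutpoints", "aie_cutpoints", "causes", "exclude_plants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# cohort CSV round trip

def _fmt_date(d: date | None) -> str:
    return d.isoformat() if d else ""


def write_cohort_csv(cohort: list[WorkerRecord], workers_path, exposures_path) -> None:
    wrows, erows = [], []
    for w in cohort:
        wrows.append([w.worker_id, w.plant, w.race, w.sex, w.pay_type,
                      _fmt_date(w.birth_date), _fmt_date(w.hire_date),
                      _fmt_date(w.termination_date), w.ever_smoker, w.asbestos_exposed,
                      w.vital_status, _fmt_date(w.death_date), w.cause or ""])
        for start, end, intensity in w.exposure.segments:
            erows.append([w.worker_id, start.isoformat(), end.isoformat(), intensity])
    pd.DataFrame(wrows, columns=WORKER_COLUMNS).to_csv(workers_path, index=False)
    pd.DataFrame(erows, columns=EXPOSURE_COLUMNS).to_csv(exposures_path, index=False)


def read_cohort_csv(workers_path, exposures_path=None
                    ) -> tuple[list[WorkerRecord], list[str]]:
    """Parse the cohort CSVs; returns (records, parse errors with line numbers).

    Malformed rows are skipped and reported; structural validity of the
    parsed records is checked separately by :func:`validate_and_recode`.
    """
    wdf = pd.read_csv(workers_path, dtype=str, keep_default_na=False)
    segments: dict[str, list] = {}
    if exposures_path is not None and Path(exposures_path).exists():
        edf = pd.read_csv(exposures_path, dtype=str, keep_default_na=False)
        for row in edf.itertuples(index=False):
            segments.setdefault(row.worker_id, []).append(
                (date.fromisoformat(row.start_date), date.fromisoformat(row.end_date),
                 float(row.intensity_ppm)))
    records, errors = [], []
    for lineno, row in enumerate(wdf.itertuples(index=False), start=2):
        try:
            dead = row.vital_status == "dead"
            records.append(WorkerRecord(
                worker_id=row.worker_id, plant=int(row.plant), race=row.race,
                sex=row.sex, pay_type=row.pay_type,
                birth_date=date.fromisoformat(row.birth_date),
                hire_date=date.fromisoformat(row.hire_date),
                termination_date=date.fromisoformat(row.termination_date),
                exposure=ExposureHistory(tuple(sorted(segments.get(row.worker_id, [])))),
                ever_smoker=int(row.ever_smoker), asbestos_exposed=int(row.asbestos_exposed),
                vital_status=row.vital_status,
                death_date=date.fromisoformat(row.death_date) if dead and row.death_date else None,
                cause=row.cause if dead and row.cause else None))
        except (ValueError, CohortValidationError) as exc:
            errors.append(f"line {lineno}: {exc}")
    return records, errors


# ---------------------------------------------------------------------------
# validation / recode

class ValidationAbort(RuntimeError):
    """Raised when the malformed-row fraction exceeds the abort threshold."""


@dataclass
class ValidationReport:
    n_input: int = 0
    n_valid: int = 0
    n_recoded_death_date: int = 0
    rejected: list[str] = field(default_factory=list)
    parse_errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_and_recode(cohort: list[WorkerRecord], config: PipelineConfig,
                        parse_errors: list[str] | None = None
                        ) -> tuple[list[WorkerRecord], ValidationReport]:
    """Apply the end-of-follow-up recode rule and reject invalid records.

    Deaths dated after the follow-up end are recoded to the end date
    (counted and logged), mirroring the handling of deaths reported just
    past a study's closing date.  Records violating event-history
    invariants are rejected and named; more than 1% bad rows aborts.
    """
    report = ValidationReport(n_input=len(cohort) + len(parse_errors or []),
                              parse_errors=list(parse_errors or []))
    end = config.follow_up[1]
    out: list[WorkerRecord] = []
    for w in cohort:
        if w.vital_status == "dead" and w.death_date is not None and w.death_date > end:
            w = dataclasses.replace(w, death_date=end,
                                    termination_date=min(w.termination_date, end))
            report.n_recoded_death_date += 1
        try:
            w.validate()
        except CohortValidationError as exc:
            report.rejected.append(str(exc))
            continue
        out.append(w)
    report.n_valid = len(out)
    n_bad = len(report.rejected) + len(report.parse_errors)
    if report.n_input and n_bad / report.n_input > 0.01:
        raise ValidationAbort(
            f"{n_bad}/{report.n_input} malformed or invalid rows (>1%): "
            + "; ".join((report.parse_errors + report.rejected)[:5]))
    log.info("validate: %d in, %d valid, %d death dates recoded, %d rejected",
             report.n_input, report.n_valid, report.n_recoded_death_date,
             len(report.rejected))
    return out, report


def apply_plant_filter(cohort: list[WorkerRecord],
                       exclude_plants: tuple[int, ...]) -> list[WorkerRecord]:
    if not exclude_plants:
        return cohort
    out = [w for w in cohort if w.plant not in exclude_plants]
    log.info("plant filter: excluded plants %s, %d -> %d workers",
             list(exclude_plants), len(cohort), len(out))
    return out


def format_count(observed: int, threshold: int) -> str:
    """Disclosure-control formatting: counts in (0, threshold) print as 'd.s.'."""
    return "d.s." if 0 < observed < threshold else str(observed)
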