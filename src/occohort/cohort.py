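"""Worker event-history records for a multi-plant occupational cohort."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from .persontime import CohortValidationError, ExposureHistory

CAUSES = ("lung", "bladder", "mesothelioma", "pneumonitis", "copd", "other")
RACES = ("white", "nonwhite")
SEXES = ("male", "female")
PAY_TYPES = ("wage", "salary")


@dataclass
class WorkerRecord:
    """One cohort member: demographics, employment, exposure, and outcome."""

    worker_id: str
    plant: int
    race: str
    sex: str
    pay_type: str
    birth_date: date
    hire_date: date
    termination_date: date
    exposure: ExposureHistory = field(default_factory=ExposureHistory)
    ever_smoker: int = 0
    asbestos_exposed: int = 0
    vital_status: str = "alive"
    death_date: date | None = None
    cause: str | None = None

    def validate(self, study_end: date | None = None) -> None:
        """Raise :class:`CohortValidationError` on any invariant violation."""
        wid = self.worker_id
        if self.race not in RACES or self.sex not in SEXES or self.pay_type not in PAY_TYPES:
            raise CohortValidationError(f"worker {wid}: bad demographic code")
        if not (self.birth_date < self.hire_date < self.termination_date):
            raise CohortValidationError(
                f"worker {wid}: requires birth < hire < termination "
                f"({self.birth_date}, {self.hire_date}, {self.termination_date})")
        if study_end is not None and self.termination_date > study_end:
            raise CohortValidationError(f"worker {wid}: termination after study end")
        if self.vital_status == "dead":
            if self.death_date is None or self.cause is None:
                raise CohortValidationError(f"worker {wid}: dead without date/cause")
            if self.death_date < self.hire_date:
                raise CohortValidationError(
                    f"worker {wid}: death {self.death_date} precedes hire {self.hire_date}")
            if self.cause not in CAUSES:
                raise CohortValidationError(f"worker {wid}: unknown cause {self.cause!r}")
        elif self.death_date is not None or self.cause is not None:
            raise CohortValidationError(f"worker {wid}: alive with death date or cause")
        for start, end, _ in self.exposure.segments:
            if start < self.hire_date or end > self.termination_date:
                raise CohortValidationError(
                    f"worker {wid}: exposure segment outside employment")


def validate_cohort(cohort: list[WorkerRecord], study_end: date | None = None) -> None:
    for w in cohort:
        w.validate(study_end=study_end)
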