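"""Reference mortality rate tables (deaths per person-year by stratum).

The table is dense over cause x race x sex x 5-year age band x 5-year
calendar period, mirroring the layout of population rate files used for
indirect standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CAUSES, RACES, SEXES
from .persontime import AGE_STARTS, PERIOD_STARTS


class MissingRateError(KeyError):
    """A stratum with person-time has no reference rate."""


@dataclass
class ReferenceRateTable:
    """Dense rate array indexed [cause, race, sex, age band, period]."""

    label: str
    values: np.ndarray
    causes: tuple[str, ...] = CAUSES
    age_starts: tuple[int, ...] = AGE_STARTS
    period_starts: tuple[int, ...] = PERIOD_STARTS

    def __post_init__(self) -> None:
        expected = (len(self.causes), len(RACES), len(SEXES),
                    len(self.age_starts), len(self.period_starts))
        if self.values.shape != expected:
            raise ValueError(f"rate array shape {self.values.shape} != {expected}")
        if np.any(self.values < 0):
            raise ValueError("negative rates")

    @classmethod
    def zeros(cls, label: str = "zero") -> "ReferenceRateTable":
        shape = (len(CAUSES), len(RACES), len(SEXES), len(AGE_STARTS), len(PERIOD_STARTS))
        return cls(label=label, values=np.zeros(shape))

    # -- indexing -----------------------------------------------------------
    def cause_index(self, cause: str) -> int:
        try:
            return self.causes.index(cause)
        except ValueError:
            raise MissingRateError(f"cause {cause!r} not in rate table {self.label!r}")

    def _stratum_index(self, race: str, sex: str, age_start: int, period_start: int):
        try:
            return (RACES.index(race), SEXES.index(sex),
                    self.age_starts.index(age_start), self.period_starts.index(period_start))
        except ValueError:
            raise MissingRateError(
                f"stratum ({race}, {sex}, age {age_start}, period {period_start}) "
                f"missing from rate table {self.label!r}")

    def rate(self, cause: str, race: str, sex: str, age_start: int, period_start: int) -> float:
        ci = self.cause_index(cause)
        r, s, a, p = self._stratum_index(race, sex, age_start, period_start)
        return float(self.values[ci, r, s, a, p])

    def scaled(self, factor: float) -> "ReferenceRateTable":
        return ReferenceRateTable(label=f"{self.label}*{factor:g}",
                                  values=self.values * factor,
                                  causes=self.causes,
                                  age_starts=self.age_starts,
                                  period_starts=self.period_starts)

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, cause in enumerate(self.causes):
            for ri, race in enumerate(RACES):
                for si, sex in enumerate(SEXES):
                    for ai, age in enumerate(self.age_starts):
                        for pi, per in enumerate(self.period_starts):
                            rows.append((cause, race, sex, age, per,
                                         self.values[ci, ri, si, ai, pi]))
        return pd.DataFrame(rows, columns=["cause", "race", "sex", "age_start",
                                           "period_start", "rate"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, label: str = "rates") -> "ReferenceRateTable":
        df = pd.read_csv(path)
        causes = tuple(dict.fromkeys(df["cause"]))
        ages = tuple(sorted(df["age_start"].unique()))
        periods = tuple(sorted(df["period_start"].unique()))
        values = np.zeros((len(causes), len(RACES), len(SEXES), len(ages), len(periods)))
        cix = {c: i for i, c in enumerate(causes)}
        rix = {c: i for i, c in enumerate(RACES)}
        six = {c: i for i, c in enumerate(SEXES)}
        aix = {a: i for i, a in enumerate(ages)}
        pix = {p: i for i, p in enumerate(periods)}
        for row in df.itertuples(index=False):
            values[cix[row.cause], rix[row.race], six[row.sex],
                   aix[row.age_start], pix[row.period_start]] = row.rate
        return cls(label=label, values=values, causes=causes,
                   age_starts=ages, period_starts=periods)


def rates_from_person_time(pt, causes: tuple[str, ...] = CAUSES,
                           label: str = "self") -> ReferenceRateTable:
    """Derive a rate table from a cohort's own deaths and person-years.

    Rates are deaths / person-years per (race, sex, age, period) stratum,
    aggregated over exposure categories.  Using this table as the reference
    makes the all-category SMR exactly 1 for every cause with deaths.
    """
    table = ReferenceRateTable.zeros(label=label)
    py: dict[tuple, float] = {}
    for (r, s, a, p, _), t in pt.cells.items():
        py[(r, s, a, p)] = py.get((r, s, a, p), 0.0) + t
    dd: dict[tuple, int] = {}
    for (r, s, a, p, _, cause), n in pt.deaths.items():
        dd[(r, s, a, p, cause)] = dd.get((r, s, a, p, cause), 0) + n
    for (r, s, a, p, cause), n in dd.items():
        t = py.get((r, s, a, p), 0.0)
        if t > 0:
            ci = table.cause_index(cause)
            ri, si, ai, pi = table._stratum_index(r, s, a, p)
            table.values[ci, ri, si, ai, pi] = n / t
    return table
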