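"""Person-time splitting with lagged, time-dependent occupational exposure.

Follow-up for each worker is partitioned into cells indexed by the SMR
adjustment strata (race, sex, 5-year age group, 5-year calendar period) and
an exposure category (cumulative ppm-years or average intensity in ppm,
lagged to reflect disease latency).  The same exposure arithmetic is reused
to evaluate exposures at risk-set event times.

All internal time arithmetic runs on a leap-aware decimal-year scale:
``year_frac(date)`` maps a date to ``year + elapsed_days / days_in_year``.
On this scale calendar-aligned intervals have exact integer lengths, so a
full calendar year at 2 ppm contributes exactly 2.0 ppm-years and a
``lag``-year shift is an exact subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Default 10-year exposure lag (years).
DEFAULT_LAG = 10.0
#: Cumulative-exposure quintile cut points (ppm-years, lagged).
CUMULATIVE_CUTPOINTS = (0.09, 0.64, 2.30, 12.08)
#: Average-intensity cut points (ppm).
AIE_CUTPOINTS = (0.06, 0.14, 0.37, 1.46)

#: 5-year age bands 0-4 ... 85+.
AGE_STARTS = tuple(range(0, 90, 5))
#: 5-year calendar periods spanning the 1942-2011 follow-up window.
PERIOD_STARTS = tuple(range(1940, 2015, 5))


class CohortValidationError(ValueError):
    """A worker record violates the event-history invariants."""


def year_frac(d: date) -> float:
    """Convert a date to leap-aware decimal years."""
    start = date(d.year, 1, 1).toordinal()
    length = date(d.year + 1, 1, 1).toordinal() - start
    return d.year + (d.toordinal() - start) / length


def date_from_year_frac(t: float) -> date:
    """Inverse of :func:`year_frac` (to daily resolution)."""
    y = int(np.floor(t))
    start = date(y, 1, 1).toordinal()
    length = date(y + 1, 1, 1).toordinal() - start
    day = int(np.floor((t - y) * length + 1e-9))
    return date.fromordinal(start + min(day, length - 1))


@dataclass(frozen=True)
class ExposureHistory:
    """Chronologically ordered, non-overlapping exposure segments.

    Each segment is ``(start, end, intensity)`` with dates half-open
    ``[start, end)`` and intensity in ppm.
    """

    segments: tuple[tuple[date, date, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, intensity in self.segments:
            if end <= start:
                raise CohortValidationError(f"segment {start}..{end} has non-positive length")
            if intensity < 0:
                raise CohortValidationError("negative exposure intensity")
            if prev_end is not None and start < prev_end:
                raise CohortValidationError("overlapping or unordered exposure segments")
            prev_end = end

    @property
    def bounds_yf(self) -> tuple[tuple[float, float, float], ...]:
        return tuple((year_frac(a), year_frac(b), i) for a, b, i in self.segments)

    @property
    def first_exposure(self) -> date | None:
        return self.segments[0][0] if self.segments else None


@dataclass(frozen=True)
class CategorySpec:
    """Exposure categorisation rule.

    kind
        ``"cumulative"`` (ppm-years) or ``"average_intensity"`` (ppm).
    cutpoints
        Strictly increasing positive bounds.  Intervals are right-closed
        above the first bound: ``[0, c1], (c1, c2], ..., (ck, inf)``.
    lag
        Exposure lag in years (the most recent ``lag`` years are ignored).
    separate_unexposed
        When true, never-exposed time (including time before the first
        lagged exposure) forms its own baseline category 0.
    """

    kind: str = "cumulative"
    cutpoints: tuple[float, ...] = CUMULATIVE_CUTPOINTS
    lag: float = DEFAULT_LAG
    separate_unexposed: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("cumulative", "average_intensity"):
            raise ValueError(f"unknown category kind {self.kind!r}")
        cp = tuple(float(c) for c in self.cutpoints)
        if any(c <= 0 for c in cp) or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be strictly increasing and positive")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        object.__setattr__(self, "cutpoints", cp)

    @property
    def n_categories(self) -> int:
        return len(self.cutpoints) + 1 + (1 if self.separate_unexposed else 0)

    @property
    def labels(self) -> tuple[str, ...]:
        cp = self.cutpoints
        bins = [f"0-{cp[0]:g}"]
        bins += [f">{a:g}-{b:g}" for a, b in zip(cp, cp[1:])]
        bins += [f">{cp[-1]:g}"]
        if self.separate_unexposed:
            return ("unexposed", *bins)
        return tuple(bins)


def cumulative_exposure(history: ExposureHistory, at: date, lag: float = 0.0) -> float:
    """Lagged cumulative exposure (ppm-years) at ``at``.

    The time-integral of intensity up to ``at - lag`` years, clipped at
    segment boundaries.  Non-decreasing in ``at``.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    cut = year_frac(at) - lag
    total = 0.0
    for a, b, intensity in history.bounds_yf:
        total += intensity * max(0.0, min(b, cut) - a)
    return total


def average_intensity(history: ExposureHistory, at: date, lag: float = 0.0) -> float:
    """Lagged average exposure intensity (ppm) at ``at``.

    Lagged cumulative exposure divided by lagged exposed duration in years;
    0 when no exposure lies outside the lag window.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    cut = year_frac(at) - lag
    total = 0.0
    dur = 0.0
    for a, b, intensity in history.bounds_yf:
        d = max(0.0, min(b, cut) - a)
        total += intensity * d
        dur += d
    return total / dur if dur > 0 else 0.0


def classify(value: float, spec: CategorySpec, ever_exposed: bool = True) -> int:
    """Map an exposure value to its category index.

    With ``separate_unexposed`` the index 0 is the unexposed baseline and
    exposed bins are 1..K+1; otherwise bins are 0..K.  Bins are right-closed
    at each cutpoint (a value exactly at a cutpoint falls in the lower bin).
    """
    if value < 0:
        raise ValueError("exposure value must be non-negative")
    if spec.separate_unexposed and (not ever_exposed or value <= 0.0):
        return 0
    base = 1 if spec.separate_unexposed else 0
    return base + int(np.searchsorted(spec.cutpoints, value, side="left"))


def category_at(history: ExposureHistory, at: date, spec: CategorySpec) -> int:
    """Category of a worker at a calendar date under ``spec`` (lag applied)."""
    if spec.kind == "cumulative":
        value = cumulative_exposure(history, at, spec.lag)
    else:
        value = average_intensity(history, at, spec.lag)
    ever = cumulative_exposure(history, at, spec.lag) > 0.0
    return classify(value, spec, ever_exposed=ever)


def cumulative_transition_times(history: ExposureHistory, spec: CategorySpec) -> list[float]:
    """Decimal-year times at which the lagged cumulative category changes.

    The running lagged cumulative exposure is piecewise linear and
    non-decreasing, so each cutpoint is crossed at most once; the entry into
    the first exposed bin happens ``lag`` years after first exposure.
    """
    if not history.segments:
        return []
    bounds = history.bounds_yf
    times: list[float] = []
    # entry into the first exposed bin (lagged value becomes positive)
    for a, _, intensity in bounds:
        if intensity > 0:
            times.append(a + spec.lag)
            break
    cum = 0.0
    targets = list(spec.cutpoints)
    ti = 0
    for a, b, intensity in bounds:
        seg_gain = intensity * (b - a)
        while ti < len(targets) and intensity > 0 and cum + seg_gain > targets[ti]:
            # crossing inside this segment (shifted by the lag)
            t = a + (targets[ti] - cum) / intensity + spec.lag
            times.append(t)
            ti += 1
        cum += seg_gain
    return sorted(set(times))


def _age_index(age: float) -> int:
    return min(max(int(age // 5), 0), len(AGE_STARTS) - 1)


def _period_index(year: float) -> int:
    idx = (int(year) - PERIOD_STARTS[0]) // 5
    return min(max(idx, 0), len(PERIOD_STARTS) - 1)


@dataclass
class PersonTimeTable:
    """Person-years and deaths cross-classified by stratum and category.

    ``cells`` maps ``(race, sex, age_start, period_start, category)`` to
    person-years; ``deaths`` maps ``(race, sex, age_start, period_start,
    category, cause)`` to counts.
    """

    spec: CategorySpec
    follow_up: tuple[date, date]
    cells: dict[tuple, float] = field(default_factory=dict)
    deaths: dict[tuple, int] = field(default_factory=dict)

    def add_time(self, key: tuple, years: float) -> None:
        self.cells[key] = self.cells.get(key, 0.0) + years

    def add_death(self, key: tuple, cause: str) -> None:
        k = (*key, cause)
        self.deaths[k] = self.deaths.get(k, 0) + 1

    def total_person_years(self) -> float:
        return float(sum(self.cells.values()))

    def person_years_by_category(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for (_, _, _, _, cat), py in self.cells.items():
            out[cat] = out.get(cat, 0.0) + py
        return out

    def observed(self, cause: str) -> dict[int, int]:
        """Observed deaths from ``cause`` per exposure category."""
        out: dict[int, int] = {}
        for (r, s, a, p, cat, c), n in self.deaths.items():
            if c == cause:
                out[cat] = out.get(cat, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (r, s, a, p, cat), py in sorted(self.cells.items()):
            rows.append({"race": r, "sex": s, "age_start": a, "period_start": p,
                         "category": cat, "person_years": py})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def tabulate(cohort: Iterable, spec: CategorySpec,
             follow_up: tuple[date, date] = (date(1942, 1, 1), date(2011, 12, 31))) -> PersonTimeTable:
    """Split each worker's follow-up into stratum x category person-time.

    Intervals are half-open on the decimal-year scale and split at every
    age-band boundary, calendar-period boundary, and exposure-category
    transition; deaths are assigned to the cell active at the death date.
    For average-intensity specs (whose running value is not monotone) the
    category is additionally re-evaluated on a yearly grid.
    """
    fu_start, fu_end = follow_up
    if fu_end < fu_start:
        raise ValueError("follow-up end precedes start")
    fu0, fu1 = year_frac(fu_start), year_frac(fu_end)
    table = PersonTimeTable(spec=spec, follow_up=follow_up)

    for w in cohort:
        birth = year_frac(w.birth_date)
        hire = year_frac(w.hire_date)
        if w.death_date is not None and year_frac(w.death_date) < hire:
            raise CohortValidationError(
                f"worker {w.worker_id}: death {w.death_date} precedes hire {w.hire_date}")
        entry = max(hire, fu0)
        dead_in_window = (w.vital_status == "dead" and w.death_date is not None
                          and year_frac(w.death_date) <= fu1)
        exit_ = year_frac(w.death_date) if dead_in_window else fu1
        if exit_ < entry:
            continue

        cuts = {entry, exit_}
        # age-band boundaries
        k0 = int(np.ceil((entry - birth) / 5))
        k1 = int(np.floor((exit_ - birth) / 5))
        for k in range(k0, k1 + 1):
            cuts.add(birth + 5 * k)
        # calendar-period boundaries
        y0 = int(np.ceil(entry / 5)) * 5
        for y in range(y0, int(exit_) + 1, 5):
            cuts.add(float(y))
        # exposure-category transitions
        if spec.kind == "cumulative":
            for t in cumulative_transition_times(w.exposure, spec):
                if entry < t < exit_:
                    cuts.add(t)
        else:
            for y in range(int(entry) + 1, int(exit_) + 1):
                cuts.add(float(y))
            for a, b, _ in w.exposure.bounds_yf:
                for t in (a + spec.lag, b + spec.lag):
                    if entry < t < exit_:
                        cuts.add(t)

        grid = sorted(t for t in cuts if entry <= t <= exit_)
        for u, v in zip(grid, grid[1:]):
            if v <= u:
                continue
            m = 0.5 * (u + v)
            key = (w.race, w.sex, AGE_STARTS[_age_index(m - birth)],
                   PERIOD_STARTS[_period_index(m)],
                   category_at(w.exposure, date_from_year_frac(m), spec))
            table.add_time(key, v - u)
        if dead_in_window:
            d = w.death_date
            key = (w.race, w.sex, AGE_STARTS[_age_index(year_frac(d) - birth)],
                   PERIOD_STARTS[_period_index(year_frac(d))],
                   category_at(w.exposure, d, spec))
            table.add_death(key, w.cause)
    return table
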