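"""Standardized mortality ratios with exact Poisson limits and trend tests.

Expected deaths come from indirect standardization: stratum-specific
reference rates applied to the cohort's person-years.  Confidence limits
use the exact Poisson (gamma-quantile) formulation, which is the standard
for small observed counts and reproduces published two-decimal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .persontime import PersonTimeTable
from .rates import MissingRateError, ReferenceRateTable

#: disclosure-control threshold: counts below this are suppressed at report time
SUPPRESSION_THRESHOLD = 10


@dataclass
class SmrResult:
    observed: int
    expected: float
    cause: str = ""
    category: int | None = None
    level: float = 0.95
    suppressed: bool = False

    @property
    def smr(self) -> float:
        return self.observed / self.expected

    @property
    def ci_low(self) -> float:
        if self.observed == 0:
            return 0.0
        return stats.gamma.ppf((1 - self.level) / 2, self.observed) / self.expected

    @property
    def ci_high(self) -> float:
        return stats.gamma.ppf(1 - (1 - self.level) / 2, self.observed + 1) / self.expected


def expected_deaths(pt: PersonTimeTable, rates: ReferenceRateTable, cause: str) -> dict[int, float]:
    """Expected deaths per exposure category: sum of person-years x rate.

    Raises :class:`MissingRateError` naming the first stratum with
    person-time but no reference rate.
    """
    out: dict[int, float] = {}
    for (race, sex, age, period, cat), py in pt.cells.items():
        r = rates.rate(cause, race, sex, age, period)
        out[cat] = out.get(cat, 0.0) + py * r
    return out


def smr_with_ci(observed: int, expected: float, level: float = 0.95,
                cause: str = "", category: int | None = None,
                suppression_threshold: int = SUPPRESSION_THRESHOLD) -> SmrResult:
    """SMR = O/E with exact Poisson (gamma-quantile) confidence limits."""
    if expected <= 0:
        raise ValueError("expected deaths must be positive")
    if observed < 0:
        raise ValueError("observed deaths must be non-negative")
    return SmrResult(observed=int(observed), expected=float(expected), cause=cause,
                     category=category, level=level,
                     suppressed=observed < suppression_threshold)


def smr_ratio(smr_a: SmrResult, smr_b: SmrResult) -> float:
    """Ratio of two SMRs (e.g. top-category SMR over baseline SMR)."""
    if smr_b.smr <= 0:
        raise ZeroDivisionError("denominator SMR is zero")
    return smr_a.smr / smr_b.smr


def smr_trend_test(results: list[SmrResult], scores: list[float] | None = None) -> float:
    """Two-sided Wald p-value for a log-linear trend in SMRs across categories.

    Fits the Poisson model O_k ~ offset(log E_k) + score_k; scores default
    to category ranks 1..K in the given order.
    """
    usable = [r for r in results if r.expected > 0]
    if len(usable) < 3:
        raise ValueError("trend test needs at least 3 categories with expected deaths")
    if scores is None:
        scores = list(range(1, len(usable) + 1))
    elif len(scores) != len(usable):
        raise ValueError("scores length does not match usable categories")
    obs = np.array([r.observed for r in usable], dtype=float)
    off = np.log([r.expected for r in usable])
    X = sm.add_constant(np.asarray(scores, dtype=float))
    fit = sm.GLM(obs, X, family=sm.families.Poisson(), offset=off).fit()
    z = fit.params[1] / fit.bse[1]
    return float(2 * stats.norm.sf(abs(z)))


def smr_by_category(pt: PersonTimeTable, rates: ReferenceRateTable, cause: str,
                    level: float = 0.95) -> dict[int, SmrResult]:
    exp = expected_deaths(pt, rates, cause)
    obs = pt.observed(cause)
    out: dict[int, SmrResult] = {}
    for cat in sorted(exp):
        if exp[cat] > 0:
            out[cat] = smr_with_ci(obs.get(cat, 0), exp[cat], level=level,
                                   cause=cause, category=cat)
    return out


def smr_report(pt: PersonTimeTable, rates: ReferenceRateTable, causes: list[str],
               suppression_threshold: int = SUPPRESSION_THRESHOLD) -> pd.DataFrame:
    """Table-style SMR report with 'd.s.' markers for suppressed cells."""
    labels = pt.spec.labels
    rows = []
    for cause in causes:
        per_cat = smr_by_category(pt, rates, cause)
        total_o = sum(r.observed for r in per_cat.values())
        total_e = sum(r.expected for r in per_cat.values())
        entries = list(per_cat.items()) + [("all", smr_with_ci(total_o, total_e, cause=cause))] \
            if total_e > 0 else list(per_cat.items())
        for cat, r in entries:
            suppress = 0 < r.observed < suppression_threshold
            rows.append({
                "cause": cause,
                "category": "all" if cat == "all" else labels[cat],
                "observed": "d.s." if suppress else r.observed,
                "expected": "d.s." if suppress else round(r.expected, 2),
                "smr": "d.s." if suppress else round(r.smr, 2),
                "ci_low": "d.s." if suppress else round(r.ci_low, 2),
                "ci_high": "d.s." if suppress else round(r.ci_high, 2),
            })
    return pd.DataFrame(rows)
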