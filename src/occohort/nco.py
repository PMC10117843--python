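"""Negative-control-outcome (NCO) indirect confounding adjustment.

An NCO is an outcome caused by the unmeasured confounder (smoking -> COPD,
asbestos -> mesothelioma) but, by assumption, not by the occupational
exposure under study.  Under the negative-control condition and the
equi-confounding assumption (the confounder biases the NCO and the outcome
of interest by the same multiplicative factor), subtracting the NCO's log
rate ratio from the outcome's removes the confounding:

    beta_adj = beta_outcome - sum_i beta_nco_i
    var_adj  = var_outcome + sum_i var_nco_i

Variances are summed treating the estimates as independent, which widens
the interval; the resulting limits are conservative.  The same coefficient
subtraction applies term-wise to log-linear-quadratic dose-response models,
where it is identical to dividing the RR curves pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rrmodels import DoseResponseModel, RateRatioEstimate, _Z


def from_rr_ci(rr: float, ci_low: float, ci_high: float, term: str = "") -> RateRatioEstimate:
    """Build an estimate from a published RR and 95% CI.

    The variance is back-solved from the CI half-width on the log scale.
    """
    if not (0 < ci_low <= rr <= ci_high):
        raise ValueError("need 0 < ci_low <= rr <= ci_high")
    se = (np.log(ci_high) - np.log(ci_low)) / (2 * _Z)
    return RateRatioEstimate(term=term, beta=float(np.log(rr)), variance=float(se ** 2))


@dataclass
class NcoAdjustment:
    outcome: RateRatioEstimate
    ncos: list[RateRatioEstimate]
    beta_adj: float
    variance_adj: float

    @property
    def rr_adj(self) -> float:
        return float(np.exp(self.beta_adj))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta_adj - _Z * np.sqrt(self.variance_adj)))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta_adj + _Z * np.sqrt(self.variance_adj)))


def _check_terms(outcome: RateRatioEstimate, ncos: list[RateRatioEstimate]) -> None:
    for nco in ncos:
        if outcome.term and nco.term and outcome.term != nco.term:
            raise ValueError(
                f"category mismatch: outcome {outcome.term!r} vs NCO {nco.term!r}")


def adjust(outcome: RateRatioEstimate, nco: RateRatioEstimate) -> NcoAdjustment:
    """Single-NCO adjustment: rr_adj = rr_outcome / rr_nco exactly."""
    _check_terms(outcome, [nco])
    return NcoAdjustment(outcome=outcome, ncos=[nco],
                         beta_adj=outcome.beta - nco.beta,
                         variance_adj=outcome.variance + nco.variance)


def adjust_double(outcome: RateRatioEstimate, nco_smoking: RateRatioEstimate,
                  nco_asbestos: RateRatioEstimate) -> NcoAdjustment:
    """Dual-NCO adjustment (e.g. smoking via COPD plus asbestos via mesothelioma)."""
    ncos = [nco_smoking, nco_asbestos]
    _check_terms(outcome, ncos)
    return NcoAdjustment(outcome=outcome, ncos=ncos,
                         beta_adj=outcome.beta - nco_smoking.beta - nco_asbestos.beta,
                         variance_adj=outcome.variance + nco_smoking.variance
                         + nco_asbestos.variance)


def adjust_continuous(outcome: DoseResponseModel, nco: DoseResponseModel) -> DoseResponseModel:
    """Coefficient-wise adjustment of a dose-response model.

    The adjusted curve equals RR_outcome(x) / RR_nco(x) at every x.
    """
    if outcome.scale != nco.scale:
        raise ValueError(f"exposure scale mismatch: {outcome.scale!r} vs {nco.scale!r}")
    return DoseResponseModel(
        beta1=outcome.beta1 - nco.beta1,
        beta2=outcome.beta2 - nco.beta2,
        covariance=np.asarray(outcome.covariance) + np.asarray(nco.covariance),
        scale=outcome.scale,
        identifiable=outcome.identifiable and nco.identifiable,
    )
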