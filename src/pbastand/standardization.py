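"""Model-based standardization (g-formula) for case-control data.

A logistic model fitted to case-control data has an intercept on the
sampling scale; with known sampling fractions for cases and controls the
population-scale intercept is recovered by subtracting
ln(sf_case / sf_control).  Standardized risks under "everyone exposed" and
"everyone unexposed" are then averages of corrected predicted risks over
the sample, weighted by inverse sampling fractions so the sample stands in
for the study base.  The marginal risk ratio and risk difference follow by
dividing and subtracting the two standardized risks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .outcome_model import FittedModel, build_design

__all__ = [
    "SamplingFractions",
    "StandardizedRisks",
    "intercept_offset",
    "standardized_risks",
]


@dataclass(frozen=True)
class SamplingFractions:
    """Fraction of the study base's cases / eligible non-cases in the sample."""

    sf_case: float
    sf_control: float

    def __post_init__(self) -> None:
        for v in (self.sf_case, self.sf_control):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"sampling fractions must be in (0, 1], got {v}")

    @classmethod
    def from_counts(cls, n_case: int, n_case_base: int,
                    n_control: int, n_control_base: int) -> "SamplingFractions":
        return cls(n_case / n_case_base, n_control / n_control_base)


@dataclass(frozen=True)
class StandardizedRisks:
    risk_exposed: float
    risk_unexposed: float

    @property
    def rr(self) -> float:
        return self.risk_exposed / self.risk_unexposed

    @property
    def rd(self) -> float:
        return self.risk_exposed - self.risk_unexposed


def intercept_offset(sf: SamplingFractions) -> float:
    """ln(sf_case / sf_control), subtracted from the apparent intercept."""
    return float(np.log(sf.sf_case / sf.sf_control))


def _normalized_weights(is_case: np.ndarray, sf: SamplingFractions) -> np.ndarray:
    w = np.where(is_case, 1.0 / sf.sf_case, 1.0 / sf.sf_control)
    return w / w.sum()


def _risks_from_design(params: np.ndarray, X: np.ndarray, exposure_idx: int,
                       weights: np.ndarray, offset: float) -> StandardizedRisks:
    """Standardized risks from a prebuilt design matrix (fast path for the MC loop)."""
    eta = X @ params - X[:, exposure_idx] * params[exposure_idx] - offset
    beta_exp = params[exposure_idx]
    risk1 = float(weights @ expit(eta + beta_exp))
    risk0 = float(weights @ expit(eta))
    if risk0 == 0.0:
        raise ZeroDivisionError("standardized risk in the unexposed is zero; RR undefined")
    return StandardizedRisks(risk_exposed=risk1, risk_unexposed=risk0)


def standardized_risks(
    model: FittedModel, data: pd.DataFrame, sf: SamplingFractions
) -> StandardizedRisks:
    """Standardized risks, RR and RD under the fitted model and sampling fractions.

    Each record's outcome probability is predicted with exposure forced to 1
    and to 0 at its observed confounders, using the intercept corrected by
    :func:`intercept_offset`; risks are inverse-sampling-fraction weighted
    means (weights normalized to sum to one, so their scale is irrelevant).
    """
    if not model.converged:
        raise ValueError("standardization requires a converged outcome model")
    X, _ = build_design(data, model.spec)
    is_case = data["outcome"].to_numpy() == 1
    return _risks_from_design(
        model.params, X, model.exposure_index,
        _normalized_weights(is_case, sf), intercept_offset(sf),
    )
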