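"""Record-level correction of exposure misclassification.

Given a sensitivity/specificity draw, the reported exposed/unexposed counts
in a group determine the expected *true* counts by inverting the 2x2
classification matrix.  Predictive values follow from the corrected counts,
and each record's exposure is then re-imputed by comparing a uniform draw
with the PPV (reported exposed) or NPV (reported unexposed) of its group.
Because exposure prevalence differs between cases and controls, the
correction and predictive values are computed separately within each group,
from the same non-differential (Se, Sp) draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias_priors import SensSpec

__all__ = [
    "GroupCounts",
    "CorrectedCounts",
    "PredictiveValues",
    "correct_counts",
    "predictive_values",
    "impute_exposure",
]


@dataclass(frozen=True)
class GroupCounts:
    """Reported exposed / unexposed counts within one group (cases or controls)."""

    n_reported_exposed: int
    n_reported_unexposed: int

    def __post_init__(self) -> None:
        if self.n_reported_exposed < 0 or self.n_reported_unexposed < 0:
            raise ValueError("counts must be non-negative")
        if self.n_reported_exposed + self.n_reported_unexposed == 0:
            raise ValueError("group is empty")

    @classmethod
    def from_records(cls, exposure: np.ndarray) -> "GroupCounts":
        exposure = np.asarray(exposure)
        return cls(int(np.sum(exposure == 1)), int(np.sum(exposure == 0)))


@dataclass(frozen=True)
class CorrectedCounts:
    """Expected true exposed (A) and unexposed (B) counts; ``valid`` iff both positive."""

    A: float
    B: float
    valid: bool


@dataclass(frozen=True)
class PredictiveValues:
    ppv: float
    npv: float


def correct_counts(counts: GroupCounts, ss: SensSpec) -> CorrectedCounts:
    """Invert the misclassification matrix to expected true counts.

    With a* reported exposed out of N = a* + b*:

        A = (a* - (1 - Sp) * N) / (Se + Sp - 1),   B = N - A

    so that Se*A + (1-Sp)*B = a* holds exactly.  Draws with A <= 0 or B <= 0
    are flagged invalid (the Monte Carlo loop redraws them); Se + Sp <= 1 is
    non-identifiable and raises.
    """
    se, sp = ss.sensitivity, ss.specificity
    if se + sp <= 1.0:
        raise ValueError(f"Se + Sp must exceed 1 for identifiability, got {se} + {sp}")
    a_star = counts.n_reported_exposed
    n = a_star + counts.n_reported_unexposed
    a = (a_star - (1.0 - sp) * n) / (se + sp - 1.0)
    b = n - a
    return CorrectedCounts(A=a, B=b, valid=bool(a > 0 and b > 0))


def predictive_values(cc: CorrectedCounts, ss: SensSpec) -> PredictiveValues:
    """PPV and NPV implied by corrected counts and the (Se, Sp) that produced them."""
    if not cc.valid:
        raise ValueError("predictive values require valid (positive) corrected counts")
    se, sp = ss.sensitivity, ss.specificity
    ppv = se * cc.A / (se * cc.A + (1.0 - sp) * cc.B)
    npv = sp * cc.B / (sp * cc.B + (1.0 - se) * cc.A)
    return PredictiveValues(ppv=float(ppv), npv=float(npv))


def impute_exposure(
    records: pd.DataFrame,
    pv_cases: PredictiveValues,
    pv_controls: PredictiveValues,
    rng: np.random.Generator,
    *,
    outcome_col: str = "outcome",
    exposure_col: str = "exposure",
) -> pd.DataFrame:
    """Re-impute each record's exposure from its group's predictive values.

    Per record, draw U ~ Uniform(0,1).  A reported-exposed record keeps
    exposure 1 unless U > PPV of its group; a reported-unexposed record keeps
    0 unless U > NPV.  Returns a copy of ``records`` with an
    ``exposure_imputed`` column.
    """
    if records[exposure_col].isna().any():
        raise ValueError("missing exposure values cannot be imputed")
    reported = records[exposure_col].to_numpy()
    is_case = records[outcome_col].to_numpy() == 1
    imputed = impute_exposure_array(reported, is_case, pv_cases, pv_controls, rng)
    out = records.copy()
    out["exposure_imputed"] = imputed
    return out


def impute_exposure_array(
    reported: np.ndarray,
    is_case: np.ndarray,
    pv_cases: PredictiveValues,
    pv_controls: PredictiveValues,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised core of :func:`impute_exposure` on plain arrays."""
    u = rng.uniform(size=reported.shape[0])
    ppv = np.where(is_case, pv_cases.ppv, pv_controls.ppv)
    npv = np.where(is_case, pv_cases.npv, pv_controls.npv)
    exposed = reported == 1
    imputed = np.where(exposed, (u <= ppv).astype(np.int64), (u > npv).astype(np.int64))
    return imputed
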