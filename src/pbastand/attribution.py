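"""Population attributable fraction (PAF).

PAF = (Pr[Y=1] - Pr[Y^{a=0}=1]) / Pr[Y=1]: the fraction of observed cases
that would not have occurred had no one been exposed.  The observed risk is
taken from the reconstructed study base (case and control counts inflated
by their inverse sampling fractions); the counterfactual risk is the
standardized risk in the unexposed from the g-formula step.  For the
bias-adjusted PAF the identity is evaluated once per Monte Carlo draw and
the draws are summarised by percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .standardization import SamplingFractions

__all__ = ["PAFResult", "observed_risk", "paf"]


@dataclass(frozen=True)
class PAFResult:
    paf: float
    observed_risk: float
    risk_no_exposure: float


def observed_risk(n_case: int, n_control: int, sf: SamplingFractions) -> float:
    """Outcome prevalence in the study base reconstructed by inverse weighting.

    (n_case/sf_case) / (n_case/sf_case + n_control/sf_control): each sampled
    case stands for 1/sf_case base cases, each control for 1/sf_control
    base non-cases.
    """
    cases_base = n_case / sf.sf_case
    controls_base = n_control / sf.sf_control
    total = cases_base + controls_base
    if total == 0:
        raise ZeroDivisionError("empty study base")
    return float(cases_base / total)


def paf(observed: float, risk_no_exposure: float) -> PAFResult:
    """PAF from an observed risk and the counterfactual risk under no exposure.

    Negative values (protective exposure) are permitted; PAF never
    exceeds 1.
    """
    if observed <= 0:
        raise ValueError("observed risk must be positive")
    return PAFResult(
        paf=float((observed - risk_no_exposure) / observed),
        observed_risk=float(observed),
        risk_no_exposure=float(risk_no_exposure),
    )
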