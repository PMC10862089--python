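"""Multivariable logistic outcome model with fractional-polynomial age terms.

The outcome model regresses case/control status on exposure and the
confounder set.  Age may enter through fractional-polynomial (FP) terms
x^p with powers from {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (0 meaning log x, a
repeated power p meaning {x^p, x^p log x}); the Royston-Altman closed test
selects between the best FP2, the best FP1, a linear term, and no age term
via deviance differences.  Age is divided by 10 before transformation to
keep the powers numerically stable.

FP selection is intended to run once on the observed data; the selected
powers are then held fixed across Monte Carlo iterations so that
model-selection noise does not leak into the bias distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "FP_POWERS",
    "ModelSpec",
    "FittedModel",
    "build_design",
    "fp_terms",
    "select_fp_powers",
    "fit_outcome_model",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

DEFAULT_CONFOUNDERS = (
    "female",
    "married",
    "education",
    "smoking",
    "passive_smoking",
    "life_events",
    "vitamin_d",
)


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the outcome model.

    ``age_powers`` lists 0-2 FP powers for age (empty: age omitted); the
    other confounders enter linearly.  ``age_scale`` divides age before the
    power transform.
    """

    exposure_term: str = "exposure"
    confounder_terms: tuple[str, ...] = DEFAULT_CONFOUNDERS
    age_powers: tuple[float, ...] = (1.0,)
    age_term: str = "age"
    age_scale: float = 10.0

    def __post_init__(self) -> None:
        if len(self.age_powers) > 2:
            raise ValueError("at most two fractional-polynomial powers")
        for p in self.age_powers:
            if p not in FP_POWERS:
                raise ValueError(f"power {p} not in the FP power set {FP_POWERS}")


@dataclass(frozen=True)
class FittedModel:
    """A fitted logistic outcome model.

    ``intercept`` is the apparent intercept on the case-control sampling
    scale; correcting it to the population scale is the standardization
    step's job.
    """

    params: np.ndarray
    names: tuple[str, ...]
    converged: bool
    deviance: float
    spec: ModelSpec
    bse: np.ndarray | None = None

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names[1:], self.params[1:])}

    @property
    def exposure_index(self) -> int:
        return self.names.index(self.spec.exposure_term)

    def predict_proba(self, X: np.ndarray, intercept_shift: float = 0.0) -> np.ndarray:
        """Predicted outcome probabilities, optionally shifting the intercept."""
        eta = X @ self.params + intercept_shift
        return expit(eta)


def fp_terms(age: np.ndarray, powers, scale: float = 10.0) -> list[np.ndarray]:
    """Fractional-polynomial columns for age, with repeated-power log convention."""
    x = np.asarray(age, dtype=float) / scale
    if np.any(x <= 0):
        raise ValueError("age must be positive after scaling")
    cols: list[np.ndarray] = []
    seen: list[float] = []
    for p in powers:
        base = np.log(x) if p == 0.0 else x**p
        if p in seen:  # repeated power: x^p * log x
            base = base * np.log(x)
        cols.append(base)
        seen.append(p)
    return cols


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix [const, exposure, age FP terms, confounders] and column names."""
    n = len(data)
    cols = [np.ones(n), data[spec.exposure_term].to_numpy(dtype=float)]
    names = ["const", spec.exposure_term]
    if spec.age_powers:
        age_cols = fp_terms(data[spec.age_term].to_numpy(), spec.age_powers, spec.age_scale)
        for p, c in zip(spec.age_powers, age_cols):
            cols.append(c)
            names.append(f"{spec.age_term}^{p:g}" if p != 0 else f"log({spec.age_term})")
        if len(spec.age_powers) == 2 and spec.age_powers[0] == spec.age_powers[1]:
            names[-1] += "*log"
    for term in spec.confounder_terms:
        cols.append(data[term].to_numpy(dtype=float))
        names.append(term)
    return np.column_stack(cols), tuple(names)


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, bool, float, np.ndarray | None]:
    """ML logistic fit; returns (params, converged, deviance, bse).

    Complete separation and failed Newton iterations are reported through the
    ``converged`` flag rather than an exception, so the Monte Carlo loop can
    redraw the iteration.
    """
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {X.shape[1]})")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return np.full(X.shape[1], np.nan), False, np.nan, None
    params = np.asarray(res.params)
    ok = bool(res.mle_retvals.get("converged", False)) and np.all(np.isfinite(params))
    # huge coefficients signal quasi-separation that Newton "converged" through
    if ok and np.max(np.abs(params)) > 50:
        ok = False
    return params, ok, float(-2.0 * res.llf), np.asarray(res.bse) if ok else None


def fit_outcome_model(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit the logistic outcome model defined by ``spec`` on ``data``.

    ``data`` must contain an ``outcome`` column plus every term in the spec,
    with no missing values in any used column.
    """
    used = ["outcome", spec.exposure_term, *spec.confounder_terms]
    if spec.age_powers:
        used.append(spec.age_term)
    if data[used].isna().any().any():
        raise ValueError("missing values in model columns")
    X, names = build_design(data, spec)
    y = data["outcome"].to_numpy(dtype=float)
    params, converged, deviance, bse = _fit_logit(y, X)
    return FittedModel(params=params, names=names, converged=converged,
                       deviance=deviance, spec=spec, bse=bse)


def _fp1_powers():
    return [(p,) for p in FP_POWERS]


def _fp2_powers():
    out = []
    for i, p in enumerate(FP_POWERS):
        for q in FP_POWERS[i:]:
            out.append((p, q))
    return out


def select_fp_powers(
    data: pd.DataFrame, spec: ModelSpec | None = None, alpha: float = 0.05
) -> tuple[float, ...]:
    """Royston-Altman closed test for the age transformation.

    Compares, at level ``alpha`` via chi-square deviance differences:
    best FP2 vs no age term (4 df), best FP2 vs linear (3 df), best FP2 vs
    best FP1 (2 df).  Returns the selected powers: ``()`` if age adds
    nothing, ``(1,)`` when linearity is not rejected, else the best FP1 or
    FP2 powers.
    """
    spec = spec or ModelSpec()
    age = data[spec.age_term].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant; no transformation can be selected")

    y = data["outcome"].to_numpy(dtype=float)

    def deviance(powers) -> float:
        X, _ = build_design(data, ModelSpec(
            exposure_term=spec.exposure_term,
            confounder_terms=spec.confounder_terms,
            age_powers=powers,
            age_term=spec.age_term,
            age_scale=spec.age_scale,
        ))
        _, ok, dev, _ = _fit_logit(y, X)
        return dev if ok else np.inf

    dev_null = deviance(())
    dev_lin = deviance((1.0,))
    fp1 = {pw: deviance(pw) for pw in _fp1_powers()}
    best_fp1 = min(fp1, key=fp1.get)
    fp2 = {pw: deviance(pw) for pw in _fp2_powers()}
    best_fp2 = min(fp2, key=fp2.get)
    dev_fp2 = fp2[best_fp2]

    def significant(dev_bigger: float, df: int) -> bool:
        return stats.chi2.sf(dev_bigger - dev_fp2, df) < alpha

    if not significant(dev_null, 4):
        return ()
    if not significant(dev_lin, 3):
        return (1.0,)
    if not significant(fp1[best_fp1], 2):
        return best_fp1
    return best_fp2
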