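"""Monte Carlo bias analysis nested in a stratified bootstrap.

One Monte Carlo iteration draws (Se, Sp) from the priors, corrects the
reported exposure counts within cases and controls, derives group-specific
PPV/NPV, re-imputes every record's exposure, refits the outcome model and
standardizes — yielding one bias-corrected RR/RD draw.  Draws whose
corrected counts are non-positive, or whose model fit fails, are discarded
and redrawn.  Random error is addressed by repeating the whole loop on
stratified bootstrap resamples (cases and controls resampled independently
with their original sizes); the pooled n_boot x n_iter draws are summarised
by their median and 2.5/97.5 percentiles (the Monte Carlo sensitivity
analysis interval).

Reproducibility: one master generator (or seed) spawns an independent
substream per bootstrap replicate, so results are bit-for-bit reproducible
for a given seed regardless of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from joblib import Parallel, delayed
from scipy.special import expit

from .attribution import observed_risk as _observed_risk
from .attribution import paf as _paf
from .bias_priors import BiasPrior, sample_sens_spec
from .misclassification import (
    GroupCounts,
    correct_counts,
    impute_exposure_array,
    predictive_values,
)
from .outcome_model import ModelSpec, _fit_logit, build_design
from .standardization import (
    SamplingFractions,
    _normalized_weights,
    _risks_from_design,
    intercept_offset,
)

__all__ = [
    "DrawRecord",
    "EffectSummary",
    "ConventionalResult",
    "run_pbam",
    "bootstrap_pbam",
    "summarize_draws",
    "summarize_per_bootstrap",
    "draws_to_frame",
    "conventional_analysis",
]

logger = logging.getLogger("pbastand")

MAX_REDRAWS = 10_000


@dataclass(frozen=True)
class DrawRecord:
    """One bias-corrected draw of the marginal effects."""

    rr: float
    rd: float
    risk_exposed: float
    risk_unexposed: float
    observed_risk: float
    observed_risk_model: float
    paf: float
    paf_model: float
    sensitivity: float
    specificity: float
    iteration: int
    bootstrap_index: int


@dataclass(frozen=True)
class EffectSummary:
    """Median and 95% simulation limits of one effect measure over draws."""

    point: float
    lower: float
    upper: float
    n_draws: int
    n_discarded: int = 0

    def __str__(self) -> str:  # e.g. "2.02 (1.15 to 4.69)"
        return f"{self.point:.2f} ({self.lower:.2f} to {self.upper:.2f})"


@dataclass(frozen=True)
class ConventionalResult:
    """Conventional (no misclassification correction) analysis results."""

    odds_ratio: float
    or_lower: float
    or_upper: float
    rr: float
    rd: float
    paf: float
    rr_ci: tuple[float, float]
    rd_ci: tuple[float, float]
    paf_ci: tuple[float, float]
    n_boot: int


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def run_pbam(
    data: pd.DataFrame,
    sens_prior: BiasPrior,
    spec_prior: BiasPrior,
    sf: SamplingFractions,
    model_spec: ModelSpec,
    n_iter: int,
    rng,
    *,
    max_redraws: int = MAX_REDRAWS,
    bootstrap_index: int = 0,
    counters: dict | None = None,
) -> list[DrawRecord]:
    """Run ``n_iter`` Monte Carlo bias-correction iterations on one dataset.

    Each returned :class:`DrawRecord` is a valid draw; invalid attempts
    (non-identifiable or non-positive corrected counts, non-converged fits)
    are discarded and redrawn, with a hard cap of ``max_redraws`` attempts
    per iteration.  Discards are logged and, when a ``counters`` dict is
    supplied, accumulated under ``"n_discarded"``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = _as_rng(rng)

    y = data["outcome"].to_numpy(dtype=float)
    is_case = y == 1
    reported = data[model_spec.exposure_term].to_numpy()
    X, names = build_design(data, model_spec)
    exp_idx = names.index(model_spec.exposure_term)
    weights = _normalized_weights(is_case, sf)
    offset = intercept_offset(sf)
    obs_risk = _observed_risk(int(is_case.sum()), int((~is_case).sum()), sf)
    counts_case = GroupCounts.from_records(reported[is_case])
    counts_ctrl = GroupCounts.from_records(reported[~is_case])

    draws: list[DrawRecord] = []
    discarded = 0
    for it in range(n_iter):
        for _attempt in range(max_redraws):
            ss = sample_sens_spec(sens_prior, spec_prior, rng)
            if ss.sensitivity + ss.specificity <= 1.0:
                discarded += 1
                continue
            cc_case = correct_counts(counts_case, ss)
            cc_ctrl = correct_counts(counts_ctrl, ss)
            if not (cc_case.valid and cc_ctrl.valid):
                discarded += 1
                continue
            pv_case = predictive_values(cc_case, ss)
            pv_ctrl = predictive_values(cc_ctrl, ss)
            X[:, exp_idx] = impute_exposure_array(reported, is_case, pv_case, pv_ctrl, rng)
            params, converged, _dev, _ = _fit_logit(y, X)
            if not converged:
                discarded += 1
                continue
            risks = _risks_from_design(params, X, exp_idx, weights, offset)
            # model-standardized observed risk (alternative PAF numerator):
            # corrected predictions at the imputed exposure, same weights
            obs_model = float(weights @ expit(X @ params - offset))
            draws.append(
                DrawRecord(
                    rr=risks.rr,
                    rd=risks.rd,
                    risk_exposed=risks.risk_exposed,
                    risk_unexposed=risks.risk_unexposed,
                    observed_risk=obs_risk,
                    observed_risk_model=obs_model,
                    paf=_paf(obs_risk, risks.risk_unexposed).paf,
                    paf_model=_paf(obs_model, risks.risk_unexposed).paf,
                    sensitivity=ss.sensitivity,
                    specificity=ss.specificity,
                    iteration=it,
                    bootstrap_index=bootstrap_index,
                )
            )
            break
        else:
            raise RuntimeError(
                f"iteration {it}: {max_redraws} attempts exhausted; priors place "
                "too much mass on (Se, Sp) combinations invalid for these counts "
                f"(reported exposed: cases {counts_case.n_reported_exposed}, "
                f"controls {counts_ctrl.n_reported_exposed})"
            )
    if discarded:
        logger.debug("run_pbam: %d invalid attempts discarded over %d iterations",
                     discarded, n_iter)
    if counters is not None:
        counters["n_discarded"] = counters.get("n_discarded", 0) + discarded
    return draws


def _stratified_resample(data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Resample cases and controls independently, keeping original group sizes."""
    is_case = data["outcome"].to_numpy() == 1
    idx_case = np.flatnonzero(is_case)
    idx_ctrl = np.flatnonzero(~is_case)
    take = np.concatenate([
        rng.choice(idx_case, size=idx_case.size, replace=True),
        rng.choice(idx_ctrl, size=idx_ctrl.size, replace=True),
    ])
    return data.iloc[take].reset_index(drop=True)


def bootstrap_pbam(
    data: pd.DataFrame,
    sens_prior: BiasPrior,
    spec_prior: BiasPrior,
    sf: SamplingFractions,
    model_spec: ModelSpec,
    n_boot: int,
    n_iter: int,
    rng,
    *,
    max_redraws: int = MAX_REDRAWS,
    counters: dict | None = None,
    n_jobs: int = 1,
) -> list[DrawRecord]:
    """Bias analysis on ``n_boot`` stratified bootstrap resamples, pooled.

    Returns ``n_boot * n_iter`` draws; ``bootstrap_index`` runs from 1.
    Results are identical for a given master ``rng``/seed regardless of
    ``n_jobs``, because each replicate gets its own spawned substream.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = _as_rng(rng)

    def one(b: int, child: np.random.Generator):
        local: dict = {}
        resample = _stratified_resample(data, child)
        d = run_pbam(resample, sens_prior, spec_prior, sf, model_spec, n_iter,
                     child, max_redraws=max_redraws, bootstrap_index=b,
                     counters=local)
        return d, local.get("n_discarded", 0)

    children = list(enumerate(rng.spawn(n_boot), start=1))
    if n_jobs == 1:
        results = [one(b, c) for b, c in children]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(one)(b, c) for b, c in children)

    draws: list[DrawRecord] = []
    discarded = 0
    for d, nd in results:
        draws.extend(d)
        discarded += nd
    if counters is not None:
        counters["n_discarded"] = counters.get("n_discarded", 0) + discarded
    return draws


def draws_to_frame(draws: list[DrawRecord]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in draws])


def summarize_draws(draws, metric: str = "rr", n_discarded: int = 0) -> EffectSummary:
    """Median and 2.5/97.5 empirical percentiles of one metric over draws.

    Percentiles use linear interpolation of order statistics (numpy's
    default), fixed here since quantile conventions differ across software.
    """
    if isinstance(draws, pd.DataFrame):
        values = draws[metric].to_numpy(dtype=float)
    else:
        values = np.array([getattr(d, metric) for d in draws], dtype=float)
    if values.size == 0:
        raise ValueError("no draws to summarize")
    lo, mid, hi = np.percentile(values, [2.5, 50.0, 97.5])
    return EffectSummary(point=float(mid), lower=float(lo), upper=float(hi),
                         n_draws=int(values.size), n_discarded=n_discarded)


def summarize_per_bootstrap(draws: list[DrawRecord], metric: str = "rr",
                            n_discarded: int = 0) -> EffectSummary:
    """Alternative summary: percentiles of per-bootstrap-replicate medians.

    Collapses each bootstrap replicate's Monte Carlo draws to its median
    first, then takes median and 2.5/97.5 percentiles across replicates.
    The default (pooled) summary in :func:`summarize_draws` treats all
    n_boot x n_iter draws as one distribution.
    """
    frame = draws_to_frame(draws)
    medians = frame.groupby("bootstrap_index")[metric].median().to_numpy()
    if medians.size == 0:
        raise ValueError("no draws to summarize")
    lo, mid, hi = np.percentile(medians, [2.5, 50.0, 97.5])
    return EffectSummary(point=float(mid), lower=float(lo), upper=float(hi),
                         n_draws=int(medians.size), n_discarded=n_discarded)


def conventional_analysis(
    data: pd.DataFrame,
    model_spec: ModelSpec,
    sf: SamplingFractions,
    n_boot: int = 500,
    rng=0,
    paf_observed: str = "counts",
) -> ConventionalResult:
    """Conventional analysis on the reported exposure (no bias correction).

    A single logistic fit gives the confounder-adjusted odds ratio with a
    Wald 95% CI; model-based standardization of the same fit gives the
    point RR, RD and PAF, whose CIs come from ``n_boot`` stratified
    bootstrap resamples (percentile method).  ``paf_observed`` selects the
    PAF numerator: outcome prevalence of the reconstructed study base
    (``"counts"``, default) or the model-standardized observed risk
    (``"model"``).
    """
    rng = _as_rng(rng)
    if paf_observed not in ("counts", "model"):
        raise ValueError("paf_observed must be 'counts' or 'model'")
    if data[model_spec.exposure_term].nunique() < 2:
        raise ValueError("reported exposure is constant; no effect is estimable")

    def point_estimates(df: pd.DataFrame):
        y = df["outcome"].to_numpy(dtype=float)
        X, names = build_design(df, model_spec)
        exp_idx = names.index(model_spec.exposure_term)
        params, converged, dev, bse = _fit_logit(y, X)
        if not converged:
            return None
        is_case = y == 1
        weights = _normalized_weights(is_case, sf)
        offset = intercept_offset(sf)
        risks = _risks_from_design(params, X, exp_idx, weights, offset)
        if paf_observed == "counts":
            obs = _observed_risk(int(is_case.sum()), int((~is_case).sum()), sf)
        else:
            obs = float(weights @ expit(X @ params - offset))
        return params, bse, exp_idx, risks, _paf(obs, risks.risk_unexposed).paf

    est = point_estimates(data)
    if est is None:
        raise ValueError("conventional logistic model did not converge")
    params, bse, exp_idx, risks, paf_point = est
    beta, se = params[exp_idx], bse[exp_idx]
    z = 1.959963984540054

    boot_rr, boot_rd, boot_paf = [], [], []
    for child in rng.spawn(n_boot) if n_boot else []:
        res = point_estimates(_stratified_resample(data, child))
        if res is None:
            continue
        _, _, _, b_risks, b_paf = res
        boot_rr.append(b_risks.rr)
        boot_rd.append(b_risks.rd)
        boot_paf.append(b_paf)

    def pct_ci(vals):
        if not vals:
            return (float("nan"), float("nan"))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return (float(lo), float(hi))

    return ConventionalResult(
        odds_ratio=float(np.exp(beta)),
        or_lower=float(np.exp(beta - z * se)),
        or_upper=float(np.exp(beta + z * se)),
        rr=risks.rr,
        rd=risks.rd,
        paf=paf_point,
        rr_ci=pct_ci(boot_rr),
        rd_ci=pct_ci(boot_rd),
        paf_ci=pct_ci(boot_paf),
        n_boot=len(boot_rr),
    )
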