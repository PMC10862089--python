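"""Prior distributions for exposure-classification accuracy (sensitivity/specificity).

Bias parameters for misclassification correction are uncertain quantities
summarised from validation studies.  This module pools accuracy estimates
across studies with a DerSimonian-Laird random-effects model on the logit
scale, fits the three prior families used in probabilistic bias analysis
(triangular, beta, logit-logistic) to a median + 95%-interval summary, and
draws sensitivity/specificity pairs for the Monte Carlo loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "QuantileSpec",
    "BiasPrior",
    "AccuracyStudy",
    "SensSpec",
    "pool_accuracy",
    "fit_prior",
    "sample_sens_spec",
]

_Z975 = stats.norm.ppf(0.975)
# logistic quantile multiplier for the central 95% interval: Q(0.975) - loc = scale * ln(39)
_L975 = np.log(0.975 / 0.025)


@dataclass(frozen=True)
class QuantileSpec:
    """Median and central 95% limits of a probability-valued quantity."""

    median: float
    q025: float
    q975: float

    def __post_init__(self) -> None:
        if not (0.0 < self.q025 < self.median < self.q975 < 1.0):
            raise ValueError(
                f"require 0 < q025 < median < q975 < 1, got "
                f"({self.q025}, {self.median}, {self.q975})"
            )


@dataclass(frozen=True)
class AccuracyStudy:
    """One validation study's accuracy estimate on the logit scale."""

    logit_estimate: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")


@dataclass(frozen=True)
class SensSpec:
    """A sensitivity/specificity pair, applied non-differentially to both groups."""

    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class BiasPrior:
    """A fitted prior for one accuracy parameter.

    ``kind`` is one of ``triangular``, ``beta``, ``logit_logistic``; ``params``
    holds the kind-specific parameters:

    * triangular: ``(min, max, mode)`` on the probability scale,
    * beta: ``(alpha, beta)``,
    * logit_logistic: ``(location, scale)`` of a logistic distribution on the
      logit scale whose expit is the prior.
    """

    kind: str
    params: tuple[float, ...]

    _KINDS = ("triangular", "beta", "logit_logistic")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "triangular":
            lo, hi, mode = self.params
            if lo == hi == mode:
                return  # point mass, allowed for degenerate/no-bias runs
            if not (lo <= mode <= hi and lo < hi):
                raise ValueError(f"triangular requires min <= mode <= max, got {self.params}")
            if not (0.0 <= lo and hi <= 1.0):
                raise ValueError("triangular support must lie within [0, 1]")
        elif self.kind == "beta":
            a, b = self.params
            if not (a > 0 and b > 0):
                raise ValueError(f"beta requires alpha, beta > 0, got {self.params}")
        else:
            _, s = self.params
            if not s >= 0:
                raise ValueError(f"logit_logistic scale must be >= 0, got {self.params}")

    # -- quantile function -------------------------------------------------

    def quantile(self, p):
        """Inverse CDF of the prior, vectorised over ``p``."""
        p = np.asarray(p, dtype=float)
        if self.kind == "triangular":
            lo, hi, mode = self.params
            if lo == hi:
                return np.full_like(p, mode)
            q = _triangular_ppf(p, lo, hi, mode)
        elif self.kind == "beta":
            a, b = self.params
            q = stats.beta.ppf(p, a, b)
        else:
            loc, s = self.params
            q = expit(loc + s * logit(p)) if s > 0 else np.full_like(p, expit(loc))
        return q if q.shape else float(q)

    def implied_quantiles(self) -> QuantileSpec:
        """The (2.5th, 50th, 97.5th) percentiles this prior actually implies."""
        q025, med, q975 = self.quantile([0.025, 0.5, 0.975])
        return QuantileSpec(median=med, q025=q025, q975=q975)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the prior by inverse-CDF transform of uniforms from ``rng``."""
        u = rng.uniform(size=size)
        return self.quantile(u)


def _triangular_ppf(p, lo, hi, mode):
    span = hi - lo
    f_mode = (mode - lo) / span
    left = lo + np.sqrt(p * span * (mode - lo))
    right = hi - np.sqrt((1.0 - p) * span * (hi - mode))
    return np.where(p <= f_mode, left, right)


# ---------------------------------------------------------------------------
# Random-effects pooling
# ---------------------------------------------------------------------------


def pool_accuracy(studies: Sequence[AccuracyStudy]) -> QuantileSpec:
    """Pool logit-scale accuracy estimates with DerSimonian-Laird random effects.

    Between-study heterogeneity tau^2 is the usual method-of-moments estimate
    truncated at zero; the pooled mean and its 95% limits are back-transformed
    to the probability scale.  A single study is returned as its own
    estimate +- 1.96 SE.
    """
    if len(studies) == 0:
        raise ValueError("need at least one accuracy study")
    y = np.array([s.logit_estimate for s in studies])
    v = np.array([s.variance for s in studies])

    if len(studies) == 1:
        mu, se = y[0], np.sqrt(v[0])
    else:
        w = 1.0 / v
        mu_fe = np.sum(w * y) / np.sum(w)
        q = np.sum(w * (y - mu_fe) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (len(studies) - 1)) / c)
        w_re = 1.0 / (v + tau2)
        mu = np.sum(w_re * y) / np.sum(w_re)
        se = np.sqrt(1.0 / np.sum(w_re))
    return QuantileSpec(
        median=float(expit(mu)),
        q025=float(expit(mu - _Z975 * se)),
        q975=float(expit(mu + _Z975 * se)),
    )


# ---------------------------------------------------------------------------
# Prior fitting
# ---------------------------------------------------------------------------


def fit_prior(kind: str, spec: QuantileSpec, params: Sequence[float] | None = None) -> BiasPrior:
    """Fit a prior of the given family to a median + 95%-interval summary.

    Parameterizations:

    * ``triangular``: the 2.5th/97.5th percentiles are taken as the support
      endpoints and the median as the mode, the convention used when bias
      parameters are specified as a pooled estimate with its 95% CI.
    * ``beta``: (alpha, beta) minimise the squared deviation of the implied
      (2.5th, 50th, 97.5th) percentiles from ``spec`` (Nelder-Mead over log
      parameters, started from a moment-matching guess).
    * ``logit_logistic``: logistic on the logit scale; location = logit(median),
      scale the average of the two one-sided solutions mapping the central 95%
      interval onto (logit(q025), logit(q975)).

    ``params`` bypasses fitting and uses the given kind-specific parameters
    verbatim (e.g. a published alpha/beta pair).
    """
    if params is not None:
        return BiasPrior(kind=kind, params=tuple(float(p) for p in params))
    if spec.q975 - spec.q025 <= 0:
        raise ValueError("degenerate quantile spec: q025 == q975")

    if kind == "triangular":
        return BiasPrior(kind, (spec.q025, spec.q975, spec.median))

    if kind == "logit_logistic":
        loc = logit(spec.median)
        s_hi = (logit(spec.q975) - loc) / _L975
        s_lo = (loc - logit(spec.q025)) / _L975
        return BiasPrior(kind, (float(loc), float(0.5 * (s_hi + s_lo))))

    if kind == "beta":
        m = spec.median
        sd = (spec.q975 - spec.q025) / (2 * _Z975)
        nu = max(m * (1 - m) / sd**2 - 1.0, 1e-3)
        x0 = np.log([max(m * nu, 1e-3), max((1 - m) * nu, 1e-3)])
        target = np.array([spec.q025, spec.median, spec.q975])

        def loss(logab):
            a, b = np.exp(logab)
            qq = stats.beta.ppf([0.025, 0.5, 0.975], a, b)
            return np.sum((qq - target) ** 2)

        res = optimize.minimize(loss, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000})
        a, b = np.exp(res.x)
        return BiasPrior("beta", (float(a), float(b)))

    raise ValueError(f"unknown prior kind {kind!r}")


def sample_sens_spec(
    sens_prior: BiasPrior, spec_prior: BiasPrior, rng: np.random.Generator
) -> SensSpec:
    """One independent draw of (sensitivity, specificity).

    The same pair is applied to cases and controls within a Monte Carlo
    iteration (non-differential misclassification).
    """
    return SensSpec(
        sensitivity=float(sens_prior.sample(rng)),
        specificity=float(spec_prior.sample(rng)),
    )
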