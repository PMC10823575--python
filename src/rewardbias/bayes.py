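"""Informed-prior and default-prior Bayes factors for one-degree-of-freedom effects.

The analyses supported here all reduce to an effect summary ``(mean, se, df)``
— a mean difference, its standard error, and the degrees of freedom of the
test that produced it.  Evidence for a directional or replication hypothesis
is quantified as a Bayes factor comparing

* H1: the effect ``delta`` is distributed as a (possibly truncated) shifted,
  scaled t distribution derived from a prior study, against
* H0: ``delta = 0`` exactly.

The observed mean is modelled as a scaled t variate centred on ``delta`` with
scale ``se`` and the data's degrees of freedom, so

    BF10 = [ integral f(mean | delta) pi(delta) d delta ] / f(mean | 0).

A default one-sample (JZS) Bayes factor with a zero-centred Cauchy prior on
the standardized effect size is provided for exploratory tests, along with
the standard-error scaling used for sequential design analysis and the
sequential stopping rule it feeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "EffectSummary",
    "PriorModel",
    "BayesFactorResult",
    "DesignAnalysis",
    "StoppingDecision",
    "informed_bf",
    "default_onesample_bf",
    "scale_se",
    "expected_bf_under_null",
    "stopping_rule",
]


class BayesNumericalError(RuntimeError):
    """Raised when the marginal-likelihood quadrature cannot be trusted."""


@dataclass(frozen=True)
class EffectSummary:
    """A one-degree-of-freedom effect: mean difference, its SE and df.

    ``n`` is optional; when provided for a paired/one-sample effect it must
    satisfy ``df == n - 1``.
    """

    mean: float
    se: float
    df: int
    n: int | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"se must be positive, got {self.se}")
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if self.n is not None and self.df != self.n - 1:
            raise ValueError(
                f"for paired/one-sample effects df must equal n-1; got df={self.df}, n={self.n}"
            )

    @property
    def t(self) -> float:
        return self.mean / self.se


class PriorFamily(str, Enum):
    SHIFTED_T = "shifted_t"
    HALF_T = "half_t"
    CAUCHY_ZERO = "cauchy_zero"


class Direction(str, Enum):
    TWO_SIDED = "two_sided"
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class PriorModel:
    """H1 effect-size distribution: a shifted/scaled, optionally truncated t.

    ``shifted_t`` with ``direction='two_sided'`` is the untruncated prior;
    a directional prior is the same t truncated at zero on the predicted
    side and renormalized.  ``half_t`` is the zero-located special case and
    must be directional.  ``cauchy_zero`` (location 0, df 1) is the default
    prior used by the JZS one-sample Bayes factor, on the standardized scale.
    """

    family: PriorFamily | str = PriorFamily.SHIFTED_T
    location: float = 0.0
    scale: float = 1.0
    df: float = 1.0
    direction: Direction | str = Direction.TWO_SIDED

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", PriorFamily(self.family))
        object.__setattr__(self, "direction", Direction(self.direction))
        if not (self.scale > 0):
            raise ValueError(f"prior scale must be positive, got {self.scale}")
        if not (self.df > 0):
            raise ValueError(f"prior df must be positive, got {self.df}")
        if self.family is PriorFamily.HALF_T:
            if self.direction is Direction.TWO_SIDED:
                raise ValueError("half_t priors must be directional")
            if self.location != 0.0:
                raise ValueError("half_t priors have location 0")
        if self.family is PriorFamily.CAUCHY_ZERO and self.location != 0.0:
            raise ValueError("cauchy_zero priors have location 0")

    # -- density helpers -------------------------------------------------
    def _base_pdf(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.family is PriorFamily.CAUCHY_ZERO:
            return stats.cauchy.pdf(x, loc=0.0, scale=self.scale)
        return stats.t.pdf(x, self.df, loc=self.location, scale=self.scale)

    def _truncation_mass(self) -> float:
        if self.direction is Direction.TWO_SIDED:
            return 1.0
        if self.family is PriorFamily.CAUCHY_ZERO:
            cdf0 = stats.cauchy.cdf(0.0, loc=0.0, scale=self.scale)
        else:
            cdf0 = stats.t.cdf(0.0, self.df, loc=self.location, scale=self.scale)
        return (1.0 - cdf0) if self.direction is Direction.POSITIVE else cdf0

    def pdf(self, x: np.ndarray | float) -> np.ndarray | float:
        """Prior density, truncated and renormalized for directional priors."""
        x = np.asarray(x, dtype=float)
        dens = np.asarray(self._base_pdf(x), dtype=float)
        if self.direction is Direction.POSITIVE:
            dens = np.where(x > 0, dens, 0.0) / self._truncation_mass()
        elif self.direction is Direction.NEGATIVE:
            dens = np.where(x < 0, dens, 0.0) / self._truncation_mass()
        return dens if dens.shape else float(dens)

    def support(self, extra_scale: float = 0.0, width: float = 12.0) -> tuple[float, float]:
        """Integration bounds: location +/- ``width`` prior scales, widened by the data scale."""
        h = width * max(self.scale, extra_scale)
        lo, hi = self.location - h, self.location + h
        if self.direction is Direction.POSITIVE:
            lo = max(lo, 0.0)
        elif self.direction is Direction.NEGATIVE:
            hi = min(hi, 0.0)
        return lo, hi


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    marginal_h1: float
    marginal_h0: float
    integration_error: float

    def __post_init__(self) -> None:
        if not (self.bf10 > 0):
            raise ValueError("bf10 must be positive")

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _t_likelihood(mean: float, df: int, se: float):
    """Density of the observed mean given effect ``delta``: scaled t, data df."""

    def lik(delta):
        return stats.t.pdf(mean, df, loc=delta, scale=se)

    return lik


def informed_bf(data: EffectSummary, prior: PriorModel) -> BayesFactorResult:
    """Bayes factor for ``data`` under an informed (shifted-t) H1 vs the point null.

    The marginal likelihood under H1 integrates the t(df=data.df, location
    delta, scale data.se) density of the observed mean against the prior on
    delta; H0 evaluates the same density at delta = 0.
    """
    if PriorFamily(prior.family) not in (PriorFamily.SHIFTED_T, PriorFamily.HALF_T):
        raise ValueError("informed_bf requires a shifted_t or half_t prior")
    lik = _t_likelihood(data.mean, data.df, data.se)
    lo, hi = prior.support(extra_scale=data.se)
    # widen to cover the likelihood's own mass; breakpoints keep quad honest
    lo = min(lo, data.mean - 12.0 * data.se)
    hi = max(hi, data.mean + 12.0 * data.se)
    if prior.direction is Direction.POSITIVE:
        lo = max(lo, 0.0)
    elif prior.direction is Direction.NEGATIVE:
        hi = min(hi, 0.0)
    if not hi > lo:
        raise ValueError("empty integration range; prior and data are incompatible")
    pts = [p for p in (data.mean, prior.location) if lo < p < hi]
    marginal_h1, err = integrate.quad(
        lambda d: lik(d) * prior.pdf(d), lo, hi,
        points=pts or None, limit=400, epsabs=0.0, epsrel=1e-10,
    )
    marginal_h0 = lik(0.0)
    if marginal_h1 <= 0 or not np.isfinite(marginal_h1):
        raise BayesNumericalError(
            f"marginal likelihood under H1 did not converge ({marginal_h1})"
        )
    bf10 = marginal_h1 / marginal_h0
    if err > 1e-6 * marginal_h1:
        raise BayesNumericalError(
            f"quadrature error {err:.3g} exceeds 1e-6 of the H1 marginal {marginal_h1:.3g}"
        )
    return BayesFactorResult(
        bf10=bf10,
        marginal_h1=marginal_h1,
        marginal_h0=marginal_h0,
        integration_error=err / marginal_h0,
    )


def default_onesample_bf(
    t_stat: float, n: int, scale: float = math.sqrt(2) / 2
) -> BayesFactorResult:
    """JZS one-sample Bayes factor: zero-centred Cauchy(scale) prior on d vs point null.

    The likelihood of the observed t statistic given a standardized effect
    ``d`` is noncentral t with ``n - 1`` df and noncentrality ``d * sqrt(n)``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not scale > 0:
        raise ValueError("scale must be positive")
    df = n - 1
    rootn = math.sqrt(n)

    def integrand(d):
        return stats.nct.pdf(t_stat, df, d * rootn) * stats.cauchy.pdf(d, 0.0, scale)

    center = t_stat / rootn
    half = 12.0 * max(scale, abs(center) / 2 + 1.0)
    marginal_h1, err = integrate.quad(
        integrand, center - half, center + half,
        points=[0.0, center], limit=400, epsabs=0.0, epsrel=1e-10,
    )
    marginal_h0 = stats.t.pdf(t_stat, df)
    if marginal_h1 <= 0 or not np.isfinite(marginal_h1):
        raise BayesNumericalError("JZS marginal likelihood did not converge")
    if err > 1e-6 * marginal_h1:
        raise BayesNumericalError("JZS quadrature error bound exceeded")
    return BayesFactorResult(
        bf10=marginal_h1 / marginal_h0,
        marginal_h1=marginal_h1,
        marginal_h0=marginal_h0,
        integration_error=err / marginal_h0,
    )


@dataclass(frozen=True)
class DesignAnalysis:
    """SE scaling of a source study to a planned sample size, and the BF expected under H0."""

    se_original: float
    n_original: int
    n_target: int
    se_scaled: float
    expected_bf_under_null: float | None = None


def scale_se(se_original: float, n_original: int, n_target: int) -> DesignAnalysis:
    """Rescale a source study's SE to a planned n: se * sqrt(n_original / n_target)."""
    if se_original <= 0 or n_original <= 0 or n_target <= 0:
        raise ValueError("se_original, n_original and n_target must all be positive")
    return DesignAnalysis(
        se_original=se_original,
        n_original=n_original,
        n_target=n_target,
        se_scaled=se_original * math.sqrt(n_original / n_target),
    )


def expected_bf_under_null(
    prior: PriorModel, se_scaled: float, df_target: int
) -> float:
    """Bayes factor expected if the planned study observes a mean of exactly zero."""
    data = EffectSummary(mean=0.0, se=se_scaled, df=df_target)
    return informed_bf(data, prior).bf10


class StoppingDecision(str, Enum):
    CONTINUE = "continue"
    STOP_H1 = "stop_h1"
    STOP_H0 = "stop_h0"
    STOP_CAP = "stop_cap"


def stopping_rule(
    bf_values: Sequence[float],
    n_collected: int,
    n_cap: int = 30,
    upper: float = 6.0,
    lower: float = 1.0 / 6.0,
) -> StoppingDecision:
    """Sequential rule: stop when every monitored BF clears a threshold or n hits the cap.

    ``stop_h1`` when all BFs exceed ``upper``; ``stop_h0`` when all fall below
    ``lower``; otherwise ``stop_cap`` once ``n_collected >= n_cap``, else
    ``continue``.
    """
    if not (upper > 1.0 > lower > 0.0):
        raise ValueError("thresholds must satisfy upper > 1 > lower > 0")
    bfs = list(bf_values)
    if not bfs:
        raise ValueError("bf_values must be non-empty")
    if any(b <= 0 for b in bfs):
        raise ValueError("Bayes factors must be positive")
    if all(b > upper for b in bfs):
        return StoppingDecision.STOP_H1
    if all(b < lower for b in bfs):
        return StoppingDecision.STOP_H0
    if n_collected >= n_cap:
        return StoppingDecision.STOP_CAP
    return StoppingDecision.CONTINUE
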