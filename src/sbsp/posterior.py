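"""Closed-form posteriors for unseen-feature counts.

Given hyperparameters (sigma, c, beta) and sufficient statistics (N, K_N),
the number of new features in M further samples — in total, or with an exact
prevalence r — follows a negative-Binomial law whose parameters are simple
Beta-sum expressions.  Large-M limits are Gamma laws: the count grows like
M^sigma with a Gamma-distributed multiplier.

Negative-Binomial convention used throughout (pinned so that the mean
reproduces the closed-form point estimator, see ``NegBinLaw``):

    pmf(u) = Gamma(u + size) / (Gamma(size) u!) * p^u * (1 - p)^size,
    mean   = size * p / (1 - p).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count as _count

import numpy as np
from scipy.special import gammaln
from scipy.stats import nbinom

from .io import FeatureFrequencies
from .special import SBSPParams, gamma0, gamma_forward, rho_prevalence

__all__ = [
    "NegBinLaw",
    "GammaLaw",
    "CredibleInterval",
    "negbin_pmf",
    "unseen_posterior",
    "unseen_prevalence_posterior",
    "unseen_point_estimate",
    "unseen_prevalence_estimate",
    "credible_interval",
    "asymptotic_law",
]


@dataclass(frozen=True)
class NegBinLaw:
    """Negative-Binomial law with pmf(u) ∝ p^u (1-p)^size.

    ``size`` is K_N + c + 1 in every posterior below.  ``p = 0`` is the
    degenerate point mass at zero (arises only behind an explicit flag).
    """

    size: float
    p: float

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"size must be > 0, got {self.size}")
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"p must lie in [0, 1), got {self.p}")

    @property
    def mean(self) -> float:
        return self.size * self.p / (1.0 - self.p)

    @property
    def variance(self) -> float:
        return self.size * self.p / (1.0 - self.p) ** 2

    def frozen(self):
        """scipy frozen distribution (scipy's p is our 1 - p)."""
        return nbinom(self.size, 1.0 - self.p)

    def to_dict(self) -> dict:
        return {"size": float(self.size), "p": float(self.p)}


@dataclass(frozen=True)
class GammaLaw:
    """Gamma law in shape/rate form: density ∝ x^(shape-1) exp(-rate x)."""

    shape: float
    rate: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def frozen(self):
        from scipy.stats import gamma as _gamma

        return _gamma(self.shape, scale=1.0 / self.rate)

    def to_dict(self) -> dict:
        return {"shape": float(self.shape), "rate": float(self.rate)}


@dataclass(frozen=True)
class CredibleInterval:
    low: int
    high: int
    level: float
    attained_mass: float

    def __post_init__(self) -> None:
        if self.low < 0 or self.high < self.low:
            raise ValueError("require 0 <= low <= high")
        if not self.attained_mass >= self.level - 1e-12:
            raise ValueError("attained_mass below the requested level")

    def to_dict(self) -> dict:
        return {
            "interval": [int(self.low), int(self.high)],
            "level": float(self.level),
            "attained_mass": float(self.attained_mass),
        }


def negbin_pmf(law: NegBinLaw, u: int) -> float:
    """pmf of ``law`` at integer u >= 0, computed in log space."""
    u = int(u)
    if u < 0:
        raise ValueError(f"u must be >= 0, got {u}")
    if law.p == 0.0:
        return 1.0 if u == 0 else 0.0
    log_pmf = (
        gammaln(u + law.size)
        - gammaln(law.size)
        - gammaln(u + 1)
        + u * np.log(law.p)
        + law.size * np.log1p(-law.p)
    )
    return float(np.exp(log_pmf))


def unseen_posterior(
    params: SBSPParams, stats: FeatureFrequencies, m_extra: int
) -> NegBinLaw:
    """Posterior law of the total number of new features in ``m_extra``
    further samples.  Depends on the data only through (n, k)."""
    if m_extra < 1:
        raise ValueError(f"m_extra must be >= 1, got {m_extra}")
    gam = gamma_forward(m_extra, stats.n, params.sigma)
    denom = params.beta + gamma0(stats.n + m_extra, params.sigma)
    return NegBinLaw(size=stats.k + params.c + 1.0, p=gam / denom)


def unseen_prevalence_posterior(
    params: SBSPParams,
    stats: FeatureFrequencies,
    m_extra: int,
    r: int,
    allow_degenerate: bool = False,
) -> NegBinLaw:
    """Posterior law of the number of new features appearing in exactly
    ``r`` of ``m_extra`` further samples.

    ``r > m_extra`` makes the law degenerate at zero; that is refused
    unless ``allow_degenerate`` is set.
    """
    if m_extra < 1:
        raise ValueError(f"m_extra must be >= 1, got {m_extra}")
    if r < 1:
        raise ValueError(f"prevalence r must be >= 1, got {r}")
    if r > m_extra and not allow_degenerate:
        raise ValueError(
            f"r={r} exceeds m_extra={m_extra}; pass allow_degenerate=True "
            "for the point mass at 0"
        )
    rho = rho_prevalence(m_extra, r, stats.n, params.sigma)
    denom = params.beta + gamma0(stats.n, params.sigma) + rho
    return NegBinLaw(size=stats.k + params.c + 1.0, p=rho / denom)


def unseen_point_estimate(
    params: SBSPParams, stats: FeatureFrequencies, m_extra: int
) -> float:
    """Squared-loss optimal estimate of the total new-feature count.

    Linear in k with slope gamma_forward / (beta + gamma0(n)).
    """
    if m_extra < 1:
        raise ValueError(f"m_extra must be >= 1, got {m_extra}")
    gam = gamma_forward(m_extra, stats.n, params.sigma)
    return (stats.k + params.c + 1.0) * gam / (params.beta + gamma0(stats.n, params.sigma))


def unseen_prevalence_estimate(
    params: SBSPParams,
    stats: FeatureFrequencies,
    m_extra: int,
    r: int,
    allow_degenerate: bool = False,
) -> float:
    """Squared-loss optimal estimate of the new-feature count at prevalence r."""
    if r < 1:
        raise ValueError(f"prevalence r must be >= 1, got {r}")
    if r > m_extra and not allow_degenerate:
        raise ValueError(
            f"r={r} exceeds m_extra={m_extra}; pass allow_degenerate=True for 0"
        )
    rho = rho_prevalence(m_extra, r, stats.n, params.sigma)
    return (stats.k + params.c + 1.0) * rho / (params.beta + gamma0(stats.n, params.sigma))


def credible_interval(
    law: NegBinLaw, level: float, equal_tailed: bool = False
) -> CredibleInterval:
    """Credible interval for a negative-Binomial law.

    Default: the smallest integer window symmetric around the rounded mean,
    [max(0, round(mean) - t), round(mean) + t], whose pmf mass reaches
    ``level``.  ``equal_tailed=True`` gives the standard quantile interval
    instead.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    dist = law.frozen()
    if equal_tailed:
        alpha = 1.0 - level
        low = int(dist.ppf(alpha / 2.0))
        high = int(dist.ppf(1.0 - alpha / 2.0))
        mass = dist.cdf(high) - (dist.cdf(low - 1) if low > 0 else 0.0)
        return CredibleInterval(low=low, high=high, level=level, attained_mass=float(mass))
    center = int(round(law.mean))
    for t in _count(0):
        low = max(0, center - t)
        high = center + t
        mass = dist.cdf(high) - (dist.cdf(low - 1) if low > 0 else 0.0)
        if mass >= level:
            return CredibleInterval(
                low=low, high=high, level=level, attained_mass=float(mass)
            )
    raise AssertionError("unreachable")


def asymptotic_law(
    params: SBSPParams, stats: FeatureFrequencies, r: int | None = None
) -> GammaLaw:
    """Large-M limit law of (new-feature count) / M^sigma.

    Total count: Gamma(k + c + 1, (beta + gamma0(n)) / Gamma(1 - sigma)).
    At prevalence r: rate Gamma(r+1) (beta + gamma0(n)) / (sigma Gamma(r - sigma)).
    """
    base = params.beta + gamma0(stats.n, params.sigma)
    shape = stats.k + params.c + 1.0
    if r is None:
        rate = base / np.exp(gammaln(1.0 - params.sigma))
    else:
        if r < 1:
            raise ValueError(f"prevalence r must be >= 1, got {r}")
        rate = (
            np.exp(gammaln(r + 1.0) - gammaln(r - params.sigma))
            * base
            / params.sigma
        )
    return GammaLaw(shape=shape, rate=float(rate))


def prediction_to_dict(
    params: SBSPParams,
    stats: FeatureFrequencies,
    m_extra: int,
    level: float | None = None,
    r_list=(),
) -> dict:
    """JSON-ready bundle of estimates, laws and intervals for one M."""
    law = unseen_posterior(params, stats, m_extra)
    out = {
        "M": int(m_extra),
        "estimate": unseen_point_estimate(params, stats, m_extra),
        "posterior": law.to_dict(),
    }
    if level is not None:
        ci = credible_interval(law, level)
        out.update(ci.to_dict())
    by_r = {}
    for r in r_list:
        r_law = unseen_prevalence_posterior(params, stats, m_extra, r)
        entry = {
            "estimate": unseen_prevalence_estimate(params, stats, m_extra, r),
            "posterior": r_law.to_dict(),
        }
        if level is not None:
            entry.update(credible_interval(r_law, level).to_dict())
        by_r[str(r)] = entry
    if by_r:
        out["by_prevalence"] = by_r
    return out
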