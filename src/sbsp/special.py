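"""Closed-form Beta/Gamma quantities driving feature-discovery rates.

The three quantities

* ``gamma0(n)``       = sigma * sum_{i=1..n} B(1-sigma, i)
* ``gamma_forward``   = sigma * sum_{i=1..m} B(1-sigma, n+i)
* ``rho_prevalence``  = C(m, r) * sigma * B(r-sigma, n+m-r+1)

control the expected number of distinct features in ``n`` samples, of new
features in ``m`` further samples, and of new features appearing in exactly
``r`` of those, respectively.

Every term is evaluated in log space via log-Gamma and accumulated directly:
all terms are strictly positive so the sums involve no cancellation.  The
cumulative sums are cached per ``sigma`` (bounded LRU) because empirical-Bayes
optimisation evaluates ``gamma0`` at the same sample size for many sigma
values, and extrapolation sweeps evaluate it at many sizes for one sigma.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "SBSPParams",
    "log_beta_fn",
    "gamma0",
    "gamma_forward",
    "rho_prevalence",
]


@dataclass(frozen=True)
class SBSPParams:
    """Hyperparameters of the stable-Beta scaled process prior.

    Attributes
    ----------
    sigma : float
        Stability/discount exponent, strictly inside (0, 1).  Governs the
        power-law growth rate of discovered features.
    c : float
        Concentration-like tilt exponent, >= 0.  ``c = 0`` is the
        Beta-process corner subcase and is permitted.
    beta : float
        Rate tilt, strictly positive.
    """

    sigma: float
    c: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < float(self.sigma) < 1.0):
            raise ValueError(f"sigma must lie strictly in (0, 1), got {self.sigma!r}")
        if not float(self.c) >= 0.0:
            raise ValueError(f"c must be >= 0, got {self.c!r}")
        if not float(self.beta) > 0.0:
            raise ValueError(f"beta must be > 0, got {self.beta!r}")

    def to_dict(self) -> dict:
        return {"sigma": float(self.sigma), "c": float(self.c), "beta": float(self.beta)}


def log_beta_fn(a: float, b: float) -> float:
    """log of the Euler Beta function, via log-Gamma.

    Finite for all strictly positive arguments.
    """
    if not (a > 0 and b > 0):
        raise ValueError(f"Beta function arguments must be positive, got ({a}, {b})")
    return float(gammaln(a) + gammaln(b) - gammaln(a + b))


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if not 0.0 < sigma < 1.0:
        raise ValueError(f"sigma must lie strictly in (0, 1), got {sigma}")
    return sigma


def _check_count(value, name: str):
    if value != int(value) or value < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    return int(value)


# sigma -> array S with S[j] = sigma * sum_{i=1..j} B(1-sigma, i); bounded LRU.
_CACHE_MAX = 64
_cumsums: "OrderedDict[float, np.ndarray]" = OrderedDict()


def _cumulative(sigma: float, upto: int) -> np.ndarray:
    arr = _cumsums.get(sigma)
    if arr is None or arr.size <= upto:
        size = max(upto + 1, 257, 0 if arr is None else 2 * arr.size)
        i = np.arange(1, size, dtype=float)
        terms = sigma * np.exp(betaln(1.0 - sigma, i))
        arr = np.concatenate(([0.0], np.cumsum(terms)))
        _cumsums[sigma] = arr
    _cumsums.move_to_end(sigma)
    while len(_cumsums) > _CACHE_MAX:
        _cumsums.popitem(last=False)
    return arr


def gamma0(n: int, sigma: float) -> float:
    """sigma * sum_{i=1..n} B(1-sigma, i); 0 at n = 0, strictly increasing."""
    sigma = _check_sigma(sigma)
    n = _check_count(n, "n")
    if n == 0:
        return 0.0
    return float(_cumulative(sigma, n)[n])


def gamma_forward(m_extra: int, n: int, sigma: float) -> float:
    """sigma * sum_{i=1..m_extra} B(1-sigma, n+i).

    Satisfies ``gamma0(n) + gamma_forward(m, n) == gamma0(n + m)`` (the two
    are computed from the same cached cumulative sums, so the identity holds
    to the last bit).
    """
    sigma = _check_sigma(sigma)
    m_extra = _check_count(m_extra, "m_extra")
    n = _check_count(n, "n")
    if m_extra == 0:
        return 0.0
    arr = _cumulative(sigma, n + m_extra)
    return float(arr[n + m_extra] - arr[n])


def rho_prevalence(m_extra: int, r: int, n: int, sigma: float) -> float:
    """C(m_extra, r) * sigma * B(r - sigma, n + m_extra - r + 1).

    Expected-rate weight for new features appearing in exactly ``r`` of
    ``m_extra`` additional samples.  Zero when ``r > m_extra`` (the binomial
    coefficient vanishes).  Evaluated in log space then exponentiated.
    """
    sigma = _check_sigma(sigma)
    m_extra = _check_count(m_extra, "m_extra")
    if m_extra < 1:
        raise ValueError(f"m_extra must be >= 1, got {m_extra}")
    r = int(r)
    if r < 1:
        raise ValueError(f"prevalence r must be >= 1, got {r}")
    n = _check_count(n, "n")
    if r > m_extra:
        return 0.0
    log_binom = gammaln(m_extra + 1) - gammaln(r + 1) - gammaln(m_extra - r + 1)
    return float(np.exp(log_binom + np.log(sigma) + betaln(r - sigma, n + m_extra - r + 1)))
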