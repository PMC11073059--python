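"""Marginal allocation probability and empirical-Bayes hyperparameter fitting.

``log_efpf`` is the log-probability that N samples display one *particular*
feature allocation with k distinct features of frequencies (m_1, ..., m_k).
All constant factors are kept, so it is a genuine log-probability: summing
exp(log_efpf) times combinatorial multiplicities over allocation classes
gives 1, and the k = 0 value equals the marginal P(K_N = 0).  This is what
lets the forward simulator cross-validate it.

``fit_empirical_bayes`` maximizes log_efpf over (sigma, c, beta) by
multi-start Nelder-Mead in transformed coordinates (logit sigma, log c,
log beta) with box backstops; (c, beta) are weakly identified, hence the
restarts, and boundary hits are reported rather than silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .errors import DegenerateDataError
from .io import FeatureFrequencies
from .special import SBSPParams, gamma0

__all__ = [
    "log_efpf",
    "fit_empirical_bayes",
    "efpf_profile",
    "FitOptions",
    "FitDiagnostics",
]

# Box backstops in natural coordinates.
SIGMA_BOX = (1e-4, 1.0 - 1e-4)
C_BOX = (1e-8, 1e4)
BETA_BOX = (1e-8, 1e6)

# Fixed 8-point spread over the transformed box corners/edges, plus one
# moment-matched start appended at fit time.
_FIXED_STARTS = np.array(
    [
        [-2.0, -2.0, -2.0],
        [-2.0, 0.0, 0.0],
        [-2.0, 2.0, 2.0],
        [0.0, -2.0, 0.0],
        [0.0, 2.0, -2.0],
        [2.0, -2.0, 2.0],
        [2.0, 0.0, -2.0],
        [2.0, 2.0, 0.0],
    ]
)


def log_efpf(params: SBSPParams, stats: FeatureFrequencies) -> float:
    """Log-probability of a particular feature allocation (N, k, m)."""
    m = np.asarray(stats.m, dtype=float)
    if m.size and m.min() < 1:
        raise ValueError("frequencies m_i must be >= 1")
    sigma, c, beta = params.sigma, params.c, params.beta
    n, k = stats.n, stats.k
    g0 = gamma0(n, sigma)
    value = (
        k * np.log(sigma)
        + (c + 1.0) * np.log(beta)
        - (k + c + 1.0) * np.log(beta + g0)
        + gammaln(k + c + 1.0)
        - gammaln(c + 1.0)
    )
    if k:
        value += float(
            np.sum(gammaln(m - sigma) + gammaln(n - m + 1.0))
            - k * gammaln(n - sigma + 1.0)
        )
    return float(value)


@dataclass(frozen=True)
class FitOptions:
    maxiter: int = 2000
    xatol: float = 1e-8
    fatol: float = 1e-12
    extra_starts: tuple = ()  # extra (x0, x1, x2) transformed-space starts


@dataclass
class FitDiagnostics:
    log_efpf: float
    n_restarts: int
    converged: list = field(default_factory=list)
    boundary: list = field(default_factory=list)
    best_start: int = -1
    start_values: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "log_efpf": float(self.log_efpf),
            "n_restarts": int(self.n_restarts),
            "converged": [bool(v) for v in self.converged],
            "boundary": list(self.boundary),
            "best_start": int(self.best_start),
        }


def _unpack(x: np.ndarray) -> tuple[float, float, float]:
    sigma = float(np.clip(expit(x[0]), *SIGMA_BOX))
    c = float(np.clip(np.exp(x[1]), *C_BOX))
    beta = float(np.clip(np.exp(x[2]), *BETA_BOX))
    return sigma, c, beta


def _moment_start(stats: FeatureFrequencies) -> np.ndarray:
    # sigma=1/2, c=1, and beta chosen so the marginal mean of K matches k:
    # E[K_N] = (c+1) gamma0(N) / beta.
    sigma0, c0 = 0.5, 1.0
    beta0 = (c0 + 1.0) * gamma0(stats.n, sigma0) / max(stats.k, 1)
    beta0 = float(np.clip(beta0, *BETA_BOX))
    return np.array([logit(sigma0), np.log(c0), np.log(beta0)])


def fit_empirical_bayes(
    stats: FeatureFrequencies, options: FitOptions | None = None
) -> tuple[SBSPParams, FitDiagnostics]:
    """Maximize log_efpf over (sigma, c, beta); deterministic multi-start."""
    if stats.k == 0:
        raise DegenerateDataError(
            "degenerate likelihood: no observed features (k = 0); the EFPF "
            "is maximized on the parameter boundary"
        )
    opts = options or FitOptions()

    def negative(x: np.ndarray) -> float:
        return -log_efpf(SBSPParams(*_unpack(x)), stats)

    starts = [row for row in _FIXED_STARTS]
    starts.append(_moment_start(stats))
    starts.extend(np.asarray(s, dtype=float) for s in opts.extra_starts)

    results = []
    for x0 in starts:
        res = minimize(
            negative,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": opts.maxiter,
                "xatol": opts.xatol,
                "fatol": opts.fatol,
            },
        )
        results.append(res)

    best_idx = int(np.argmin([res.fun for res in results]))
    best = results[best_idx]
    sigma, c, beta = _unpack(best.x)
    params = SBSPParams(sigma=sigma, c=c, beta=beta)

    boundary = []
    for name, value, box in (
        ("sigma", sigma, SIGMA_BOX),
        ("c", c, C_BOX),
        ("beta", beta, BETA_BOX),
    ):
        if value <= box[0] * (1 + 1e-9) or value >= box[1] * (1 - 1e-9):
            boundary.append(name)

    diag = FitDiagnostics(
        log_efpf=-float(best.fun),
        n_restarts=len(starts),
        converged=[bool(res.success) for res in results],
        boundary=boundary,
        best_start=best_idx,
        start_values=[-float(negative(x0)) for x0 in starts],
    )
    return params, diag


def efpf_profile(stats: FeatureFrequencies, grid) -> pd.DataFrame:
    """Evaluate log_efpf on a grid of parameter points.

    ``grid`` is an iterable of SBSPParams or (sigma, c, beta) triples.
    """
    records = []
    for point in grid:
        params = point if isinstance(point, SBSPParams) else SBSPParams(*point)
        records.append(
            {
                "sigma": params.sigma,
                "c": params.c,
                "beta": params.beta,
                "log_efpf": log_efpf(params, stats),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["sigma", "c", "beta", "log_efpf"]
    )
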