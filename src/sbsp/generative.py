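"""Exact forward and posterior-predictive simulation, plus misspecified
fixed-probability generators.

The sampler exploits the conditional structure of the prior: the transformed
largest-atom variable T = Delta_1^(-sigma) is Gamma(c+1, beta) a priori and
Gamma(k+c+1, beta + gamma0(N)) given data.  Conditional on T, sample j
reveals Poisson(T * sigma * B(1-sigma, j)) brand-new features, each with a
persistent latent probability drawn from Beta(1-sigma, j); previously created
features recur as independent coin flips of their latent probabilities.

The latent probability is drawn once at creation and reused ("conditional
iid"); by Beta-Bernoulli conjugacy this is exactly equivalent to the
Polya-style marginal scheme in which a feature seen m times in j samples
recurs with probability (m - sigma) / (j + 1 - sigma).  The equivalence is
asserted by the test suite, not assumed.

Beta(1-sigma, b) variates use the Gamma-ratio construction, which stays
accurate when the first parameter is close to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import betaln

from .io import BinaryFeatureMatrix, FeatureFrequencies
from .special import SBSPParams, gamma0

__all__ = [
    "SimState",
    "draw_total_mass_prior",
    "draw_total_mass_posterior",
    "simulate_forward",
    "simulate_continuation",
    "ContinuationDraw",
    "simulate_fixed_probabilities",
    "powerlaw_probabilities",
]


@dataclass
class FeatureRecord:
    identifier: int
    latent_probability: float
    count: int


@dataclass
class SimState:
    """Latent state of the sequential sampler."""

    total_mass: float
    features: list = field(default_factory=list)
    n_done: int = 0

    def validate(self) -> None:
        if not self.total_mass > 0:
            raise ValueError("total_mass must be positive")
        for rec in self.features:
            if not 0.0 < rec.latent_probability < 1.0:
                raise ValueError("latent probabilities must lie strictly in (0, 1)")
            if not 1 <= rec.count <= self.n_done:
                raise ValueError("feature counts must lie in 1..n_done")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_total_mass_prior(params: SBSPParams, seed) -> float:
    """One draw of T = Delta_1^(-sigma) ~ Gamma(c + 1, rate beta)."""
    rng = _rng(seed)
    return float(rng.gamma(params.c + 1.0, 1.0 / params.beta))


def draw_total_mass_posterior(params: SBSPParams, stats: FeatureFrequencies, seed) -> float:
    """One draw of T given data: Gamma(k + c + 1, rate beta + gamma0(n))."""
    rng = _rng(seed)
    rate = params.beta + gamma0(stats.n, params.sigma)
    return float(rng.gamma(stats.k + params.c + 1.0, 1.0 / rate))


def _beta_one_minus_sigma(rng: np.random.Generator, sigma: float, b: np.ndarray) -> np.ndarray:
    """Beta(1 - sigma, b) via the Gamma-ratio construction."""
    g1 = rng.gamma(1.0 - sigma, size=b.shape)
    g2 = rng.gamma(b)
    return g1 / (g1 + g2)


def _new_feature_rates(sigma: float, first_step: int, n_steps: int) -> np.ndarray:
    """sigma * B(1 - sigma, j) for j = first_step .. first_step + n_steps - 1."""
    j = np.arange(first_step, first_step + n_steps, dtype=float)
    return sigma * np.exp(betaln(1.0 - sigma, j))


def simulate_forward(
    params: SBSPParams,
    n: int,
    seed,
    total_mass: float | None = None,
    return_state: bool = False,
):
    """Simulate an n-row incidence matrix from the prior predictive.

    Feature identifiers are consecutive integers in creation order; the
    creation order is part of the seeded determinism contract.  Passing
    ``total_mass`` conditions on T instead of drawing it.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = _rng(seed)
    T = draw_total_mass_prior(params, rng) if total_mass is None else float(total_mass)
    if n == 0:
        matrix = BinaryFeatureMatrix.from_dense(np.zeros((0, 0), dtype=np.int8))
        if return_state:
            return matrix, SimState(total_mass=T, features=[], n_done=0)
        return matrix

    steps = np.arange(1, n + 1)
    counts = rng.poisson(T * _new_feature_rates(params.sigma, 1, n))
    creation = np.repeat(steps, counts)  # creation step of each feature
    n_feat = creation.size
    probs = _beta_one_minus_sigma(rng, params.sigma, creation.astype(float))

    # Sample creation row is forced present; earlier rows absent; later rows
    # are independent flips of the persistent latent probability.
    flips = rng.random((n, n_feat)) < probs[None, :]
    incidence = np.where(steps[:, None] > creation[None, :], flips, False)
    incidence[creation - 1, np.arange(n_feat)] = True

    matrix = BinaryFeatureMatrix.from_dense(
        incidence.astype(np.int8), feature_ids=list(range(n_feat))
    )
    if return_state:
        state = SimState(
            total_mass=T,
            features=[
                FeatureRecord(int(i), float(probs[i]), int(incidence[:, i].sum()))
                for i in range(n_feat)
            ],
            n_done=n,
        )
        return matrix, state
    return matrix


class ContinuationDraw(NamedTuple):
    u_total: int
    by_prevalence: dict


def simulate_continuation(
    stats: FeatureFrequencies,
    params: SBSPParams,
    m_extra: int,
    n_reps: int,
    seed,
) -> list:
    """Posterior-predictive draws of the unseen counts.

    Each draw samples T from its Gamma posterior, creates new features at
    steps n+1 .. n+m_extra with the sequential rates, and records the total
    count and its exact-prevalence decomposition (a feature created at
    relative step i appears 1 + Binomial(m_extra - i, latent p) times).
    Per draw, the prevalence counts sum to the total.
    """
    if m_extra < 1:
        raise ValueError(f"m_extra must be >= 1, got {m_extra}")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = _rng(seed)
    sigma = params.sigma
    rate = params.beta + gamma0(stats.n, sigma)
    shape = stats.k + params.c + 1.0
    rates_template = _new_feature_rates(sigma, stats.n + 1, m_extra)
    rel_steps = np.arange(1, m_extra + 1)

    draws = []
    for _ in range(n_reps):
        T = rng.gamma(shape, 1.0 / rate)
        counts = rng.poisson(T * rates_template)
        creation = np.repeat(rel_steps, counts)
        if creation.size:
            probs = _beta_one_minus_sigma(
                rng, sigma, (stats.n + creation).astype(float)
            )
            prevalence = 1 + rng.binomial(m_extra - creation, probs)
            tally = np.bincount(prevalence)
            by_prev = {int(r): int(tally[r]) for r in np.nonzero(tally)[0]}
        else:
            by_prev = {}
        draws.append(ContinuationDraw(int(creation.size), by_prev))
    return draws


def simulate_fixed_probabilities(probabilities, n: int, seed) -> BinaryFeatureMatrix:
    """Misspecified generator: feature i present independently w.p. p_i."""
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() <= 0.0 or p.max() >= 1.0):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    rng = _rng(seed)
    incidence = (rng.random((int(n), p.size)) < p[None, :]).astype(np.int8)
    return BinaryFeatureMatrix.from_dense(incidence, feature_ids=list(range(p.size)))


def powerlaw_probabilities(n_features: int, exponent: float, scale: float) -> np.ndarray:
    """Deterministic heavy-tailed sequence scale * i^(-exponent), clipped to (0, 1).

    Emulates variant-frequency spectra for misspecification experiments.
    """
    if n_features < 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    if exponent < 0:
        raise ValueError(f"exponent must be >= 0, got {exponent}")
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale must lie in (0, 1], got {scale}")
    i = np.arange(1, n_features + 1, dtype=float)
    return np.clip(scale * i ** (-exponent), 1e-300, 1.0 - 1e-12)
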