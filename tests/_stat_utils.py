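"""Shared statistical helpers for the test suite (independent oracles)."""

import math
from collections import Counter

import numpy as np
from scipy.stats import chisquare


def pool_and_chisquare(observed_counts, probabilities, min_expected=5.0):
    """Chi-square goodness-of-fit with small-expected-cell pooling.

    ``observed_counts``: histogram over support 0..L-1 (tail implicit).
    ``probabilities``: matching pmf values; remaining mass goes to a tail
    bin.  Returns the p-value.
    """
    observed = np.asarray(observed_counts, dtype=float)
    probs = np.asarray(probabilities, dtype=float)
    n = observed.sum()
    tail_prob = max(1.0 - probs.sum(), 0.0)
    obs = list(observed) + [0.0]
    exp = list(probs * n) + [tail_prob * n]

    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if pooled_obs:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    pooled_exp = np.asarray(pooled_exp)
    pooled_exp *= np.sum(pooled_obs) / pooled_exp.sum()
    return chisquare(pooled_obs, pooled_exp).pvalue


def allocation_class_multiplicity(n: int, m) -> float:
    """Combinatorial weight turning the per-allocation probability into the
    probability of the (k, sorted m) class:

        prod_j C(n, m_j) / prod_v (multiplicity of value v in m)!

    Derived by counting ordered tuples of sample-subsets with the given
    size multiset, divided by k! (identically-filled features are
    indistinguishable).
    """
    weight = 1.0
    for mj in m:
        weight *= math.comb(n, mj)
    for mult in Counter(m).values():
        weight /= math.factorial(mult)
    return weight
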