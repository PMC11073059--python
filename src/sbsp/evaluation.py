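"""Accuracy metric, replicate subsampling experiments, coverage calibration.

The accuracy of an estimate u_hat against a truth u_true is the clipped
percent deviation 1 - min(|u_true - u_hat| / u_true, 1): it is 1 for a
perfect estimate and hits 0 once the estimate at least doubles the truth.
When u_true = 0 the ratio is undefined; by continuity with the clipping
rule the accuracy is 1 iff the estimate is also 0, else 0 (logged when
triggered).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .efpf import fit_empirical_bayes
from .errors import DegenerateDataError
from .io import BinaryFeatureMatrix, split_rows, sufficient_stats, true_unseen
from .posterior import (
    credible_interval,
    unseen_point_estimate,
    unseen_posterior,
    unseen_prevalence_estimate,
)
from .special import SBSPParams

__all__ = ["accuracy", "replicate_experiment", "coverage_calibration"]

logger = logging.getLogger(__name__)


def accuracy(u_true, u_hat) -> float:
    if u_true < 0 or u_hat < 0:
        raise ValueError("accuracy requires non-negative inputs")
    if u_true == 0:
        logger.info("accuracy with u_true = 0: returning %d", int(u_hat == 0))
        return 1.0 if u_hat == 0 else 0.0
    return 1.0 - min(abs(u_true - u_hat) / u_true, 1.0)


def _rep_seeds(seed: int, n_reps: int):
    return np.random.SeedSequence(seed).spawn(n_reps)


def replicate_experiment(
    matrix: BinaryFeatureMatrix,
    n_train: int,
    n_reps: int,
    r_list=(),
    seed: int = 0,
    params: SBSPParams | None = None,
) -> pd.DataFrame:
    """Subsample, fit, extrapolate, and score accuracy, n_reps times.

    Each replicate draws a uniform train/test row split, fits the
    hyperparameters on the train rows by empirical Bayes (or uses ``params``
    when supplied), predicts the unseen counts for M = n_test, and scores
    them against the held-out truth.  Per-replicate fit failures (e.g. a
    train split with no features) are recorded in the ``error`` column, not
    raised.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rows = []
    for rep, child in enumerate(_rep_seeds(seed, n_reps)):
        rng = np.random.default_rng(child)
        train, test = split_rows(matrix, n_train, rng)
        stats = sufficient_stats(train)
        m_extra = test.n_samples
        record: dict = {
            "rep": rep,
            "n_train": n_train,
            "M": m_extra,
            "k_train": stats.k,
            "error": None,
        }
        try:
            if params is None:
                fitted, _ = fit_empirical_bayes(stats)
            else:
                fitted = params
            record.update(sigma=fitted.sigma, c=fitted.c, beta=fitted.beta)
            u_hat = unseen_point_estimate(fitted, stats, m_extra)
            u_true = true_unseen(train, test)
            record.update(
                u_true=u_true, u_hat=u_hat, accuracy=accuracy(u_true, u_hat)
            )
            for r in r_list:
                ur_hat = unseen_prevalence_estimate(
                    fitted, stats, m_extra, r, allow_degenerate=True
                )
                ur_true = true_unseen(train, test, r=r)
                record[f"u_true_r{r}"] = ur_true
                record[f"u_hat_r{r}"] = ur_hat
                record[f"accuracy_r{r}"] = accuracy(ur_true, ur_hat)
        except DegenerateDataError as exc:
            record["error"] = str(exc)
        rows.append(record)
    return pd.DataFrame.from_records(rows)


def coverage_calibration(
    matrix: BinaryFeatureMatrix,
    n_train: int,
    n_reps: int,
    levels,
    seed: int = 0,
    params: SBSPParams | None = None,
    shift_by_k: bool = True,
) -> dict:
    """Empirical coverage of credible intervals across subsampling replicates.

    Per replicate: split the rows, fit on the train subset (once per
    replicate, reused across levels; or use ``params``), build the level
    credible interval for the unseen count with M = n_test, shift it by the
    train K so both sides count total distinct features, and score whether
    the total distinct-feature count of the full matrix falls inside.  With
    ``shift_by_k=False`` the raw interval is scored against the held-out
    unseen count instead (sensitivity variant).

    Replicates whose fit fails (k = 0 train split) are excluded from the
    denominator; the exclusion count is logged.
    """
    levels = [float(a) for a in levels]
    if any(not 0.0 < a < 1.0 for a in levels):
        raise ValueError("levels must lie strictly in (0, 1)")
    k_total = matrix.n_features
    hits = {a: 0 for a in levels}
    n_used = 0
    n_excluded = 0
    for child in _rep_seeds(seed, n_reps):
        rng = np.random.default_rng(child)
        train, test = split_rows(matrix, n_train, rng)
        stats = sufficient_stats(train)
        try:
            fitted = params if params is not None else fit_empirical_bayes(stats)[0]
        except DegenerateDataError:
            n_excluded += 1
            continue
        law = unseen_posterior(fitted, stats, test.n_samples)
        if shift_by_k:
            target = k_total
            shift = stats.k
        else:
            target = true_unseen(train, test)
            shift = 0
        for a in levels:
            ci = credible_interval(law, a)
            if ci.low + shift <= target <= ci.high + shift:
                hits[a] += 1
        n_used += 1
    if n_excluded:
        logger.info("coverage: excluded %d replicates with degenerate fits", n_excluded)
    if n_used == 0:
        raise DegenerateDataError("all replicates had degenerate train splits")
    return {a: hits[a] / n_used for a in levels}
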