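"""Resampling-based inference: bootstrap, BH-FDR, permutation, paired t.

Conventions follow the analyses the package implements: one-sided tests
against a positive alternative by default (two-sided available via flag),
and a ``(x+1)/(n+1)`` continuity correction on every Monte-Carlo p-value
so that p is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceResult",
    "bootstrap_mean_test",
    "fdr_bh",
    "paired_permutation",
    "paired_t_bonferroni",
]


@dataclass
class SignificanceResult:
    """Per-lag p-values and significance flags with their provenance."""

    pvals: np.ndarray
    significant: np.ndarray
    procedure: str  # bootstrap | perm | t
    correction: str  # e.g. "fdr q=0.01" | "bonferroni alpha=0.05"
    n_resamples: int | None = None
    seed: int | None = None


def bootstrap_mean_test(
    per_word_scores,
    n_boot: int = 5000,
    seed: int = 0,
    one_sided: bool = True,
) -> float:
    """Bootstrap test of "the mean score is zero" against a positive mean.

    Scores are resampled across words with replacement ``n_boot`` times;
    the p-value is the continuity-corrected proportion of bootstrap means
    at or below zero (doubled-and-capped symmetric version when
    ``one_sided=False``).
    """
    scores = np.asarray(per_word_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(n_boot, scores.size))
    boot_means = scores[idx].mean(axis=1)
    if np.ptp(scores) == 0:
        logger.info("bootstrap_mean_test: degenerate (all-identical) scores")
    p_low = (1 + np.sum(boot_means <= 0.0)) / (n_boot + 1)
    if one_sided:
        return float(p_low)
    p_high = (1 + np.sum(boot_means >= 0.0)) / (n_boot + 1)
    return float(min(1.0, 2 * min(p_low, p_high)))


def fdr_bh(pvals, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up over all tests; returns boolean flags."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def paired_permutation(
    diffs,
    n_perm: int = 10000,
    seed: int = 0,
    one_sided: bool = True,
) -> float:
    """Sign-flip permutation test on per-word paired differences.

    The observed mean difference is compared to the null distribution of
    means under random sign flips; p is the continuity-corrected
    proportion of null means at or above the observed mean (absolute
    values when two-sided).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least 2 differences")
    rng = np.random.default_rng(seed)
    obs = diffs.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    null = (signs * diffs).mean(axis=1)
    if one_sided:
        p = (1 + np.sum(null >= obs)) / (n_perm + 1)
    else:
        p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1)
    return float(p)


def paired_t_bonferroni(
    a,
    b,
    n_lags: int | None = None,
    alpha: float = 0.05,
    one_sided: bool = False,
) -> SignificanceResult:
    """Per-lag paired t-test on a - b with Bonferroni-corrected flags.

    ``a`` and ``b`` are word-aligned score arrays of shape
    ``(n_lags, n_words)`` (or 1-D for a single lag); the significance
    level is divided by the number of lags tested (override with
    ``n_lags`` when flagging a subset of a larger family).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("a and b must be aligned (same shape)")
    m = n_lags if n_lags is not None else a.shape[0]
    pvals = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        d = a[i] - b[i]
        if np.ptp(d) == 0:
            if d.mean() == 0:
                pvals[i] = 1.0
            else:
                logger.info("paired_t: zero-variance nonzero difference at row %d", i)
                pvals[i] = 0.0
            continue
        alt = "greater" if one_sided else "two-sided"
        pvals[i] = sps.ttest_rel(a[i], b[i], alternative=alt).pvalue
    flags = pvals <= alpha / m
    return SignificanceResult(
        pvals=pvals,
        significant=flags,
        procedure="t",
        correction=f"bonferroni alpha={alpha}/m={m}",
    )
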