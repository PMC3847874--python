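"""Mutual-information estimation and permutation-calibrated significance.

The estimator is rank-based: both variables are replaced by their average
ranks (a copula transform), discretized into ``ceil(1 + log2 n)``
equal-frequency bins, and plug-in MI is computed from the joint histogram
with a Miller-Madow bias correction, floored at zero.  Rank invariance makes
the estimate identical under any strictly monotone transform of either
margin, and it also makes the null distribution of the estimate depend only
on the sample size and tie structure — which is what lets the significance
threshold be calibrated by permuting ranks alone.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy import stats

from .types import MIThreshold, PrognetError

logger = logging.getLogger(__name__)


def n_bins(n: int) -> int:
    """Sturges-style bin count used throughout: ceil(1 + log2 n)."""
    return int(math.ceil(1.0 + math.log2(n)))


def rank_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin index per observation via average ranks."""
    r = stats.rankdata(x, method="average")  # in [1, n]
    n = len(x)
    idx = np.minimum(((r - 0.5) / n * bins).astype(int), bins - 1)
    return idx


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, bins: int, n: int) -> float:
    joint = np.bincount(bx * bins + by, minlength=bins * bins).reshape(bins, bins)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    pj = joint[nz] / n
    outer = np.outer(px, py)[nz] / (n * n)
    mi = float(np.sum(pj * np.log(pj / outer)))
    # Miller-Madow: H_mm = H_ml + (K-1)/(2n) per entropy term
    kx = int(np.count_nonzero(px))
    ky = int(np.count_nonzero(py))
    kxy = int(np.count_nonzero(joint))
    mi += (kx + ky - kxy - 1) / (2.0 * n)
    return max(mi, 0.0)


def estimate_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information between two samples, in nats.

    Symmetric, non-negative, and invariant under strictly monotone transforms
    of either argument.  A constant input carries no information; it yields 0
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PrognetError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 8:
        raise PrognetError(f"need at least 8 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PrognetError("non-finite values in MI input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector in MI estimate; returning 0", stacklevel=2)
        return 0.0
    bins = n_bins(n)
    bx, by = rank_bins(x, bins), rank_bins(y, bins)
    # canonical argument order so estimate_mi(x, y) == estimate_mi(y, x)
    # bit-for-bit (the joint histogram is transposed otherwise and float
    # summation order would differ in the last ulp)
    if tuple(bx) > tuple(by):
        bx, by = by, bx
    return _mi_from_bins(bx, by, bins, n)


def _null_sample(
    n: int,
    n_perm: int,
    rng: np.random.Generator,
    resample_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Null MI draws: estimator applied to independent rank permutations.

    When ``resample_idx`` is given (a bootstrap resampling of 0..n-1), the
    same duplication is applied to both independent vectors before
    estimating — duplicated sample pairs carry genuine joint information
    even under independence, so a bootstrap replicate needs a null with the
    identical tie structure.
    """
    bins = n_bins(n)
    base = np.arange(n, dtype=float)
    out = np.empty(n_perm)
    if resample_idx is None:
        bx = rank_bins(base, bins)
        for i in range(n_perm):
            out[i] = _mi_from_bins(bx, rng.permutation(bx), bins, n)
    else:
        m = len(resample_idx)
        bins_m = n_bins(m)
        bx = rank_bins(base[resample_idx], bins_m)
        for i in range(n_perm):
            y = rng.permutation(n).astype(float)[resample_idx]
            out[i] = _mi_from_bins(bx, rank_bins(y, bins_m), bins_m, m)
    return out


def mi_threshold(
    n_samples: int,
    n_tests: int,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
    *,
    resample_idx: np.ndarray | None = None,
) -> MIThreshold:
    """Bonferroni MI threshold from a permutation null with exponential tail fit.

    Builds ``n_perm`` null MI values by permuting one variable, fits the
    right tail ln P(MI > t) ~ a - b t on the upper 5% of the null sample,
    and solves the fitted tail for the familywise level ``alpha / n_tests``.
    ``resample_idx`` recalibrates the null for a bootstrap replicate with
    that resampling's tie structure.
    """
    if n_tests < 1 or not (0 < alpha < 1):
        raise PrognetError("need n_tests >= 1 and alpha in (0,1)")
    rng = np.random.default_rng(seed)
    null = np.sort(_null_sample(n_samples, n_perm, rng, resample_idx))
    k = max(int(math.ceil(0.05 * n_perm)), 10)
    tail = null[-k:]
    # exceedance probability just above each tail point
    exceed = (n_perm - (n_perm - k + np.arange(k)) - 1 + 0.5) / n_perm
    t = tail
    ln_p = np.log(exceed)
    slope, intercept = np.polyfit(t, ln_p, 1)
    b = -slope
    a = intercept
    if b <= 0:
        raise PrognetError(
            "degenerate null tail fit (non-decaying tail); increase n_perm"
        )
    target = alpha / n_tests
    threshold = (a - math.log(target)) / b
    # never threshold below the empirical null quantile for the same level
    emp_q = float(np.quantile(null, 1 - min(target, 1.0))) if target > 1 / n_perm else None
    if emp_q is not None:
        threshold = max(threshold, emp_q)
    return MIThreshold(
        alpha=alpha,
        n_tests=n_tests,
        threshold_mi=float(threshold),
        null_tail_params=(float(a), float(b)),
        n_samples=n_samples,
        n_perm=n_perm,
    )
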