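"""Resampling statistics for field-level fluorescence comparisons.

Implements the comparison protocol used for severing and immunostaining
experiments: per-field mean gray values (MGVs) from two conditions are
compared with (i) a two-sided Mann-Whitney U test, (ii) a bootstrap of
the difference of means whose middle-95% interval must exclude zero to
call a significant increase, and (iii) a ratio of means with a standard
error propagated from Gaussian fits to each group's bootstrapped mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BootstrapDiff",
    "RatioOfMeans",
    "bootstrap_diff_means",
    "ratio_of_means_bootstrap",
    "rank_sum_test",
]


def _as_samples(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"sample group '{name}' is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample group '{name}' contains non-finite values")
    return arr


@dataclass(frozen=True)
class BootstrapDiff:
    mean_difference: float
    interval_low: float
    interval_high: float
    n_resamples: int

    @property
    def significant_positive(self) -> bool:
        """True when the middle-95% interval excludes zero from below."""
        return self.interval_low > 0.0


@dataclass(frozen=True)
class RatioOfMeans:
    ratio: float
    standard_error: float


def bootstrap_diff_means(
    a, b, n_resamples: int = 5000, seed: int | np.random.Generator = 0
) -> BootstrapDiff:
    """Bootstrap the difference of group means, mean(a) - mean(b).

    Each group is resampled with replacement at its own size
    ``n_resamples`` times; the returned interval is the empirical middle
    95% (2.5th..97.5th percentiles) of the resampled differences.
    """
    a = _as_samples(a, "a")
    b = _as_samples(b, "b")
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    ra = rng.choice(a, size=(n_resamples, a.size), replace=True).mean(axis=1)
    rb = rng.choice(b, size=(n_resamples, b.size), replace=True).mean(axis=1)
    diffs = ra - rb
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapDiff(
        mean_difference=float(a.mean() - b.mean()),
        interval_low=float(lo),
        interval_high=float(hi),
        n_resamples=int(n_resamples),
    )


def ratio_of_means_bootstrap(
    a, b, n_resamples: int = 5000, seed: int | np.random.Generator = 0
) -> RatioOfMeans:
    """Ratio of group means with a propagated bootstrap standard error.

    Each group's mean is bootstrapped and the resulting distribution fit
    to a Gaussian (its sample mean and standard deviation); the ratio
    r = mean(a)/mean(b) gets the first-order propagated error
    r * sqrt((sd_a/mu_a)**2 + (sd_b/mu_b)**2).
    """
    a = _as_samples(a, "a")
    b = _as_samples(b, "b")
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    ra = rng.choice(a, size=(n_resamples, a.size), replace=True).mean(axis=1)
    rb = rng.choice(b, size=(n_resamples, b.size), replace=True).mean(axis=1)
    mu_a, sd_a = sps.norm.fit(ra)
    mu_b, sd_b = sps.norm.fit(rb)
    if abs(b.mean()) < 1e-300 or abs(mu_b) < 1e-300:
        raise ValueError("denominator group mean is zero; ratio undefined")
    r = float(a.mean() / b.mean())
    se = abs(r) * float(np.hypot(sd_a / mu_a, sd_b / mu_b))
    return RatioOfMeans(ratio=r, standard_error=se)


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when the combined sample size is <= 12 and the
    pooled data carry no ties, and the tie-corrected normal approximation
    (with continuity correction) otherwise.  Returns (U of group a,
    two-sided p-value).
    """
    a = _as_samples(a, "a")
    b = _as_samples(b, "b")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) != len(pooled)
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
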