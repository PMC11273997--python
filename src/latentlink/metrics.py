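"""Score-recovery and reconstruction metrics.

MAE and RMSE between true and estimated factor scores, the pooled
explained variance of item reconstruction, and numeric density summaries
(moments, a Kolmogorov-Smirnov distance to N(0,1), and a dip-style
unimodality flag) that replace the original density figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RecoveryReport",
    "score_recovery",
    "explained_variance",
    "explained_variance_per_item",
    "density_summary",
    "unimodality_dip",
    "dip_test",
]


@dataclass(frozen=True)
class DensitySummary:
    mean: float
    sd: float
    skew: float
    excess_kurtosis: float
    ks_vs_standard_normal: float
    dip: float | None = None
    bimodal: bool | None = None


@dataclass(frozen=True)
class RecoveryReport:
    """MAE/RMSE of factor-score recovery plus reconstruction quality."""

    mae: float
    rmse: float
    per_factor: tuple[tuple[float, float], ...]  # (mae, rmse) per factor
    explained_variance: float | None = None
    explained_variance_per_item: tuple[float, ...] | None = None
    density: DensitySummary | None = None


def score_recovery(
    true_scores: np.ndarray,
    est_scores: np.ndarray,
    **extra,
) -> RecoveryReport:
    """MAE and RMSE per factor and averaged across factors.

    ``est_scores`` must already be aligned (sign/permutation) to the truth.
    """
    t = np.atleast_2d(np.asarray(true_scores, dtype=float).T).T
    e = np.atleast_2d(np.asarray(est_scores, dtype=float).T).T
    if t.shape != e.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {e.shape}")
    err = t - e
    per_factor = tuple(
        (float(np.mean(np.abs(c))), float(np.sqrt(np.mean(c**2)))) for c in err.T
    )
    mae = float(np.mean([m for m, _ in per_factor]))
    rmse = float(np.mean([r for _, r in per_factor]))
    return RecoveryReport(mae=mae, rmse=rmse, per_factor=per_factor, **extra)


def explained_variance(observed: np.ndarray, reconstructed: np.ndarray) -> float:
    """Pooled explained variance ``1 - sum (x - xhat)^2 / sum (x - xbar_j)^2``.

    Residual and total sums of squares are pooled over all items before the
    ratio is taken; column means are the per-item means of the observed data.
    """
    x = np.asarray(observed, dtype=float)
    xh = np.asarray(reconstructed, dtype=float)
    if x.shape != xh.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xh.shape}")
    tss = float(np.sum((x - x.mean(axis=0)) ** 2))
    if tss == 0:
        raise ValueError("observed data has zero total variance")
    rss = float(np.sum((x - xh) ** 2))
    return 1.0 - rss / tss


def explained_variance_per_item(
    observed: np.ndarray, reconstructed: np.ndarray
) -> np.ndarray:
    """Per-item R-squared of the reconstruction (secondary convention)."""
    x = np.asarray(observed, dtype=float)
    xh = np.asarray(reconstructed, dtype=float)
    tss = np.sum((x - x.mean(axis=0)) ** 2, axis=0)
    if np.any(tss == 0):
        raise ValueError("an item has zero variance")
    rss = np.sum((x - xh) ** 2, axis=0)
    return 1.0 - rss / tss


# ---------------------------------------------------------------------------
# density summaries


def density_summary(
    scores: np.ndarray, dip_boot: int = 100, seed: int = 0
) -> DensitySummary:
    """Numeric stand-in for a score-density plot.

    Moments, the one-sample KS distance to N(0,1), and (when ``dip_boot``
    is positive) a Monte-Carlo calibrated unimodality (dip) flag.
    """
    v = np.asarray(scores, dtype=float).ravel()
    if dip_boot > 0:
        d, p = dip_test(v, n_boot=dip_boot, seed=seed)
    else:
        d, p = None, None
    return DensitySummary(
        mean=float(np.mean(v)),
        sd=float(np.std(v, ddof=1)),
        skew=float(stats.skew(v)),
        excess_kurtosis=float(stats.kurtosis(v)),
        ks_vs_standard_normal=float(stats.kstest(v, "norm").statistic),
        dip=d,
        bimodal=None if p is None else bool(p < 0.05),
    )


def _prefix_minorant_gaps(x: np.ndarray, f: np.ndarray, k: int) -> float:
    """Max gap between the ECDF and its convex minorant on points [0..k]."""
    # Andrew-style lower hull of the points (x_i, f_i), i <= k
    hull: list[int] = [0]
    for i in range(1, k + 1):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b if it lies on/above segment a->i
            if (f[b] - f[a]) * (x[i] - x[a]) >= (f[i] - f[a]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    c = np.interp(x[: k + 1], x[hull], f[hull])
    return float(np.max(f[: k + 1] - c))


def unimodality_dip(values: np.ndarray) -> float:
    """Dip-style departure of a sample from unimodality.

    For a candidate mode position k, the empirical CDF is approximated by the
    closest function that is convex to the left of the mode and concave to
    the right; the deviation is half the larger of the two envelope gaps.
    The statistic is the minimum deviation over mode positions, found by
    bisection (the left gap is nondecreasing in k and the right gap
    nonincreasing).  Large values indicate multimodality; the statistic is
    calibrated by Monte Carlo in :func:`dip_test`.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = v.size
    if n < 4:
        return 0.0
    f = (np.arange(1, n + 1) - 0.5) / n

    def left_gap(k: int) -> float:
        return _prefix_minorant_gaps(v, f, k)

    def right_gap(k: int) -> float:
        # concave majorant on [k..n-1] == convex minorant of the reversed,
        # negated ECDF
        return _prefix_minorant_gaps(-v[::-1], -f[::-1], n - 1 - k)

    lo, hi = 0, n - 1
    while hi - lo > 2:
        mid = (lo + hi) // 2
        if left_gap(mid) < right_gap(mid):
            lo = mid
        else:
            hi = mid
    best = min(
        max(left_gap(k), right_gap(k)) for k in range(lo, hi + 1)
    )
    return 0.5 * float(best)


def dip_test(
    values: np.ndarray, n_boot: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Unimodality dip with a Monte-Carlo p-value under the uniform null.

    Returns ``(dip, p)``; small p flags multimodality.  The uniform null is
    the standard calibration reference for dip statistics (it is the least
    favourable unimodal distribution).
    """
    v = np.asarray(values, dtype=float).ravel()
    d = unimodality_dip(v)
    rng = np.random.default_rng(seed)
    null = np.array(
        [unimodality_dip(rng.uniform(size=v.size)) for _ in range(n_boot)]
    )
    p = float((np.sum(null >= d) + 1) / (n_boot + 1))
    return d, p
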