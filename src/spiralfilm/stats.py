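"""Exact Wilcoxon signed-rank test for small paired samples.

Plane-by-plane and grid-size pass-rate comparisons involve on the order
of ten paired values, where the normal approximation to the signed-rank
statistic is poor.  The p-value here is exact: under the null every
sign assignment of the ranked absolute differences is equally likely,
and the distribution of the positive rank sum is enumerated over all
2**n assignments (dynamic programming over the rank-sum distribution,
equivalent to the full enumeration and feasible to n = 25).  Ties get
mid-ranks; zero differences are dropped before ranking (Wilcoxon's
original treatment); the two-sided p doubles the smaller tail, capped
at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["PairedSample", "WilcoxonResult", "wilcoxon_exact", "compare_conditions"]


@dataclass(frozen=True)
class PairedSample:
    """Paired differences (e.g. plan-by-plan pass-rate differences, %)."""

    differences: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.differences) < 1:
            raise ValueError("need at least one difference")
        if not np.all(np.isfinite(self.differences)):
            raise ValueError("differences must be finite")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min of positive / negative rank sums
    p_value: float  # two-sided, exact
    n_nonzero: int


def _rank_sum_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Exact null distribution of twice the positive rank sum.

    ``ranks2`` are the (mid-)ranks doubled to integers.  Returns counts
    over all 2**n sign assignments indexed by the doubled rank sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def wilcoxon_exact(sample: PairedSample | list | np.ndarray) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test.

    Returns W = min(positive, negative rank sum) with mid-ranks for
    tied |differences| and the exact two-sided p-value
    ``min(1, 2 * min(P(W+ <= w+), P(W+ >= w+)))``.  If every difference
    is zero, p = 1.0 with a warning.
    """
    if not isinstance(sample, PairedSample):
        sample = PairedSample(tuple(float(x) for x in np.ravel(sample)))
    d = np.asarray(sample.differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_nonzero=0)
    ranks = rankdata(np.abs(d))  # mid-ranks for ties
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    ranks2 = np.round(2.0 * ranks).astype(int)
    counts = _rank_sum_distribution(ranks2)
    total = counts.sum()  # == 2**n
    w2 = int(round(2.0 * w_pos))
    p_lo = counts[: w2 + 1].sum() / total
    p_hi = counts[w2:].sum() / total
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return WilcoxonResult(
        statistic=min(w_pos, w_neg), p_value=p, n_nonzero=int(d.size)
    )


def compare_conditions(a, b, alpha: float = 0.05) -> dict:
    """Paired comparison of pass rates under two conditions.

    ``a`` and ``b`` are equal-length lists of percentages paired by
    plan.  Reports per-pair differences (b - a), mean/max/min/sample-SD
    summaries of each condition, the exact Wilcoxon p and a
    significance flag at the given alpha.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("conditions must be equal-length 1D paired samples")

    def summary(x):
        return {
            "mean": float(x.mean()),
            "max": float(x.max()),
            "min": float(x.min()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        }

    diffs = b - a
    res = wilcoxon_exact(diffs)
    return {
        "n_pairs": int(a.size),
        "differences": diffs.tolist(),
        "condition_a": summary(a),
        "condition_b": summary(b),
        "wilcoxon_w": res.statistic,
        "p_value": res.p_value,
        "significant": bool(res.p_value < alpha),
        "alpha": alpha,
    }
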