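"""Exact power and sample size for the two-sided paired t-test.

The study design compares two primary outcomes within subject, so the
planning test is a paired t at a per-comparison two-sided level
``alpha`` (0.05 pre-split over two primaries gives 0.025).  With n
pairs and a standardized effect d (mean change over SD of change), the
test statistic under the alternative is noncentral t with n - 1 degrees
of freedom and noncentrality d*sqrt(n); power follows in closed form
from its distribution function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PowerQuery", "paired_t_power", "solve_n"]


@dataclass(frozen=True)
class PowerQuery:
    n: int
    effect_size: float
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 pairs")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")


def paired_t_power(query: PowerQuery | None = None, *, n: int | None = None,
                   effect_size: float | None = None, alpha: float = 0.025) -> float:
    """P(two-sided paired t rejects) at the given n, effect size, alpha.

    ``power = P(|T'| > t_{1-alpha/2, n-1})`` with ``T'`` noncentral t,
    df = n - 1, noncentrality ``d * sqrt(n)``.  With d = 0 this equals
    alpha (the size of the test).
    """
    q = query if query is not None else PowerQuery(n, effect_size, alpha)
    df = q.n - 1
    tcrit = sps.t.ppf(1 - q.alpha / 2, df)
    nc = q.effect_size * np.sqrt(q.n)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def solve_n(target_power: float, effect_size: float, alpha: float = 0.025,
            n_max: int = 1_000_000) -> int:
    """Smallest number of pairs whose paired-t power reaches the target."""
    if not 0 < target_power < 1:
        raise ValueError("target power must be in (0, 1)")
    if effect_size == 0 and target_power > alpha:
        raise ValueError("unreachable: zero effect size cannot exceed the test size")
    lo, hi = 2, 2
    while paired_t_power(PowerQuery(hi, effect_size, alpha)) < target_power:
        lo = hi + 1
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power not reached by n = {n_max}")
    # power is increasing in n: binary search the first n meeting the target
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_t_power(PowerQuery(mid, effect_size, alpha)) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo
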