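"""Closed-form power for Mendelian randomization with a continuous outcome.

Normal-approximation power of the two-sided IV test: the noncentrality of the
causal z statistic is z* = sqrt(n * r2_gx) * beta_std, where ``r2_gx`` is the
variance share of the exposure explained by the instrument and ``beta_std``
the causal effect per SD of exposure in SD-outcome units; power is
1 - Phi(z_{1-a/2} - z*) + Phi(-z_{1-a/2} - z*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerQuery", "mr_power"]


@dataclass(frozen=True)
class PowerQuery:
    n: int
    r2_gx: float
    beta_std: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.r2_gx < 1.0:
            raise ValueError("r2_gx must lie in (0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


def mr_power(n: int, r2_gx: float, beta_std: float, alpha: float = 0.05) -> float:
    """Power of the IV test of a causal effect on a continuous outcome."""
    q = PowerQuery(n=n, r2_gx=r2_gx, beta_std=beta_std, alpha=alpha)
    if q.alpha == 1.0:
        return 1.0
    z_crit = stats.norm.ppf(1 - q.alpha / 2)
    ncp = np.sqrt(q.n * q.r2_gx) * q.beta_std
    return float(stats.norm.sf(z_crit - ncp) + stats.norm.cdf(-z_crit - ncp))
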