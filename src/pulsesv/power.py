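"""Matched-pairs t-test power analysis via the noncentral t distribution.

Implements the standard a-priori sample-size computation for "difference
between two dependent means": given a standardized effect size dz, the power
at sample size n is the probability that a noncentral-t variate with
df = n − 1 and noncentrality dz·√n exceeds the central-t critical value.
Both rejection tails are included for the two-tailed test (the lower-tail
contribution is negligible at moderate effect sizes but kept for exactness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .types import ValidationError

__all__ = ["PowerSpec", "pooled_effect_size", "paired_t_power", "min_sample_size"]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a matched-pairs power computation."""

    dz: float
    alpha: float = 0.05
    power: float = 0.95
    tails: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < self.power < 1):
            raise ValidationError("need 0 < alpha < power < 1")
        if self.dz <= 0:
            raise ValidationError("effect size dz must be positive")
        if self.tails not in (1, 2):
            raise ValidationError("tails must be 1 or 2")


def pooled_effect_size(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """dz = |mean1 − mean2| / sqrt((sd1² + sd2²)/2).

    Standardized difference between two summarised measurement conditions,
    pooling the two SDs by root mean square.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    return abs(mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)


def paired_t_power(n: int, dz: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of a paired t-test at sample size n (pairs).

    power = P(T' > t_crit) [+ P(T' < −t_crit) for two tails], with T'
    noncentral t, df = n − 1, noncentrality dz·√n, and t_crit the
    (1 − α/tails) quantile of the central t.
    """
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    df = n - 1
    nc = dz * math.sqrt(n)
    t_crit = stats.t.ppf(1.0 - alpha / tails, df)
    power = float(stats.nct.sf(t_crit, df, nc))
    if tails == 2:
        power += float(stats.nct.cdf(-t_crit, df, nc))
    return power


def min_sample_size(
    dz: float,
    alpha: float = 0.05,
    power: float = 0.95,
    tails: int = 2,
    n_max: int = 100_000,
) -> int:
    """Smallest n (pairs) with paired_t_power(n) ≥ the target power."""
    spec = PowerSpec(dz=dz, alpha=alpha, power=power, tails=tails)  # validates
    for n in range(2, n_max + 1):
        if paired_t_power(n, spec.dz, spec.alpha, spec.tails) >= spec.power:
            return n
    raise ValidationError(
        f"no n ≤ {n_max} reaches power {power} at dz={dz}; effect too small"
    )
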