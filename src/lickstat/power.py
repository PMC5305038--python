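"""Sample-size calculation for a hypothetical two-arm treatment study.

The detectable difference is a stated fraction of the control-vs-lesion
gap (e.g. a 50% or 75% recovery toward control performance), the common SD
of both hypothetical arms is the lesion group's SD, and the test is a
two-sided two-sample t.  The group size is solved on the noncentral-t
power function and rounded up; the normal-approximation closed form is
exposed as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "required_n", "power_at_n", "normal_approximation_n"]


@dataclass(frozen=True)
class PowerSpec:
    control_mean: float
    mcao_mean: float
    mcao_sd: float
    improvement_fraction: float = 0.5
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.mcao_sd <= 0:
            raise ValueError("mcao_sd must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if not 0 < self.improvement_fraction <= 1:
            raise ValueError("improvement_fraction must lie in (0, 1]")

    @property
    def delta(self) -> float:
        """Detectable mean difference."""
        return self.improvement_fraction * abs(self.control_mean - self.mcao_mean)


def power_at_n(n: int, effect_size: float, alpha: float) -> float:
    """Power of the two-sided pooled t test with n subjects per group.

    ``effect_size`` is delta / sd (Cohen's d for the designed difference).
    """
    if n < 2:
        return 0.0
    df = 2 * n - 2
    ncp = effect_size * math.sqrt(n / 2.0)
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    )


def normal_approximation_n(effect_size: float, alpha: float, power: float) -> int:
    """Closed-form 2 (z_{1-a/2} + z_{1-b})^2 / d^2, rounded up."""
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    return math.ceil(2.0 * (za + zb) ** 2 / effect_size**2)


def required_n(spec: PowerSpec, method: str = "nct") -> int:
    """Smallest per-group n achieving the target power.

    ``method`` selects the noncentral-t iteration (``"nct"``, default) or
    the normal approximation (``"normal"``).
    """
    delta = spec.delta
    if delta == 0:
        raise ValueError("detectable difference is zero (equal group means)")
    d = delta / spec.mcao_sd
    if method == "normal":
        return max(2, normal_approximation_n(d, spec.alpha, spec.power))
    if method != "nct":
        raise ValueError(f"unknown method {method!r}")

    n = max(2, normal_approximation_n(d, spec.alpha, spec.power) - 2)
    while power_at_n(n, d, spec.alpha) < spec.power:
        n += 1
    # The approximation start point may overshoot; walk back to the minimum.
    while n > 2 and power_at_n(n - 1, d, spec.alpha) >= spec.power:
        n -= 1
    return n
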