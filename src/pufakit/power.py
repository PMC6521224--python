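"""Two-arm power and sample-size design arithmetic.

The design scenarios this module reproduces compare mean 3-year changes
between two arms: the primary WMH scenario (placebo 7.0 +/- 5 cm^3 vs
active 3.5 +/- 5, alpha 0.05 two-tailed, 80% power), the sICAM-1 scenario
(219.19 +/- 39.12 vs 269.34 +/- 78.89 ng/mL), and the cognitive scenarios
(standardized effect 0.7 at 35 per arm).

Two methods are exposed:

* ``normal_approx`` — the closed-form design formula
  n = (z_{1-alpha/tails} + z_{power})^2 (sd1^2 + sd2^2) / delta^2, ceiled.
  For the primary scenario this gives 32.04 -> 33 per arm, the published
  design number.
* ``noncentral_t`` — exact power of the two-sample t test via the
  noncentral t distribution, iterated to the smallest n whose power meets
  the target.  For the primary scenario the exact power at n=33 is 0.7997
  (80% at the precision power statements are usually quoted at), so a
  strict power floor returns 34; both numbers are real and the methods
  note discusses the off-by-one.

Attrition arithmetic: enrolling 100 at 30% three-year attrition leaves an
expected 70 completers (35 per arm when 50 are enrolled per arm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

METHODS = ("normal_approx", "noncentral_t")


@dataclass(frozen=True)
class PowerSpec:
    delta: float
    sd1: float
    sd2: float | None = None
    alpha: float = 0.05
    target_power: float = 0.80
    tails: int = 2
    method: str = "noncentral_t"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.target_power < 1:
            raise ValueError(f"target_power must lie in (0, 1), got {self.target_power}")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.sd1 <= 0 or (self.sd2 is not None and self.sd2 <= 0):
            raise ValueError("SDs must be > 0")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


def _sds(sd1: float, sd2: float | None) -> tuple[float, float]:
    return sd1, sd1 if sd2 is None else sd2


def power_two_arm(
    n1: int,
    n2: int,
    delta: float,
    sd1: float,
    sd2: float | None = None,
    alpha: float = 0.05,
    tails: int = 2,
    method: str = "noncentral_t",
    welch: bool | None = None,
) -> float:
    """Power of the two-sample test of mean difference ``delta``.

    ``welch=None`` uses Welch-Satterthwaite df when the two SDs differ and
    pooled df otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need n >= 2 per arm, got ({n1}, {n2})")
    s1, s2 = _sds(sd1, sd2)
    se = math.sqrt(s1**2 / n1 + s2**2 / n2)
    ncp = delta / se
    if method == "normal_approx":
        z_crit = stats.norm.ppf(1 - alpha / tails)
        p = 1 - stats.norm.cdf(z_crit - ncp)
        if tails == 2:
            p += stats.norm.cdf(-z_crit - ncp)
        return float(p)
    if welch is None:
        welch = s1 != s2
    if welch:
        df = (s1**2 / n1 + s2**2 / n2) ** 2 / (
            (s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1)
        )
    else:
        df = n1 + n2 - 2
    t_crit = stats.t.ppf(1 - alpha / tails, df)
    p = 1 - stats.nct.cdf(t_crit, df, ncp)
    if tails == 2:
        p += stats.nct.cdf(-t_crit, df, ncp)
    return float(p)


def sample_size_two_arm(
    delta: float,
    sd1: float,
    sd2: float | None = None,
    alpha: float = 0.05,
    target_power: float = 0.80,
    tails: int = 2,
    method: str = "noncentral_t",
) -> int:
    """Smallest integer n per arm (1:1 allocation) meeting ``target_power``."""
    if delta == 0:
        raise ValueError("delta = 0: no finite sample size detects a null difference")
    if not 0 < alpha < 1 or not 0 < target_power < 1:
        raise ValueError("alpha and target_power must lie in (0, 1)")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    s1, s2 = _sds(sd1, sd2)
    z_a = stats.norm.ppf(1 - alpha / tails)
    z_b = stats.norm.ppf(target_power)
    n_cont = (z_a + z_b) ** 2 * (s1**2 + s2**2) / delta**2
    n_normal = max(2, math.ceil(n_cont))
    if method == "normal_approx":
        if n_cont < 2:
            warnings.warn("design is overpowered at the minimum n of 2 per arm")
        return n_normal
    # noncentral-t iteration, seeded near the normal approximation
    n = max(2, n_normal - 5)
    while power_two_arm(n, n, delta, sd1, sd2, alpha, tails, "noncentral_t") < target_power:
        n += 1
    if n == 2 and power_two_arm(2, 2, delta, sd1, sd2, alpha, tails, "noncentral_t") >= target_power:
        warnings.warn("design is overpowered at the minimum n of 2 per arm")
    return n


def attrition_adjust(n_enrolled: int, attrition_rate: float) -> tuple[float, int]:
    """Expected completers after attrition: (unrounded, nearest-int)."""
    if not 0 <= attrition_rate < 1:
        raise ValueError(f"attrition rate must lie in [0, 1), got {attrition_rate}")
    if n_enrolled < 0:
        raise ValueError("n_enrolled must be >= 0")
    expected = n_enrolled * (1 - attrition_rate)
    return expected, round(expected)


def enrollment_for_completers(n_completers: int, attrition_rate: float) -> int:
    """Smallest enrollment yielding the required expected completers (ceiled)."""
    if not 0 <= attrition_rate < 1:
        raise ValueError(f"attrition rate must lie in [0, 1), got {attrition_rate}")
    return math.ceil(n_completers / (1 - attrition_rate))


def standardized_effect(delta: float, sd1: float, sd2: float | None = None) -> float:
    """Cohen-type d: delta over the pooled SD sqrt((sd1^2 + sd2^2)/2)."""
    s1, s2 = _sds(sd1, sd2)
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be > 0")
    return delta / math.sqrt((s1**2 + s2**2) / 2)


def daily_dose_g(softgels: int = 3, epa_mg_per_gel: float = 325.0,
                 dha_mg_per_gel: float = 225.0) -> float:
    """Daily marine n-3 dose in grams (design: 3 softgels x (325 EPA + 225 DHA) mg
    = 1.65 g/day)."""
    if softgels < 0 or epa_mg_per_gel < 0 or dha_mg_per_gel < 0:
        raise ValueError("dose components must be non-negative")
    return softgels * (epa_mg_per_gel + dha_mg_per_gel) / 1000.0
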