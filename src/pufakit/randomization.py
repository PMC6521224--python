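"""Covariate-adaptive minimization randomization (Pocock-Simon marginal
method with a biased coin).

The trial balances its two arms on five prognostic factors: age in 5-year
bands (75-79, 80-84, 85-89, 90+), sex, education (3 levels), total-WMH
stratum (5-15, 15-30, >=30 cm^3) and CDR (0 / 0.5).  For each arriving
participant the rule forms, for each candidate arm, the hypothetical
post-assignment marginal counts at the participant's own factor levels and
scores the arm by

    imbalance(arm) = sum over the 5 factors of |count_active - count_placebo|

with equal factor weights.  Ties are broken by a fair coin; otherwise the
imbalance-minimizing arm is chosen with probability ``p_best`` (default
0.8).  The assignment log records factor levels, both imbalance scores, the
uniform draw, and the arm, so the whole sequence can be replayed and
verified against the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ARM_ACTIVE, ARM_PLACEBO
from .screening import age_band, wmh_stratum

FACTORS = ("age_band", "sex", "education", "wmh_stratum", "cdr")
ARMS = (ARM_ACTIVE, ARM_PLACEBO)


def factor_levels(record) -> dict:
    """Derive the five balancing-factor levels from a participant record."""
    return {
        "age_band": age_band(float(record["age"])),
        "sex": str(record["sex"]),
        "education": str(record["education"]),
        "wmh_stratum": wmh_stratum(float(record["wmh_total_cm3"])),
        "cdr": str(float(record["cdr"])),
    }


@dataclass
class RandomizationState:
    """Running marginal counts plus assignment log; must be seeded."""

    seed: int | None = None
    p_best: float = 0.8
    counts: dict = field(default_factory=dict)  # (factor, level) -> [n_active, n_placebo]
    log: list = field(default_factory=list)
    _rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("randomization state must be seeded for reproducibility")
        if not 0.5 < self.p_best <= 1.0:
            raise ValueError(f"p_best must lie in (0.5, 1], got {self.p_best}")
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)

    def marginal_count(self, factor: str, level: str, arm: str) -> int:
        pair = self.counts.get((factor, level), [0, 0])
        return pair[0] if arm == ARM_ACTIVE else pair[1]

    def arm_sizes(self) -> dict:
        sizes = {ARM_ACTIVE: 0, ARM_PLACEBO: 0}
        for entry in self.log:
            sizes[entry["arm"]] += 1
        return sizes

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log)


def _imbalance_if(state: RandomizationState, levels: dict, arm: str) -> int:
    """Total marginal imbalance if the participant were assigned to ``arm``."""
    total = 0
    for factor in FACTORS:
        pair = state.counts.get((factor, levels[factor]), [0, 0])
        a, p = pair
        if arm == ARM_ACTIVE:
            a += 1
        else:
            p += 1
        total += abs(a - p)
    return total


def assign(record, state: RandomizationState) -> str:
    """Assign one participant; updates counts and the log, returns the arm."""
    levels = factor_levels(record)
    imb = {arm: _imbalance_if(state, levels, arm) for arm in ARMS}
    u = float(state._rng.random())
    if imb[ARM_ACTIVE] == imb[ARM_PLACEBO]:
        arm = ARM_ACTIVE if u < 0.5 else ARM_PLACEBO
    else:
        best = ARM_ACTIVE if imb[ARM_ACTIVE] < imb[ARM_PLACEBO] else ARM_PLACEBO
        other = ARM_PLACEBO if best == ARM_ACTIVE else ARM_ACTIVE
        arm = best if u < state.p_best else other
    for factor in FACTORS:
        pair = state.counts.setdefault((factor, levels[factor]), [0, 0])
        pair[0 if arm == ARM_ACTIVE else 1] += 1
    state.log.append(
        {
            "id": record["id"] if "id" in record else None,
            **levels,
            "imbalance_active": imb[ARM_ACTIVE],
            "imbalance_placebo": imb[ARM_PLACEBO],
            "coin": u,
            "arm": arm,
        }
    )
    return arm


def assign_cohort(records: pd.DataFrame, state: RandomizationState) -> pd.DataFrame:
    """Assign every row in order; returns the cohort with an ``arm`` column."""
    arms = [assign(row, state) for _, row in records.iterrows()]
    out = records.copy()
    out["arm"] = arms
    return out


def simple_randomize(n: int, rng: np.random.Generator) -> list:
    """Plain 1:1 coin-flip randomization (the comparison benchmark)."""
    return [ARM_ACTIVE if rng.random() < 0.5 else ARM_PLACEBO for _ in range(n)]


def max_marginal_imbalance(state_or_counts) -> int:
    """Largest |active - placebo| over all (factor, level) marginal counts."""
    counts = (
        state_or_counts.counts
        if isinstance(state_or_counts, RandomizationState)
        else state_or_counts
    )
    if not counts:
        return 0
    return max(abs(a - p) for a, p in counts.values())


def replay(log: list, seed: int, p_best: float = 0.8) -> bool:
    """Re-run the assignment sequence from the seed and verify each logged arm."""
    state = RandomizationState(seed=seed, p_best=p_best)
    for entry in log:
        record = {
            "id": entry["id"],
            # reconstruct a record that maps to the logged factor levels
            "age": {"75-79": 77, "80-84": 82, "85-89": 87, "90+": 92}[entry["age_band"]],
            "sex": entry["sex"],
            "education": entry["education"],
            "wmh_total_cm3": {"low": 10.0, "mid": 20.0, "high": 40.0}[entry["wmh_stratum"]],
            "cdr": float(entry["cdr"]),
        }
        if assign(record, state) != entry["arm"]:
            return False
    return True
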