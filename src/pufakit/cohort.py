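"""Synthetic cohorts and longitudinal trajectories.

``generate_cohort`` draws baseline participant records whose marginal
distributions reproduce, in expectation, the enrolled population: mean age
81.1 (SD 4.4, floor 75), 60.8% female, total WMH 19.4 cm^3 (SD 16.1,
log-normal), plasma EPA 22.43 and DHA 63.20 ug/mL, MMSE 27.9 (1.7),
CDR 0 prevalence 69.6%, GDS 1.5 (1.4).  A configurable fraction of records
can be forced to violate each eligibility criterion so the screening funnel
has something to reject.

``simulate_trajectories`` generates visit-level outcomes under the analysis
model the trial pre-specifies: a linear time trend per arm plus participant
random intercept and slope plus residual noise,

    y_ij = baseline_i + delta3 * (t_ij / 3) * (1 - f * active_i)
           + b0_i + b1_i * t_ij + eps_ij

where ``delta3`` is the placebo-arm 3-year change (WMH: +7.0 cm^3) and
``f`` the proportional slope reduction in the active arm (design value
0.5, giving an active 3-year change of 3.5 cm^3).  Dropout is a constant
per-scheduled-visit hazard solved from
``(1 - h)^(#follow-up visits) = 1 - three_year_attrition`` (30% design
attrition -> 70% expected completers), and is monotone: once a visit is
missed, all later visits are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

ARM_ACTIVE = "active"
ARM_PLACEBO = "placebo"

EDUCATION_LEVELS = ("hs_or_less", "some_college", "bachelor_plus")

INELIGIBILITY_KEYS = ("age", "cdr", "mmse", "gds", "wmh", "n3", "exclusion")

IMAGING_MONTHS = (0, 12, 24, 36)
BLOOD_MONTHS = (0, 3, 6, 12, 18, 24, 30, 36)


@lru_cache(maxsize=32)
def _truncnorm_params(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Underlying (loc, scale) of a normal truncated below at ``floor`` whose
    *truncated* distribution has the requested mean and SD."""

    def resid(p):
        loc, log_scale = p
        scale = np.exp(log_scale)
        a = (floor - loc) / scale
        m, v = stats.truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal moment-matched to (mean, sd)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("log-normal moment matching needs mean > 0 and sd > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2), float(np.sqrt(sigma2))


@dataclass(frozen=True)
class CohortSpec:
    n: int
    age_mean: float = 81.1
    age_sd: float = 4.4
    age_floor: float = 75.0
    pct_female: float = 0.608
    education_probs: tuple[float, float, float] = (0.235, 0.196, 0.569)
    wmh_mean: float = 19.4
    wmh_sd: float = 16.1
    pv_fraction: float = 17.4 / 19.4  # share of total WMH that is periventricular
    epa_mean: float = 22.43
    epa_sd: float = 11.49
    dha_mean: float = 63.20
    dha_sd: float = 20.46
    mmse_mean: float = 27.9
    mmse_sd: float = 1.7
    cdr0_prob: float = 0.696
    gds_mean: float = 1.5
    gds_sd: float = 1.4
    apoe4_prob: float = 0.275
    hypertension_prob: float = 0.5
    trails_b_mean: float = 118.7
    trails_b_sd: float = 63.1
    digit_symbol_mean: float = 48.8
    digit_symbol_sd: float = 12.4
    sicam_mean: float = 269.34
    sicam_sd: float = 78.89
    ineligibility_rates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"cohort size must be positive, got n={self.n}")
        probs = (self.pct_female, self.cdr0_prob, self.apoe4_prob, self.hypertension_prob)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(not 0 <= p <= 1 for p in self.education_probs) or not np.isclose(
            sum(self.education_probs), 1.0
        ):
            raise ValueError("education_probs must be probabilities summing to 1")
        if not 0 <= self.pv_fraction <= 1:
            raise ValueError("pv_fraction must lie in [0, 1]")
        bad = set(self.ineligibility_rates) - set(INELIGIBILITY_KEYS)
        if bad:
            raise ValueError(f"unknown ineligibility keys: {sorted(bad)}")
        if any(not 0 <= r <= 1 for r in self.ineligibility_rates.values()):
            raise ValueError("ineligibility rates must lie in [0, 1]")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw ``spec.n`` participant records; reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    loc, scale = _truncnorm_params(spec.age_mean, spec.age_sd, spec.age_floor)
    a = (spec.age_floor - loc) / scale
    age = stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=n, random_state=rng)

    sex = np.where(rng.random(n) < spec.pct_female, "F", "M")
    education = rng.choice(EDUCATION_LEVELS, size=n, p=spec.education_probs)
    cdr = np.where(rng.random(n) < spec.cdr0_prob, 0.0, 0.5)

    mu, sg = _lognormal_params(spec.wmh_mean, spec.wmh_sd)
    wmh = rng.lognormal(mu, sg, size=n)
    mu, sg = _lognormal_params(spec.epa_mean, spec.epa_sd)
    epa = rng.lognormal(mu, sg, size=n)
    mu, sg = _lognormal_params(spec.dha_mean, spec.dha_sd)
    dha = rng.lognormal(mu, sg, size=n)

    mmse = np.clip(np.rint(rng.normal(spec.mmse_mean, spec.mmse_sd, n)), 0, 30).astype(int)
    gds = np.clip(np.rint(rng.normal(spec.gds_mean, spec.gds_sd, n)), 0, 15).astype(int)
    apoe4 = (rng.random(n) < spec.apoe4_prob).astype(int)
    htn = (rng.random(n) < spec.hypertension_prob).astype(int)
    trails_b = np.maximum(rng.normal(spec.trails_b_mean, spec.trails_b_sd, n), 20.0)
    digit = np.maximum(rng.normal(spec.digit_symbol_mean, spec.digit_symbol_sd, n), 0.0)
    mu, sg = _lognormal_params(spec.sicam_mean, spec.sicam_sd)
    sicam = rng.lognormal(mu, sg, size=n)

    df = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            "cdr": cdr,
            "mmse": mmse,
            "gds": gds,
            "wmh_total_cm3": wmh,
            "wmh_pv_cm3": wmh * spec.pv_fraction,
            "wmh_deep_cm3": wmh * (1 - spec.pv_fraction),
            "epa_ugml": epa,
            "dha_ugml": dha,
            "apoe4": apoe4,
            "hypertension": htn,
            "trails_b": trails_b,
            "digit_symbol": digit,
            "sicam_ngml": sicam,
            "anticoagulant_use": False,
            "other_exclusion": False,
        }
    )

    # forced violations, one Bernoulli draw per criterion per record
    rates = spec.ineligibility_rates
    def hit(key):
        r = rates.get(key, 0.0)
        return rng.random(n) < r if r > 0 else np.zeros(n, dtype=bool)

    m = hit("age")
    df.loc[m, "age"] = rng.uniform(70.0, 74.9, int(m.sum()))
    m = hit("cdr")
    df.loc[m, "cdr"] = 1.0
    m = hit("mmse")
    df.loc[m, "mmse"] = rng.integers(15, 24, int(m.sum()))
    m = hit("gds")
    df.loc[m, "gds"] = rng.integers(6, 16, int(m.sum()))
    m = hit("wmh")
    low = rng.uniform(0.5, 4.9, int(m.sum()))
    df.loc[m, "wmh_total_cm3"] = low
    df.loc[m, "wmh_pv_cm3"] = low * spec.pv_fraction
    df.loc[m, "wmh_deep_cm3"] = low * (1 - spec.pv_fraction)
    m = hit("n3")
    high = rng.uniform(115.0, 180.0, int(m.sum()))
    df.loc[m, "epa_ugml"] = high * 0.25
    df.loc[m, "dha_ugml"] = high * 0.75
    m = hit("exclusion")
    df.loc[m, "other_exclusion"] = True

    df["epa_dha_ugml"] = df["epa_ugml"] + df["dha_ugml"]
    # the two inclusion thresholds (110 ug/mL, 5.5 wt%) are made to coincide
    df["n3_wt_pct"] = df["epa_dha_ugml"] / 20.0
    return df


# --- trajectories ----------------------------------------------------------


@dataclass(frozen=True)
class OutcomeSpec:
    """Longitudinal model for one outcome: placebo 3-year change plus
    random-intercept/random-slope/residual SDs (outcome units; slope SD is
    per year)."""

    name: str
    baseline_col: str
    placebo_change_3yr: float
    random_intercept_sd: float
    random_slope_sd: float
    residual_sd: float
    months: tuple = IMAGING_MONTHS
    effect_fraction: float | None = None  # None -> TrajectorySpec global value

    def __post_init__(self) -> None:
        for nm in ("random_intercept_sd", "random_slope_sd", "residual_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        object.__setattr__(self, "months", tuple(self.months))


def default_outcomes() -> tuple[OutcomeSpec, ...]:
    # Variance splits are chosen so the implied SD of the 3-year change,
    # sqrt(9*slope_sd^2 + 2*residual_sd^2), matches the design SDs
    # (WMH 5, trails B 13, digit symbol 2).
    return (
        OutcomeSpec("wmh_total", "wmh_total_cm3", 7.0, 2.0, 1.6, 1.0, IMAGING_MONTHS),
        OutcomeSpec("sicam", "sicam_ngml", 50.15, 10.0, 10.0, 15.0, BLOOD_MONTHS),
        OutcomeSpec("trails_b", "trails_b", 12.0, 5.0, 3.9, 4.0, IMAGING_MONTHS),
        OutcomeSpec("digit_symbol", "digit_symbol", -2.25, 1.0, 0.6, 0.6, IMAGING_MONTHS),
    )


@dataclass(frozen=True)
class TrajectorySpec:
    treatment_effect_fraction: float = 0.5
    three_year_attrition: float = 0.30
    outcomes: tuple = field(default_factory=default_outcomes)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.treatment_effect_fraction <= 1:
            raise ValueError("treatment_effect_fraction must lie in [0, 1]")
        if not 0 <= self.three_year_attrition < 1:
            raise ValueError("three_year_attrition must lie in [0, 1)")
        object.__setattr__(self, "outcomes", tuple(self.outcomes))


def dropout_hazard(three_year_attrition: float, n_followups: int) -> float:
    """Constant per-visit hazard h with (1-h)^k = 1 - attrition."""
    if not 0 <= three_year_attrition < 1:
        raise ValueError("attrition must lie in [0, 1)")
    if n_followups <= 0:
        raise ValueError("need at least one follow-up visit")
    return 1.0 - (1.0 - three_year_attrition) ** (1.0 / n_followups)


def simulate_trajectories(
    cohort: pd.DataFrame,
    spec: TrajectorySpec,
    arm_assignments,
) -> pd.DataFrame:
    """Long-format visit table (one row per participant x visit x outcome).

    ``arm_assignments`` maps participant id -> "active" | "placebo".
    Missing-after-dropout rows are retained with ``observed=False`` and NaN
    values so completeness accounting stays explicit.
    """
    arms = dict(arm_assignments)
    bad = set(arms.values()) - {ARM_ACTIVE, ARM_PLACEBO}
    if bad:
        raise ValueError(f"arm labels must be 'active' or 'placebo', got {sorted(bad)}")
    missing = [pid for pid in cohort["id"] if pid not in arms]
    if missing:
        raise ValueError(f"no arm assignment for participants: {missing[:5]} ...")

    rng = np.random.default_rng(spec.seed)
    followups = sorted({m for oc in spec.outcomes for m in oc.months if m > 0})
    h = dropout_hazard(spec.three_year_attrition, len(followups))

    # participant-level dropout month (first missed scheduled follow-up)
    ids = list(cohort["id"])
    dropout_month = {}
    for pid in ids:
        dm = np.inf
        for m in followups:
            if rng.random() < h:
                dm = m
                break
        dropout_month[pid] = dm

    effects = {}
    for oc in spec.outcomes:
        f = oc.effect_fraction if oc.effect_fraction is not None else spec.treatment_effect_fraction
        effects[oc.name] = f

    rows = []
    baselines = cohort.set_index("id")
    for pid in ids:
        active = arms[pid] == ARM_ACTIVE
        for oc in spec.outcomes:
            b0 = rng.normal(0.0, oc.random_intercept_sd) if oc.random_intercept_sd > 0 else 0.0
            b1 = rng.normal(0.0, oc.random_slope_sd) if oc.random_slope_sd > 0 else 0.0
            base = float(baselines.loc[pid, oc.baseline_col])
            f = effects[oc.name]
            for m in oc.months:
                years = m / 12.0
                observed = m < dropout_month[pid] or m == 0
                eps = rng.normal(0.0, oc.residual_sd) if oc.residual_sd > 0 else 0.0
                trend = oc.placebo_change_3yr * (years / 3.0)
                if active:
                    trend *= 1.0 - f
                value = base + trend + b0 + b1 * years + eps
                rows.append(
                    (pid, arms[pid], oc.name, m, years, value if observed else np.nan, observed)
                )
    return pd.DataFrame(
        rows, columns=["id", "arm", "outcome", "month", "years", "value", "observed"]
    )
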