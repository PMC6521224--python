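"""Eligibility screening and funnel accounting.

Inclusion requires, jointly: age >= 75, CDR <= 0.5, MMSE >= 24, GDS < 6,
MRI-derived total WMH >= 5 cm^3, suboptimal blood n-3 PUFA
(EPA+DHA < 110 ug/mL, or n-3 weight percent <= 5.5), and no exclusion flag
(anticoagulant use or any other exclusion category collapsed to a boolean).
Boundary conventions: WMH >= 5 and MMSE >= 24 inclusive, GDS < 6 and
EPA+DHA < 110 strict, weight-percent <= 5.5 inclusive.

The funnel applies the criteria in a fixed order and reports, per stage,
the surviving count and the percent of the prior stage (half-up rounding to
two decimals).  Final eligibility is order-invariant; order affects only
the first-failing-criterion attribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_MIN = 75.0
CDR_MAX = 0.5
MMSE_MIN = 24
GDS_MAX_EXCLUSIVE = 6
WMH_MIN_CM3 = 5.0
N3_UGML_MAX_EXCLUSIVE = 110.0
N3_WTPCT_MAX = 5.5

REQUIRED_FIELDS = ("age", "cdr", "mmse", "gds", "wmh_total_cm3")

# (criterion name, predicate over a record) in funnel order
CRITERIA = (
    ("age", lambda r: r["age"] >= AGE_MIN),
    ("cdr", lambda r: r["cdr"] <= CDR_MAX),
    ("mmse", lambda r: r["mmse"] >= MMSE_MIN),
    ("gds", lambda r: r["gds"] < GDS_MAX_EXCLUSIVE),
    ("wmh", lambda r: r["wmh_total_cm3"] >= WMH_MIN_CM3),
    ("n3", lambda r: _n3_ok(r)),
    ("exclusion", lambda r: not (
        bool(r.get("anticoagulant_use", False)) or bool(r.get("other_exclusion", False))
    )),
)


def _n3_ok(r) -> bool:
    ugml = r.get("epa_dha_ugml", np.nan)
    wt = r.get("n3_wt_pct", np.nan)
    if np.isnan(ugml) and np.isnan(wt):
        raise KeyError("record has neither epa_dha_ugml nor n3_wt_pct")
    ok = False
    if not np.isnan(ugml):
        ok = ok or ugml < N3_UGML_MAX_EXCLUSIVE
    if not np.isnan(wt):
        ok = ok or wt <= N3_WTPCT_MAX
    return ok


def funnel_percent(numerator: int, denominator: int) -> float:
    """100*numerator/denominator, half-up rounded to 2 decimals."""
    if denominator <= 0:
        raise ValueError(f"denominator must be > 0, got {denominator}")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator must lie in [0, {denominator}], got {numerator}")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EligibilityReport:
    records: pd.DataFrame    # id, eligible, first_fail
    funnel: pd.DataFrame     # stage, surviving, pct_of_prior
    n_assessed: int
    n_invalid: int

    @property
    def eligible_ids(self) -> list:
        return list(self.records.loc[self.records["eligible"], "id"])

    @property
    def n_eligible(self) -> int:
        return int(self.records["eligible"].sum())


def _record_valid(row) -> bool:
    for f in REQUIRED_FIELDS:
        v = row.get(f, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return False
    try:
        _n3_ok(row)
    except KeyError:
        return False
    return True


def apply_eligibility(records: pd.DataFrame) -> EligibilityReport:
    """Screen a cohort table; returns per-record outcomes and the funnel.

    Records missing a required field are excluded from the funnel
    denominator with a logged warning.
    """
    rows = []
    n_invalid = 0
    for _, row in records.iterrows():
        r = row.to_dict()
        if not _record_valid(r):
            n_invalid += 1
            logger.warning("record %s missing required eligibility fields; skipped",
                           r.get("id", "<no id>"))
            continue
        first_fail = None
        for name, pred in CRITERIA:
            if not pred(r):
                first_fail = name
                break
        rows.append({"id": r.get("id"), "eligible": first_fail is None,
                     "first_fail": first_fail})
    rec = pd.DataFrame(rows, columns=["id", "eligible", "first_fail"])

    funnel_rows = []
    prior = len(rec)
    surviving = rec
    funnel_rows.append({"stage": "assessed", "surviving": prior, "pct_of_prior": 100.0})
    # recompute survival stage by stage on the validated records
    alive = np.ones(len(rec), dtype=bool)
    valid = records[[_record_valid(r.to_dict()) for _, r in records.iterrows()]].reset_index(
        drop=True
    )
    for name, pred in CRITERIA:
        passed = np.array([pred(r.to_dict()) for _, r in valid.iterrows()])
        alive_new = alive & passed
        n_prev, n_now = int(alive.sum()), int(alive_new.sum())
        funnel_rows.append({
            "stage": name,
            "surviving": n_now,
            "pct_of_prior": funnel_percent(n_now, n_prev) if n_prev > 0 else float("nan"),
        })
        alive = alive_new
    funnel = pd.DataFrame(funnel_rows, columns=["stage", "surviving", "pct_of_prior"])
    return EligibilityReport(records=rec, funnel=funnel,
                             n_assessed=len(rec), n_invalid=n_invalid)


def wmh_stratum(wmh_volume: float) -> str:
    """Balancing stratum for total WMH: [5,15) low, [15,30) mid, [30,inf) high."""
    if wmh_volume < WMH_MIN_CM3:
        raise ValueError(f"WMH {wmh_volume} cm^3 below the eligible range (>= 5)")
    if wmh_volume < 15.0:
        return "low"
    if wmh_volume < 30.0:
        return "mid"
    return "high"


def age_band(age: float) -> str:
    """5-year balancing bands with a single open top band."""
    if age < AGE_MIN:
        raise ValueError(f"age {age} below the eligible range (>= 75)")
    if age < 80:
        return "75-79"
    if age < 85:
        return "80-84"
    if age < 90:
        return "85-89"
    return "90+"
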