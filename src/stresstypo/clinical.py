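"""Clinical derivations: Friedewald LDL, weekly MET-minutes, ATP III metabolic syndrome.

These are the standard clinical conventions:

* LDL cholesterol by the Friedewald relation ``LDL = TC - HDL - TG/5``
  (mg/dL), valid only below 400 mg/dL triglycerides;
* weekly physical-activity volume in MET-minutes, one multiplier per
  intensity category (walking 3.3, moderate 4.0, vigorous 8.0 by default);
* metabolic-syndrome status by the ATP III rule: at least 3 of 5 criteria
  met is the syndrome, 1-2 is preclinical, 0 is normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import CohortTable

#: MET multipliers per intensity category (multiples of resting expenditure),
#: the standard values of the activity-questionnaire literature.
DEFAULT_MET_MULTIPLIERS: dict[str, float] = {
    "walking": 3.3,
    "moderate": 4.0,
    "vigorous": 8.0,
}

#: Triglyceride bound above which the Friedewald relation is invalid (mg/dL).
FRIEDEWALD_TG_LIMIT = 400.0


class FriedewaldInvalid(ValueError):
    """Triglycerides at or above 400 mg/dL: Friedewald LDL is undefined."""


def friedewald_ldl(total_chol: float, hdl: float, tg: float) -> float:
    """LDL cholesterol (mg/dL) from the Friedewald relation TC - HDL - TG/5.

    Raises :class:`FriedewaldInvalid` when ``tg >= 400`` mg/dL and
    ``ValueError`` on negative inputs.  The relation is linear, so it maps
    sample means to the mean of per-subject LDL values.
    """
    if min(total_chol, hdl, tg) < 0:
        raise ValueError("lipid panel values must be non-negative")
    if tg >= FRIEDEWALD_TG_LIMIT:
        raise FriedewaldInvalid(
            f"Friedewald invalid: triglycerides {tg} >= {FRIEDEWALD_TG_LIMIT} mg/dL"
        )
    return total_chol - hdl - tg / 5.0


def friedewald_ldl_batch(
    total_chol: np.ndarray, hdl: np.ndarray, tg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Friedewald LDL.

    Returns ``(ldl, valid)``; entries with ``tg >= 400`` get ``nan`` and
    ``valid=False`` instead of raising.
    """
    total_chol, hdl, tg = (np.asarray(a, dtype=float) for a in (total_chol, hdl, tg))
    valid = tg < FRIEDEWALD_TG_LIMIT
    ldl = np.where(valid, total_chol - hdl - tg / 5.0, np.nan)
    return ldl, valid


@dataclass(frozen=True)
class ActivityProfile:
    """Self-reported activity: minutes per day and days per week by intensity."""

    walking_min_per_day: float = 0.0
    moderate_min_per_day: float = 0.0
    vigorous_min_per_day: float = 0.0
    walking_days_per_week: int = 0
    moderate_days_per_week: int = 0
    vigorous_days_per_week: int = 0

    def __post_init__(self) -> None:
        mins = (
            self.walking_min_per_day,
            self.moderate_min_per_day,
            self.vigorous_min_per_day,
        )
        if min(mins) < 0:
            raise ValueError("minutes per day must be >= 0")
        days = (
            self.walking_days_per_week,
            self.moderate_days_per_week,
            self.vigorous_days_per_week,
        )
        if min(days) < 0 or max(days) > 7:
            raise ValueError("days per week must lie in 0..7")


@dataclass(frozen=True)
class MetMinutes:
    """Weekly activity volume in MET-minutes per intensity category."""

    walking: float
    moderate: float
    vigorous: float

    @property
    def total(self) -> float:
        return self.walking + self.moderate + self.vigorous


def weekly_met_minutes(
    profile: ActivityProfile,
    multipliers: dict[str, float] | None = None,
) -> MetMinutes:
    """Weekly MET-minutes: multiplier x min/day x days/week per category."""
    mult = dict(DEFAULT_MET_MULTIPLIERS if multipliers is None else multipliers)
    if min(mult.values()) <= 0:
        raise ValueError("MET multipliers must be positive")
    return MetMinutes(
        walking=mult["walking"] * profile.walking_min_per_day * profile.walking_days_per_week,
        moderate=mult["moderate"] * profile.moderate_min_per_day * profile.moderate_days_per_week,
        vigorous=mult["vigorous"] * profile.vigorous_min_per_day * profile.vigorous_days_per_week,
    )


MES_CRITERIA = ("bp", "tg", "hdl", "glucose", "waist")


@dataclass(frozen=True)
class MeSAssessment:
    """ATP III metabolic-syndrome assessment for one respondent."""

    criteria_met: frozenset
    sex: str

    @property
    def count(self) -> int:
        return len(self.criteria_met)

    @property
    def status(self) -> str:
        if self.count >= 3:
            return "mes"
        if self.count >= 1:
            return "preclinical"
        return "normal"


def assess_mes(
    sbp: float,
    dbp: float,
    tg: float,
    hdl: float,
    glucose: float,
    waist: float,
    sex: str,
) -> MeSAssessment:
    """Evaluate the five ATP III criteria.

    Criteria: blood pressure >=130/85 mmHg (systolic OR diastolic), TG >=150
    mg/dL, HDL <40 (male) / <50 (female) mg/dL, fasting glucose >100 mg/dL,
    waist >102 (male) / >88 (female) cm.  Three or more -> metabolic
    syndrome; one or two -> preclinical; none -> normal.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    if min(sbp, dbp, tg, hdl, glucose, waist) <= 0:
        raise ValueError("all clinical inputs must be positive")
    met = set()
    if sbp >= 130 or dbp >= 85:
        met.add("bp")
    if tg >= 150:
        met.add("tg")
    if hdl < (40 if sex == "male" else 50):
        met.add("hdl")
    if glucose > 100:
        met.add("glucose")
    if waist > (102 if sex == "male" else 88):
        met.add("waist")
    return MeSAssessment(criteria_met=frozenset(met), sex=sex)


def add_derived_columns(
    table: CohortTable,
    *,
    sex_column: str = "sex",
    columns: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Batch clinical derivations over a cohort.

    Adds ``ldl``, ``mes_count`` and ``mes_status`` columns computed from the
    biochemistry/anthropometric columns (default names ``total_chol``,
    ``hdl``, ``triglycerides``, ``glucose``, ``sbp``, ``dbp``, ``waist``).
    Rows with triglycerides >= 400 mg/dL get a missing LDL.  Returns a copy
    of the data frame with the derived columns appended.
    """
    names = {
        "total_chol": "total_chol",
        "hdl": "hdl",
        "triglycerides": "triglycerides",
        "glucose": "glucose",
        "sbp": "sbp",
        "dbp": "dbp",
        "waist": "waist",
    }
    if columns:
        names.update(columns)
    df = table.data.copy()
    ldl, _ = friedewald_ldl_batch(
        df[names["total_chol"]], df[names["hdl"]], df[names["triglycerides"]]
    )
    df["ldl"] = ldl
    counts, statuses = [], []
    for _, row in df.iterrows():
        a = assess_mes(
            sbp=row[names["sbp"]],
            dbp=row[names["dbp"]],
            tg=row[names["triglycerides"]],
            hdl=row[names["hdl"]],
            glucose=row[names["glucose"]],
            waist=row[names["waist"]],
            sex=row[sex_column],
        )
        counts.append(a.count)
        statuses.append(a.status)
    df["mes_count"] = counts
    df["mes_status"] = statuses
    return df
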