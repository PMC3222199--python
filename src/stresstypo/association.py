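"""Typology-covariate association: percentages, chi-square, adjusted Pearson residuals.

Each typology is cross-classified against an external categorical variable
(gender, age group, work category, illness status, metabolic-syndrome
status).  Three layers of analysis:

* descriptive -- within-typology versus total percentage distributions (total
  percentages are the count-weighted means of the within-typology ones);
* an overall Pearson chi-square test of independence of the two-way table;
* cellwise adjusted Pearson residuals (APRs),
  ``(O - E) / sqrt(E (1 - r/n)(1 - c/n))``, asymptotically standard normal
  under independence, flagged at |APR| thresholds 2, 3 and 3.5 (two-tailed
  P = .046, .003 and < .001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLDS = (2.0, 3.0, 3.5)


class AssociationError(ValueError):
    pass


@dataclass
class ContingencyTable:
    """Observed counts of typologies (rows) by categories (columns)."""

    observed: pd.DataFrame

    def __post_init__(self) -> None:
        obs = self.observed
        if (obs.to_numpy() < 0).any():
            raise AssociationError("counts must be non-negative")
        if obs.shape[0] < 2 or obs.shape[1] < 2:
            raise AssociationError("need at least a 2x2 table")

    @property
    def n(self) -> int:
        return int(self.observed.to_numpy().sum())

    @property
    def row_margins(self) -> pd.Series:
        return self.observed.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.observed.sum(axis=0)

    def expected(self) -> pd.DataFrame:
        r = self.row_margins.to_numpy(dtype=float)
        c = self.col_margins.to_numpy(dtype=float)
        if np.any(r == 0) or np.any(c == 0):
            raise AssociationError("zero margin in contingency table")
        return pd.DataFrame(
            np.outer(r, c) / self.n, index=self.observed.index, columns=self.observed.columns
        )

    @classmethod
    def from_columns(cls, assignments: pd.Series, variable: pd.Series) -> "ContingencyTable":
        obs = pd.crosstab(assignments, variable)
        return cls(observed=obs)


@dataclass
class PercentProfile:
    within_typology_pct: pd.DataFrame  # rows: typologies; cols: categories; rows sum to 100
    total_pct: pd.Series  # per category, over all subjects


def percent_profile(assignments: pd.Series, variable: pd.Series) -> PercentProfile:
    """Within-typology and total percentage distributions of a variable.

    The total percentages equal the count-weighted arithmetic means of the
    within-typology percentages.
    """
    ct = ContingencyTable.from_columns(assignments, variable)
    obs = ct.observed
    row_tot = obs.sum(axis=1)
    if (row_tot == 0).any():
        raise AssociationError("empty typology: within percentages undefined")
    within = obs.div(row_tot, axis=0) * 100.0
    total = obs.sum(axis=0) / ct.n * 100.0
    return PercentProfile(within_typology_pct=within, total_pct=total)


def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence: (statistic, df, p).

    No continuity correction is applied.
    """
    O = table.observed.to_numpy(dtype=float)
    E = table.expected().to_numpy()
    stat = float(((O - E) ** 2 / E).sum())
    r, c = O.shape
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


@dataclass
class APRMatrix:
    residuals: pd.DataFrame
    p_values: pd.DataFrame  # two-tailed standard-normal
    low_expected: pd.DataFrame  # cells with expected count < 1

    def flags(self, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
        return flag_associations(self, thresholds)


def adjusted_pearson_residuals(table: ContingencyTable) -> APRMatrix:
    """Adjusted Pearson residuals of a two-way table.

    ``APR_ij = (O_ij - E_ij) / sqrt(E_ij (1 - r_i/n)(1 - c_j/n))``; under
    independence the residuals are asymptotically standard normal, so the
    two-tailed p-value is ``2 (1 - Phi(|APR|))``.
    """
    O = table.observed.to_numpy(dtype=float)
    E = table.expected().to_numpy()
    n = table.n
    r = table.row_margins.to_numpy(dtype=float)
    c = table.col_margins.to_numpy(dtype=float)
    denom = np.sqrt(E * np.outer(1.0 - r / n, 1.0 - c / n))
    if np.any(denom == 0):
        raise AssociationError("degenerate margin: APR undefined")
    apr = (O - E) / denom
    p = 2.0 * stats.norm.sf(np.abs(apr))
    low = E < 1.0
    if low.any():
        warnings.warn("cells with expected count < 1: APR may be unreliable", RuntimeWarning)
    idx, cols = table.observed.index, table.observed.columns
    return APRMatrix(
        residuals=pd.DataFrame(apr, index=idx, columns=cols),
        p_values=pd.DataFrame(p, index=idx, columns=cols),
        low_expected=pd.DataFrame(low, index=idx, columns=cols),
    )


def flag_associations(apr: APRMatrix, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Signed flags per cell at the highest exceeded |APR| threshold.

    ``"+3.5"`` means over-representation beyond the 3.5 threshold, ``"-2"``
    under-representation beyond 2 but not 3; an empty string means no
    threshold exceeded.
    """
    thresholds = tuple(sorted(float(t) for t in thresholds))
    if any(t <= 0 for t in thresholds):
        raise AssociationError("thresholds must be positive")
    res = apr.residuals

    def cell(v: float) -> str:
        exceeded = [t for t in thresholds if abs(v) >= t]
        if not exceeded:
            return ""
        sign = "+" if v > 0 else "-"
        return f"{sign}{exceeded[-1]:g}"

    return res.map(cell)


@dataclass
class AssociationResult:
    variable: str
    profile: PercentProfile
    chi2: float
    df: int
    p: float
    apr: APRMatrix
    flags: pd.DataFrame


def associate(
    assignments: pd.Series,
    data: pd.DataFrame,
    variables: list[str],
    thresholds=DEFAULT_THRESHOLDS,
) -> dict[str, AssociationResult]:
    """Full association battery of the typologies against each variable."""
    out = {}
    for var in variables:
        ct = ContingencyTable.from_columns(assignments, data[var])
        prof = percent_profile(assignments, data[var])
        stat, df, p = chi_square_independence(ct)
        apr = adjusted_pearson_residuals(ct)
        out[var] = AssociationResult(
            variable=var,
            profile=prof,
            chi2=stat,
            df=df,
            p=p,
            apr=apr,
            flags=flag_associations(apr, thresholds),
        )
    return out


def significant_associations(results: dict[str, AssociationResult]) -> list[dict]:
    """Flatten flagged cells into a serializable list (typology x category)."""
    rows = []
    for var, res in results.items():
        for typ in res.flags.index:
            for cat in res.flags.columns:
                flag = res.flags.loc[typ, cat]
                if flag:
                    rows.append(
                        {
                            "variable": var,
                            "typology": typ,
                            "category": cat,
                            "apr": float(res.apr.residuals.loc[typ, cat]),
                            "p": float(res.apr.p_values.loc[typ, cat]),
                            "flag": flag,
                        }
                    )
    return rows
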