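"""Validation battery for typologies: parametric and nonparametric group tests.

Because questionnaire-derived variables are rarely normal, every comparison
is run under two procedures and a result is only called *sufficiently
revealing* when both agree at the chosen significance level:

* two-group comparisons: one-way ANOVA for equality of means, Mann-Whitney
  and two-sample Kolmogorov-Smirnov for equality of distributions;
* k-group cluster validation: per-variable ANOVA and Kruskal-Wallis,
  one-way MANOVA on all classification variables simultaneously (Wilks'
  lambda with Rao's F approximation, Hotelling-Lawley trace with McKeon's
  F approximation), and pairwise squared Mahalanobis distance tests of
  cluster centroids via the two-sample Hotelling T^2 / F transform with the
  pooled within-cluster covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# two-group dual-procedure rule


@dataclass
class DualRuleRecord:
    anova_p: float
    mann_whitney_p: float
    ks_p: float
    revealing: bool
    unreliable: bool  # zero-variance group: the ANOVA assumption fails


def apply_dual_rule(
    anova_p: float,
    mann_whitney_p: float,
    ks_p: float,
    alpha: float = 0.05,
    strict_all: bool = False,
) -> bool:
    """A result is revealing if significant by both procedure families.

    Default: parametric (ANOVA) AND at least one nonparametric test
    (Mann-Whitney or Kolmogorov-Smirnov).  ``strict_all=True`` requires all
    three.
    """
    nonparam = (
        (mann_whitney_p < alpha) and (ks_p < alpha)
        if strict_all
        else (mann_whitney_p < alpha) or (ks_p < alpha)
    )
    return (anova_p < alpha) and nonparam


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    # exact enumeration for small untied samples, normal approximation
    # (tie-corrected) otherwise
    small = max(len(a), len(b)) <= 20
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (small and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def dual_rule_tests(
    x: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
    strict_all: bool = False,
) -> DualRuleRecord:
    """Two-group comparison of a numeric variable under the dual rule."""
    x = np.asarray(x, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise InferenceError(f"need exactly 2 groups, got {len(levels)}")
    a, b = x[g == levels[0]], x[g == levels[1]]
    if min(len(a), len(b)) < 2:
        raise InferenceError("each group needs n >= 2")
    unreliable = a.var(ddof=1) == 0 or b.var(ddof=1) == 0
    anova_p = float(stats.f_oneway(a, b).pvalue) if not unreliable else np.nan
    mw_p = _mann_whitney(a, b)
    ks_p = float(stats.ks_2samp(a, b).pvalue)
    revealing = (not unreliable) and apply_dual_rule(anova_p, mw_p, ks_p, alpha, strict_all)
    return DualRuleRecord(
        anova_p=anova_p,
        mann_whitney_p=mw_p,
        ks_p=ks_p,
        revealing=revealing,
        unreliable=bool(unreliable),
    )


# ---------------------------------------------------------------------------
# MANOVA statistics (one-way layout)


@dataclass
class ManovaStat:
    value: float
    f_value: float
    df_num: float
    df_den: float
    p: float


def _sscp(Z: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    grand = Z.mean(axis=0)
    p = Z.shape[1]
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for g in np.unique(labels):
        sub = Z[labels == g]
        d = sub.mean(axis=0) - grand
        H += len(sub) * np.outer(d, d)
        r = sub - sub.mean(axis=0)
        E += r.T @ r
    return H, E


def manova_oneway(Z: np.ndarray | pd.DataFrame, labels) -> dict[str, ManovaStat]:
    """One-way MANOVA: Wilks' lambda (Rao's F) and Hotelling-Lawley trace
    (McKeon's F), from the eigenvalues of ``E^{-1} H``."""
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    N, p = Z.shape
    k = len(np.unique(labels))
    if k < 2:
        raise InferenceError("MANOVA needs >= 2 groups")
    H, E = _sscp(Z, labels)
    try:
        lam = np.linalg.eigvals(np.linalg.solve(E, H))
    except np.linalg.LinAlgError as exc:
        raise InferenceError(
            "singular pooled covariance; consider removing a classification variable"
        ) from exc
    lam = np.real(lam)
    lam[lam < 0] = 0.0
    v = N - k  # error df
    q = k - 1  # hypothesis df
    s = min(p, q)
    n_ = (v - p - 1) / 2.0

    # Wilks' lambda with Rao's F approximation
    wilks = float(np.prod(1.0 / (1.0 + lam)))
    r = v - (p - q + 1) / 2.0
    u = (p * q - 2) / 4.0
    t = np.sqrt((p * p * q * q - 4) / (p * p + q * q - 5)) if p * p + q * q - 5 > 0 else 1.0
    df1 = p * q
    df2 = r * t - 2 * u
    lam_t = wilks ** (1.0 / t)
    f_w = (1 - lam_t) / lam_t * df2 / df1
    p_w = float(stats.f.sf(f_w, df1, df2))

    # Hotelling-Lawley trace with McKeon's F approximation
    hlt = float(lam.sum())
    m_ = (abs(p - q) - 1) / 2.0
    if n_ > 0:
        b = (p + 2 * n_) * (q + 2 * n_) / (2 * (2 * n_ + 1) * (n_ - 1))
        df1_h = p * q
        df2_h = 4 + (p * q + 2) / (b - 1)
        c = (df2_h - 2) / (2 * n_)
        f_h = df2_h / df1_h * hlt / c
    else:
        df1_h = s * (2 * m_ + s + 1)
        df2_h = s * (s * n_ + 1)
        f_h = df2_h / df1_h / s * hlt
    p_h = float(stats.f.sf(f_h, df1_h, df2_h))

    return {
        "wilks_lambda": ManovaStat(wilks, float(f_w), df1, float(df2), p_w),
        "hotelling_lawley": ManovaStat(hlt, float(f_h), float(df1_h), float(df2_h), p_h),
    }


# ---------------------------------------------------------------------------
# pairwise squared Mahalanobis distance tests


@dataclass
class PairwiseD2:
    pair: tuple
    d2: float
    t2: float
    f_value: float
    df_num: int
    df_den: int
    p: float


def mahalanobis_pairwise(Z: np.ndarray | pd.DataFrame, labels) -> list[PairwiseD2]:
    """Squared Mahalanobis distance between every pair of cluster centroids.

    ``D^2 = (m_a - m_b)' S^{-1} (m_a - m_b)`` with ``S`` the pooled
    within-cluster covariance (all clusters, ``N - k`` df); significance via
    the two-sample Hotelling ``T^2 = n_a n_b/(n_a+n_b) D^2`` and its exact F
    transform ``F = (v - p + 1)/(v p) T^2`` on ``(p, v - p + 1)`` df.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    N, p = Z.shape
    groups = np.unique(labels)
    k = len(groups)
    _, E = _sscp(Z, labels)
    v = N - k
    S = E / v
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise InferenceError(
            "singular pooled covariance; consider removing a classification variable"
        ) from exc
    out = []
    for a, b in combinations(groups, 2):
        za, zb = Z[labels == a], Z[labels == b]
        diff = za.mean(axis=0) - zb.mean(axis=0)
        d2 = float(diff @ S_inv @ diff)
        na, nb = len(za), len(zb)
        t2 = na * nb / (na + nb) * d2
        f_val = (v - p + 1) / (v * p) * t2
        df_num, df_den = p, v - p + 1
        out.append(
            PairwiseD2(
                pair=(a, b),
                d2=d2,
                t2=float(t2),
                f_value=float(f_val),
                df_num=df_num,
                df_den=df_den,
                p=float(stats.f.sf(f_val, df_num, df_den)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# full battery


@dataclass
class TestBattery:
    per_variable: pd.DataFrame  # anova_p, kruskal_p per classification variable
    manova: dict[str, ManovaStat]
    pairwise: list[PairwiseD2]
    k: int

    @property
    def n_pairwise(self) -> int:
        return len(self.pairwise)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "per_variable": self.per_variable.to_dict(orient="index"),
            "manova": {
                name: {
                    "value": s.value,
                    "F": s.f_value,
                    "df": [s.df_num, s.df_den],
                    "p": s.p,
                }
                for name, s in self.manova.items()
            },
            "pairwise_mahalanobis": [
                {
                    "pair": [str(x) for x in r.pair],
                    "D2": r.d2,
                    "F": r.f_value,
                    "df": [r.df_num, r.df_den],
                    "p": r.p,
                }
                for r in self.pairwise
            ],
        }


def cluster_validation(Z: pd.DataFrame, assignments) -> TestBattery:
    """Validate a partition: per-variable ANOVA + Kruskal-Wallis, MANOVA,
    and all k(k-1)/2 pairwise Mahalanobis centroid tests."""
    labels = np.asarray(assignments)
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise InferenceError("need >= 2 clusters")
    sizes = [np.sum(labels == g) for g in groups]
    if min(sizes) < 2:
        raise InferenceError("every cluster needs n >= 2")
    rows = {}
    for col in Z.columns:
        samples = [Z[col].to_numpy()[labels == g] for g in groups]
        rows[col] = {
            "anova_p": float(stats.f_oneway(*samples).pvalue),
            "kruskal_p": float(stats.kruskal(*samples).pvalue),
        }
    return TestBattery(
        per_variable=pd.DataFrame(rows).T,
        manova=manova_oneway(Z.to_numpy(), labels),
        pairwise=mahalanobis_pairwise(Z.to_numpy(), labels),
        k=k,
    )
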