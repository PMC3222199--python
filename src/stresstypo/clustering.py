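"""Subject typologies: multi-restart k-means, Calinski-Harabasz selection, outliers.

The typology stage groups respondents on six standardized classification
variables (stress, control, activity, smoking and alcohol indicators plus
reported absenteeism).  k-means is run with many random starts -- each start
seeds the k centroids with k subjects drawn at random without replacement --
and the minimum within-cluster-deviance partition is kept, which removes the
classic dependence of the algorithm on row order.  The number of clusters is
chosen by the Calinski-Harabasz (CH) statistic, here computed with
between/within deviances divided by ``k`` and ``N - k`` respectively (the
classic ``k - 1`` convention is available behind a flag).

Outliers are found by a first clustering pass: very small clusters whose
exact membership stays the same over several consecutive values of ``k`` are
isolated subjects, removed before the variables are restandardized and the
final partition is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# k-means with random starts


@dataclass
class KMeansSolution:
    assignments: np.ndarray  # cluster id per row, 0..k-1
    centroids: np.ndarray  # k x d
    within_deviance: float
    k: int
    n_starts: int
    rng_seed: object

    def recompute_within(self, Z: np.ndarray) -> float:
        return float(((Z - self.centroids[self.assignments]) ** 2).sum())


def _assign(Z: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = ((Z[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _lloyd(Z: np.ndarray, seed_idx: np.ndarray, max_iter: int = 300):
    """One k-means run from given seed rows; returns (assignments, centroids, W)."""
    k = len(seed_idx)
    C = Z[seed_idx].copy()
    assign = None
    for _ in range(max_iter):
        new = _assign(Z, C)
        # empty-cluster repair: re-seed with the point farthest from the
        # centroid of the largest cluster
        sizes = np.bincount(new, minlength=k)
        while np.any(sizes == 0):
            empty = int(np.flatnonzero(sizes == 0)[0])
            big = int(sizes.argmax())
            members = np.flatnonzero(new == big)
            d = ((Z[members] - C[big]) ** 2).sum(axis=1)
            far = members[int(d.argmax())]
            new[far] = empty
            sizes = np.bincount(new, minlength=k)
        if assign is not None and np.array_equal(new, assign):
            break
        assign = new
        for c in range(k):
            C[c] = Z[assign == c].mean(axis=0)
    W = float(((Z - C[assign]) ** 2).sum())
    return assign, C, W


def kmeans_random_starts(
    Z: np.ndarray | pd.DataFrame,
    k: int,
    n_starts: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    max_iter: int = 300,
) -> KMeansSolution:
    """Best-of-``n_starts`` k-means partition (minimum within-cluster deviance).

    Each start draws its k initial centroids as k distinct subjects, at
    random without replacement.  With the same seed, smaller ``n_starts`` use
    a prefix of the same start sequence, so the best deviance is
    nonincreasing in ``n_starts``.
    """
    Zm = np.asarray(Z, dtype=float)
    N = len(Zm)
    if not (2 <= k <= N):
        raise ClusteringError(f"k must lie in [2, {N}], got {k}")
    if n_starts < 1:
        raise ClusteringError("n_starts must be >= 1")
    if len(np.unique(Zm, axis=0)) < k:
        raise ClusteringError(f"k={k} exceeds the number of distinct rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        seed_idx = rng.choice(N, size=k, replace=False)
        assign, C, W = _lloyd(Zm, seed_idx, max_iter=max_iter)
        if best is None or W < best[2] - 1e-12:
            best = (assign, C, W)
    assign, C, W = best
    return KMeansSolution(
        assignments=assign,
        centroids=C,
        within_deviance=W,
        k=k,
        n_starts=n_starts,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# Calinski-Harabasz


def deviances(Z: np.ndarray, assignments: np.ndarray) -> tuple[float, float]:
    """(between, within) deviances (sums of squares) of a partition."""
    Z = np.asarray(Z, dtype=float)
    grand = Z.mean(axis=0)
    B = W = 0.0
    for c in np.unique(assignments):
        sub = Z[assignments == c]
        centroid = sub.mean(axis=0)
        B += len(sub) * float(((centroid - grand) ** 2).sum())
        W += float(((sub - centroid) ** 2).sum())
    return B, W


def calinski_harabasz(
    Z: np.ndarray | pd.DataFrame,
    assignments: np.ndarray,
    *,
    df_convention: str = "deviance_ratio",
) -> float:
    """Calinski-Harabasz statistic of a partition.

    ``df_convention="deviance_ratio"`` divides the between deviance by ``k``
    and the within deviance by ``N - k``; ``"classic"`` uses the textbook
    ``k - 1`` numerator degrees of freedom.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(assignments)
    k = len(np.unique(labels))
    N = len(Z)
    if k < 2:
        raise ClusteringError("CH requires at least 2 nonempty clusters")
    B, W = deviances(Z, labels)
    df_b = k if df_convention == "deviance_ratio" else k - 1
    if df_convention not in ("deviance_ratio", "classic"):
        raise ClusteringError(f"unknown df_convention {df_convention!r}")
    if W == 0:
        warnings.warn("zero within-cluster deviance: CH is infinite", RuntimeWarning)
        return np.inf
    return (B / df_b) / (W / (N - k))


@dataclass
class CHProfile:
    entries: dict[int, float]  # k -> CH
    argmax_k: int
    near_ties: list[int]  # k values within the tie tolerance of the max
    tie_tol: float
    prefer_larger_k: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": list(self.entries), "ch": list(self.entries.values())})


def ch_scan(
    Z: np.ndarray | pd.DataFrame,
    k_range=range(2, 16),
    n_starts: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    *,
    df_convention: str = "deviance_ratio",
    tie_tol: float = 0.005,
    prefer_larger_k: bool = True,
) -> CHProfile:
    """CH statistic over a range of k, each at the best-of-restarts partition.

    The selected ``argmax_k`` is the k with maximal CH; when several k fall
    within ``tie_tol`` (relative) of the maximum they are reported as near
    ties and the largest (default) or smallest is selected.
    """
    Zm = np.asarray(Z, dtype=float)
    ks = list(k_range)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(ks))
    entries: dict[int, float] = {}
    for k, child in zip(ks, children):
        sol = kmeans_random_starts(Zm, k, n_starts=n_starts, seed=child)
        entries[k] = calinski_harabasz(Zm, sol.assignments, df_convention=df_convention)
    best = max(entries.values())
    ties = [k for k, v in entries.items() if v >= best * (1.0 - tie_tol)]
    argmax = max(ties) if prefer_larger_k else min(ties)
    return CHProfile(
        entries=entries,
        argmax_k=argmax,
        near_ties=sorted(ties),
        tie_tol=tie_tol,
        prefer_larger_k=prefer_larger_k,
    )


# ---------------------------------------------------------------------------
# outlier detection by stable small clusters


@dataclass
class OutlierGroup:
    members: tuple  # row ids
    k_onset: int
    stability_span: int


@dataclass
class OutlierReport:
    outlier_row_ids: list
    groups: list[OutlierGroup]

    def __bool__(self) -> bool:
        return bool(self.outlier_row_ids)


def detect_outliers(
    Z: pd.DataFrame | np.ndarray,
    k_range=range(2, 16),
    max_cluster_size: int | None = None,
    min_stability: int = 3,
    n_starts: int = 100,
    seed: int | np.random.SeedSequence | None = None,
) -> OutlierReport:
    """Flag small clusters whose exact membership recurs over consecutive k.

    A group of rows qualifies as outliers when it forms a cluster of size at
    most ``max_cluster_size`` (default: 1% of N, at least 1) in the
    best-of-restarts solutions for at least ``min_stability`` consecutive
    values of k.
    """
    if isinstance(Z, pd.DataFrame):
        index = Z.index.to_numpy()
        Zm = Z.to_numpy(dtype=float)
    else:
        Zm = np.asarray(Z, dtype=float)
        index = np.arange(len(Zm))
    N = len(Zm)
    if max_cluster_size is None:
        max_cluster_size = max(1, round(0.01 * N))
    if max_cluster_size < 1 or min_stability < 2:
        raise ClusteringError("max_cluster_size >= 1 and min_stability >= 2 required")
    ks = list(k_range)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(ks))
    small_by_k: dict[int, set[frozenset]] = {}
    for k, child in zip(ks, children):
        if k > N - 1:
            continue
        sol = kmeans_random_starts(Zm, k, n_starts=n_starts, seed=child)
        sizes = np.bincount(sol.assignments, minlength=k)
        small = set()
        for c in np.flatnonzero((sizes >= 1) & (sizes <= max_cluster_size)):
            small.add(frozenset(index[sol.assignments == c].tolist()))
        small_by_k[k] = small

    candidates = set().union(*small_by_k.values()) if small_by_k else set()
    groups: list[OutlierGroup] = []
    scanned = sorted(small_by_k)
    for cand in candidates:
        present = {k for k in scanned if cand in small_by_k[k]}
        # longest run over consecutive k values
        best_run, best_onset = 0, None
        run, onset, prev_k = 0, None, None
        for k in scanned:
            if k in present:
                if run > 0 and prev_k == k - 1:
                    run += 1
                else:
                    run, onset = 1, k
                if run > best_run:
                    best_run, best_onset = run, onset
            else:
                run, onset = 0, None
            prev_k = k
        if best_run >= min_stability:
            groups.append(
                OutlierGroup(
                    members=tuple(sorted(cand)),
                    k_onset=int(best_onset),
                    stability_span=int(best_run),
                )
            )
    # keep maximal groups only (a stable singleton inside a stable pair is the pair's)
    groups.sort(key=lambda g: (-len(g.members), g.k_onset))
    kept: list[OutlierGroup] = []
    for g in groups:
        if not any(set(g.members) <= set(h.members) for h in kept):
            kept.append(g)
    outliers = sorted({rid for g in kept for rid in g.members})
    return OutlierReport(outlier_row_ids=outliers, groups=kept)


# ---------------------------------------------------------------------------
# end-to-end typology pipeline


@dataclass
class TypologyConfig:
    k_range: tuple[int, int] = (2, 15)
    n_starts: int = 1000
    outlier_n_starts: int = 100
    max_cluster_size: int | None = None
    min_stability: int = 3
    tie_tol: float = 0.005
    prefer_larger_k: bool = True
    df_convention: str = "deviance_ratio"
    zscore_ddof: int = 1
    seed: int | None = None


@dataclass
class Typology:
    cluster: int
    size: int
    share_pct: float
    label: str
    quartiles: pd.DataFrame  # per variable: min, q1, median, q3, max


@dataclass
class TypologyResult:
    outliers: OutlierReport
    ch_profile: CHProfile
    solution: KMeansSolution
    typologies: list[Typology]
    classification: pd.DataFrame  # restandardized variables, outliers removed

    def assignments_series(self) -> pd.Series:
        return pd.Series(
            self.solution.assignments + 1, index=self.classification.index, name="cluster"
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": [t.cluster for t in self.typologies],
                "size": [t.size for t in self.typologies],
                "share_pct": [t.share_pct for t in self.typologies],
                "label": [t.label for t in self.typologies],
            }
        )


def _zscore_frame(df: pd.DataFrame, ddof: int) -> pd.DataFrame:
    sd = df.std(ddof=ddof)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ClusteringError(f"zero variance in classification variable {bad!r}")
    return (df - df.mean()) / sd


def _label_cluster(centroid: pd.Series) -> str:
    var = centroid.abs().idxmax()
    return f"{'high' if centroid[var] > 0 else 'low'} {var}"


def run_typology_pipeline(
    classification: pd.DataFrame,
    config: TypologyConfig | None = None,
) -> TypologyResult:
    """Two-phase typology construction.

    Phase 1 standardizes the classification variables and removes stable
    small clusters (outliers); phase 2 restandardizes the remaining rows,
    scans k by the CH statistic, and fits the final best-of-restarts
    partition at the selected k.  Deterministic given ``config.seed``.
    """
    cfg = config or TypologyConfig()
    ss = np.random.SeedSequence(cfg.seed)
    s_outl, s_scan, s_final = ss.spawn(3)
    k_lo, k_hi = cfg.k_range
    ks = range(k_lo, k_hi + 1)

    Z1 = _zscore_frame(classification, cfg.zscore_ddof)
    report = detect_outliers(
        Z1,
        k_range=ks,
        max_cluster_size=cfg.max_cluster_size,
        min_stability=cfg.min_stability,
        n_starts=cfg.outlier_n_starts,
        seed=s_outl,
    )
    retained = classification.loc[~classification.index.isin(report.outlier_row_ids)]
    Z2 = _zscore_frame(retained, cfg.zscore_ddof)

    profile = ch_scan(
        Z2,
        k_range=ks,
        n_starts=cfg.n_starts,
        seed=s_scan,
        df_convention=cfg.df_convention,
        tie_tol=cfg.tie_tol,
        prefer_larger_k=cfg.prefer_larger_k,
    )
    solution = kmeans_random_starts(
        Z2.to_numpy(), profile.argmax_k, n_starts=cfg.n_starts, seed=s_final
    )

    typologies = []
    N = len(Z2)
    for c in range(solution.k):
        members = Z2[solution.assignments == c]
        centroid = members.mean()
        q = members.quantile([0.0, 0.25, 0.5, 0.75, 1.0]).T
        q.columns = ["min", "q1", "median", "q3", "max"]
        typologies.append(
            Typology(
                cluster=c + 1,
                size=len(members),
                share_pct=round(100.0 * len(members) / N, 1),
                label=_label_cluster(centroid),
                quartiles=q,
            )
        )
    return TypologyResult(
        outliers=report,
        ch_profile=profile,
        solution=solution,
        typologies=typologies,
        classification=Z2,
    )
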