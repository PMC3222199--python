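"""Nonlinear principal component analysis with optimal scaling (PRINCALS/CATPCA).

Classical PCA assumes metric variables.  Mixed questionnaire data (nominal
work categories, ordinal consumption scales, numeric biochemistry) instead
require *optimal scaling*: each qualitative variable's categories are replaced
by metric quantifications, chosen jointly with the low-dimensional object
scores so that the extracted dimensions explain as much variance of the
scaled variables as possible.  The fit alternates least-squares updates over

* object scores ``X`` (one p-vector per respondent; columns centered, with
  ``X'X = N I`` so loadings are plain correlations), and
* per-variable category quantifications ``q_j`` (nominal: category centroids
  of the projected scores; ordinal: the same targets passed through weighted
  monotone regression so the declared category order is preserved; numeric:
  fixed at the z-scored original).

Each transformed column ``t_j = q_j[codes]`` is normalized to mean 0,
variance 1, so the component loadings ``a_j = X' t_j / N`` are correlation
coefficients of dimensions with the optimally scaled variables
(variable-principal normalization).  On convergence the dimensions are
rotated to the principal axes of the transformed data, which makes the
eigenvalue identities hold exactly: ``lambda_d = sum_j a_jd^2`` equals the
d-th eigenvalue of the correlation matrix of the transformed columns, and
``VAF_d = 100 lambda_d / m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import CohortTable


class PrincalsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# weighted monotone (isotonic) regression


def monotone_regression(targets, weights=None) -> np.ndarray:
    """Weighted least-squares fit under a nondecreasing constraint (PAVA).

    Pool-adjacent-violators: scan left to right, pooling adjacent blocks by
    weighted mean whenever the fitted sequence would decrease.  Ties in
    targets are handled by the same pooling rule.  ``weights`` default to 1.
    """
    y = np.asarray(targets, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("targets must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match targets in length")

    # blocks as (value, weight, count)
    vals: list[float] = []
    wts: list[float] = []
    cnt: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(yi)
        wts.append(wi)
        cnt.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]
            cnt[-2] += cnt[-1]
            vals[-2] = v
            del vals[-1], wts[-1], cnt[-1]
    return np.repeat(vals, cnt)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class Quantification:
    """Optimal-scaling transform of one variable."""

    name: str
    level: str
    categories: tuple  # category labels, declared order (numeric: empty)
    quantifications: np.ndarray  # one value per category (numeric: empty)
    frequencies: np.ndarray  # category counts (numeric: empty)
    transformed: np.ndarray  # N-vector, mean 0, variance 1 (1/N convention)


@dataclass
class PrincalsResult:
    """Converged optimal-scaling PCA solution."""

    var_names: list[str]
    scores: pd.DataFrame  # N x p object scores, X'X = N I
    loadings: pd.DataFrame  # m x p correlations of dims with scaled vars
    quantifications: dict[str, Quantification]
    eigenvalues: np.ndarray  # per-dimension, descending
    vaf_per_dim: np.ndarray  # percent, 100*lambda_d/m
    vaf_total: float  # percent
    alpha_total: float  # eigenvalue-based Cronbach alpha on sum(lambda)
    alpha_per_dim: np.ndarray
    loss_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def n_dims(self) -> int:
        return self.scores.shape[1]

    def transformed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {n: self.quantifications[n].transformed for n in self.var_names},
            index=self.scores.index,
        )


def cronbach_alpha_from_eigenvalue(lambda_: float, m: int) -> float:
    """Cronbach alpha from an eigenvalue (sum): ``m (lambda - 1) / ((m-1) lambda)``.

    ``lambda_`` is the variance explained by the dimension(s), on the scale
    where each of the ``m`` scaled variables contributes unit variance; the
    total-VAF fraction times ``m`` gives the multi-dimension alpha.
    """
    if m < 2:
        raise ValueError("alpha requires m >= 2 variables")
    if lambda_ <= 0:
        raise ValueError("alpha requires a positive eigenvalue")
    return m * (lambda_ - 1.0) / ((m - 1.0) * lambda_)


def cronbach_alpha(items: np.ndarray) -> float:
    """Classical covariance-based Cronbach alpha of an N x k item matrix."""
    items = np.asarray(items, dtype=float)
    k = items.shape[1]
    if k < 2:
        raise ValueError("alpha requires >= 2 items")
    item_var = items.var(axis=0, ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return k / (k - 1.0) * (1.0 - item_var / total_var)


def classify_loadings(loadings, threshold: float = 0.4) -> pd.DataFrame:
    """Flag essential (|loading| >= threshold) vs negligible loadings."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    a = pd.DataFrame(loadings)
    return a.abs() >= threshold


# ---------------------------------------------------------------------------
# low-level ALS steps (exposed for testing and reuse)


def quantify_nominal(codes: np.ndarray, X: np.ndarray, n_categories: int) -> np.ndarray:
    """Centroid principle: each category's quantification is the mean object
    score of its members.  Returns an ``n_categories x p`` array."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(codes) != 1:
        X = X.T
    counts = np.bincount(codes, minlength=n_categories)
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0])
        raise PrincalsError(f"empty category {empty} has no members")
    out = np.zeros((n_categories, X.shape[1]))
    for d in range(X.shape[1]):
        out[:, d] = np.bincount(codes, weights=X[:, d], minlength=n_categories) / counts
    return out


def update_object_scores(T: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Least-squares update of object scores given transformed columns and loadings.

    Minimizes ``sum_j ||X - t_j a_j'||^2`` subject to ``1'X = 0`` and
    ``X'X = N I``; the solution is the orthogonal-Procrustes projection of
    ``T A / m`` (scaled by sqrt(N)).
    """
    T = np.asarray(T, dtype=float)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[0] != T.shape[1]:
        A = A.T
    N, m = T.shape
    S = T @ A / m
    S = S - S.mean(axis=0)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    p = A.shape[1]
    if np.sum(s > 1e-12 * max(1.0, s[0] if s.size else 0.0)) < p:
        raise PrincalsError(f"cannot support {p} dimensions: rank-deficient update")
    return np.sqrt(N) * U @ Vt


def _loss(X: np.ndarray, T: np.ndarray, A: np.ndarray) -> float:
    N, m = T.shape
    total = 0.0
    for j in range(m):
        resid = X - np.outer(T[:, j], A[j])
        total += float((resid**2).sum())
    return total / (N * m)


# ---------------------------------------------------------------------------
# main fit


def fit_princals(
    data: CohortTable | pd.DataFrame,
    var_names: list[str] | None = None,
    p: int = 2,
    *,
    levels: dict[str, str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: str = "pca",
    seed: int | None = None,
) -> PrincalsResult:
    """Fit the optimal-scaling PCA by alternating least squares.

    Parameters
    ----------
    data
        A :class:`~stresstypo.schema.CohortTable` (levels taken from its
        schema) or a plain data frame with ``levels`` supplied.
    var_names
        Variables to include (default: all).
    p
        Number of dimensions to extract (``1 <= p <= m``).
    levels
        Mapping name -> {"nominal", "ordinal", "numeric"}; ordinal category
        order is taken from the schema, from a pandas Categorical dtype, or
        from sorted unique values, in that order of preference.
    tol, max_iter
        Convergence: stop when the relative loss change drops below ``tol``.
    init
        ``"pca"`` (deterministic: classical PCA of the integer-coded,
        z-scored data) or ``"random"`` with ``seed``.
    """
    if isinstance(data, CohortTable):
        frame = data.data
        lev = data.levels()
        cat_orders = {v.name: v.categories for v in data.schema if v.categories}
    else:
        frame = data
        if levels is None:
            raise PrincalsError("levels mapping required when fitting a plain DataFrame")
        lev = dict(levels)
        cat_orders = {}
    if var_names is None:
        var_names = [c for c in frame.columns if c in lev]
    m = len(var_names)
    if not (1 <= p <= m):
        raise PrincalsError(f"p must lie in [1, {m}], got {p}")

    frame = frame[var_names].dropna()
    N = len(frame)
    if N < 3:
        raise PrincalsError("need at least 3 complete records")

    # --- encode columns
    codes_list: list[np.ndarray | None] = []
    cats_list: list[tuple] = []
    counts_list: list[np.ndarray] = []
    T = np.zeros((N, m))
    for j, name in enumerate(var_names):
        level = lev[name]
        col = frame[name]
        if level == "numeric":
            x = col.to_numpy(dtype=float)
            sd = x.std()  # 1/N convention internally so t't = N
            if sd == 0:
                raise PrincalsError(f"degenerate variable {name!r}: zero spread")
            T[:, j] = (x - x.mean()) / sd
            codes_list.append(None)
            cats_list.append(())
            counts_list.append(np.array([]))
        else:
            if name in cat_orders:
                order = [c for c in cat_orders[name] if c in set(col)]
            elif isinstance(col.dtype, pd.CategoricalDtype):
                order = [c for c in col.cat.categories if c in set(col)]
            else:
                order = sorted(col.unique())
            if len(order) < 2:
                raise PrincalsError(f"degenerate variable {name!r}: <2 observed categories")
            lookup = {c: i for i, c in enumerate(order)}
            codes = col.map(lookup).to_numpy(dtype=int)
            counts = np.bincount(codes, minlength=len(order)).astype(float)
            z = codes.astype(float)
            T[:, j] = (z - z.mean()) / z.std()
            codes_list.append(codes)
            cats_list.append(tuple(order))
            counts_list.append(counts)

    # --- initialize object scores
    if init == "pca":
        U, s, _ = np.linalg.svd(T - T.mean(axis=0), full_matrices=False)
        if np.sum(s > 1e-10 * s[0]) < p:
            raise PrincalsError(f"cannot support {p} dimensions: data rank too low")
        X = np.sqrt(N) * U[:, :p]
    elif init == "random":
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((N, p))
        X -= X.mean(axis=0)
        U, _, Vt = np.linalg.svd(X, full_matrices=False)
        X = np.sqrt(N) * U @ Vt
    else:
        raise PrincalsError(f"unknown init {init!r}")

    A = T.T @ X / N  # m x p loadings (correlations)
    loss_trace = [_loss(X, T, A)]
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        # quantification step (numeric columns stay fixed)
        for j in range(m):
            codes = codes_list[j]
            if codes is None:
                A[j] = X.T @ T[:, j] / N
                continue
            a = A[j]
            if np.dot(a, a) < 1e-14:
                continue  # no usable direction this sweep; keep previous transform
            u = X @ a
            counts = counts_list[j]
            ybar = np.bincount(codes, weights=u, minlength=len(counts)) / counts
            if lev[var_names[j]] == "ordinal":
                q = monotone_regression(ybar, counts)
            else:
                q = ybar.copy()
            q = q - (counts @ q) / N
            ss = counts @ q**2
            if ss < 1e-14:
                continue  # pooled to a constant; keep previous transform
            q *= np.sqrt(N / ss)
            T[:, j] = q[codes]
            A[j] = X.T @ T[:, j] / N
        # object-score step
        X = update_object_scores(T, A)
        A = T.T @ X / N
        loss = _loss(X, T, A)
        if loss > loss_trace[-1] + 1e-10:
            raise PrincalsError("loss increased during ALS; numerical failure")
        rel = abs(loss_trace[-1] - loss) / max(loss_trace[-1], 1e-12)
        loss_trace.append(loss)
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("PRINCALS did not converge within max_iter", RuntimeWarning)

    # --- rotate to principal axes of the transformed columns
    R = T.T @ T / N  # correlation matrix of scaled variables
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = evals[:p].copy()
    V = evecs[:, :p]
    if np.any(lam <= 1e-12):
        raise PrincalsError(f"cannot support {p} dimensions: zero eigenvalue")
    A = V * np.sqrt(lam)
    X = T @ V / np.sqrt(lam)
    # sign convention: largest-|loading| variable loads positively per dimension
    for d in range(p):
        j_star = int(np.argmax(np.abs(A[:, d])))
        if A[j_star, d] < 0:
            A[:, d] *= -1
            X[:, d] *= -1

    quants: dict[str, Quantification] = {}
    for j, name in enumerate(var_names):
        codes = codes_list[j]
        if codes is None:
            q_arr = np.array([])
        else:
            # per-category value of the transformed column
            q_arr = np.zeros(len(cats_list[j]))
            q_arr[codes] = T[:, j]
        quants[name] = Quantification(
            name=name,
            level=lev[name],
            categories=cats_list[j],
            quantifications=q_arr,
            frequencies=counts_list[j],
            transformed=T[:, j].copy(),
        )

    lam_sum = float(lam.sum())
    dim_cols = [f"dim{d + 1}" for d in range(p)]
    return PrincalsResult(
        var_names=list(var_names),
        scores=pd.DataFrame(X, index=frame.index, columns=dim_cols),
        loadings=pd.DataFrame(A, index=var_names, columns=dim_cols),
        quantifications=quants,
        eigenvalues=lam,
        vaf_per_dim=100.0 * lam / m,
        vaf_total=100.0 * lam_sum / m,
        alpha_total=(
            cronbach_alpha_from_eigenvalue(lam_sum, m) if m >= 2 and lam_sum > 0 else np.nan
        ),
        alpha_per_dim=np.array(
            [
                cronbach_alpha_from_eigenvalue(l, m) if m >= 2 and l > 0 else np.nan
                for l in lam
            ]
        ),
        loss_trace=np.asarray(loss_trace),
        converged=converged,
        n_iter=n_iter,
    )
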