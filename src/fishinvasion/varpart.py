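"""Collinearity screening and variation partitioning across driver groups.

Variation partitioning decomposes the adjusted R² of a response over up to
four groups of explanatory variables into 15 unique and shared fractions plus
a residual, by inclusion–exclusion over the adjusted R² of every non-empty
union of groups (the Legendre & Legendre convention: shared fractions may be
negative).  Unique fractions are tested by permutation ANOVA with
residual-permutation under the reduced (conditioning) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _design(X: np.ndarray | None, n: int) -> np.ndarray:
    """Design matrix with intercept; X=None means intercept only."""
    if X is None or X.size == 0:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(len(X)), X])


def _rss(y: np.ndarray, D: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    r = y - D @ beta
    return float(r @ r)


def r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """Ordinary R² of y on X (with intercept), via least squares."""
    y = np.asarray(y, dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant response")
    return 1.0 - _rss(y, _design(X, len(y))) / tss


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R²)(n - 1)/(n - p - 1).

    Identity at p = 0; NaN (flagged) when n <= p + 1.
    """
    if p == 0:
        return r2
    if n <= p + 1:
        logger.warning("adjusted_r2 undefined: n=%d <= p+1=%d", n, p + 1)
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def vif_scores(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1/(1 - R²) of each variable
    regressed on the others in the table (inf for exact collinearity)."""
    cols = list(X.columns)
    out = {}
    for j, c in enumerate(cols):
        others = [x for x in cols if x != c]
        if not others:
            out[c] = 1.0
            continue
        r2 = r_squared(X[c].to_numpy(), X[others].to_numpy())
        out[c] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_filter(
    X: pd.DataFrame, threshold: float = 8.0
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Iteratively drop the highest-VIF variable until all VIF <= threshold.

    Exactly collinear sets resolve by dropping the later-listed member first.
    Returns (retained table, final VIFs, dropped names in order).
    """
    if len(X) <= len(X.columns):
        raise ValueError("need n > p for VIF screening")
    work = X.copy()
    dropped: list[str] = []
    while len(work.columns) > 1:
        vifs = vif_scores(work)
        worst = vifs.max()
        if worst <= threshold:
            break
        # among (near-)ties at the max, drop the later-listed column
        candidates = [c for c in work.columns if vifs[c] >= worst * (1 - 1e-9)]
        victim = candidates[-1]
        logger.info("vif_filter: dropping %s (VIF=%.3g)", victim, vifs[victim])
        dropped.append(victim)
        work = work.drop(columns=[victim])
    return work, vif_scores(work), dropped


@dataclass
class PartitionResult:
    """15 adjusted-R² fractions (+ residual) over up to 4 explanatory groups.

    ``fractions`` is indexed by '&'-joined group names: unique fractions under
    each single group name, shared fractions under the joined names.  Shared
    fractions can be negative; the fractions sum to the full-model adjusted
    R² and residual = 1 - that total.
    """

    group_names: list[str]
    fractions: pd.Series
    residual: float
    adj_r2_full: float
    subset_adj_r2: pd.Series  # adjusted R² of every non-empty group union
    unique_p: dict[str, float] | None = None
    unique_F: dict[str, float] | None = None

    def closure_error(self) -> float:
        return abs(float(self.fractions.sum()) - self.adj_r2_full)


def _label(subset: tuple[str, ...]) -> str:
    return "&".join(subset)


def variation_partition(
    y: np.ndarray, groups: dict[str, pd.DataFrame]
) -> PartitionResult:
    """Partition the adjusted R² of ``y`` over 2-4 variable groups.

    Fits every non-empty union of groups by least squares, adjusts each R²
    for its number of predictors, and solves the inclusion–exclusion system
    for the unique/shared fractions.
    """
    names = list(groups)
    if not 2 <= len(names) <= 4:
        raise ValueError("variation partitioning needs 2-4 groups")
    y = np.asarray(y, dtype=float)
    n = len(y)
    subsets = [
        combo for r in range(1, len(names) + 1) for combo in combinations(names, r)
    ]
    adj: dict[tuple[str, ...], float] = {}
    for s in subsets:
        Xs = pd.concat([groups[g] for g in s], axis=1)
        mat = Xs.to_numpy(dtype=float)
        if mat.shape[1] == 0:  # union of empty groups explains nothing
            adj[s] = 0.0
            continue
        p = np.linalg.matrix_rank(mat - mat.mean(axis=0))
        adj[s] = adjusted_r2(r_squared(y, mat), n, p)
    # fractions f(T): adjR2(S) = sum over T intersecting S of f(T)
    M = np.array(
        [[1.0 if set(t) & set(s) else 0.0 for t in subsets] for s in subsets]
    )
    f = np.linalg.solve(M, np.array([adj[s] for s in subsets]))
    fractions = pd.Series(f, index=[_label(s) for s in subsets])
    full = adj[tuple(names)]
    return PartitionResult(
        group_names=names,
        fractions=fractions,
        residual=1.0 - full,
        adj_r2_full=full,
        subset_adj_r2=pd.Series(adj.values(), index=[_label(s) for s in adj]),
    )


def test_unique_fraction(
    y: np.ndarray,
    X_target: np.ndarray | pd.DataFrame,
    X_condition: np.ndarray | pd.DataFrame | None,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial permutation ANOVA of ``X_target`` given ``X_condition``.

    F compares the residual sums of squares of the conditioning-only and full
    models; the null distribution permutes the residuals of the conditioning
    model (Freedman–Lane), and p = (exceedances + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xt = np.atleast_2d(np.asarray(X_target, dtype=float).reshape(n, -1))
    Xc = (
        None
        if X_condition is None
        else np.atleast_2d(np.asarray(X_condition, dtype=float).reshape(n, -1))
    )
    D_red = _design(Xc, n)
    D_full = np.column_stack([D_red, Xt])
    df_t = np.linalg.matrix_rank(D_full) - np.linalg.matrix_rank(D_red)
    df_resid = n - np.linalg.matrix_rank(D_full)
    if df_t < 1 or df_resid < 1:
        raise ValueError("insufficient degrees of freedom for the partial test")

    H_red = D_red @ np.linalg.pinv(D_red)
    H_full = D_full @ np.linalg.pinv(D_full)
    R_red = np.eye(n) - H_red
    R_full = np.eye(n) - H_full

    def f_stat(vec: np.ndarray) -> np.ndarray:
        rss_red = ((R_red @ vec) ** 2).sum(axis=0)
        rss_full = ((R_full @ vec) ** 2).sum(axis=0)
        return ((rss_red - rss_full) / df_t) / (rss_full / df_resid)

    F_obs = float(f_stat(y[:, None])[0])
    rng = np.random.default_rng(seed)
    fitted = H_red @ y
    resid = y - fitted
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = resid[rng.permutation(n)]
    F_perm = f_stat(fitted[:, None] + perms)
    p = (int((F_perm >= F_obs).sum()) + 1) / (n_perm + 1)
    return F_obs, float(p)


def partition_with_tests(
    y: np.ndarray,
    groups: dict[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int = 0,
) -> PartitionResult:
    """Variation partitioning plus permutation tests of each unique fraction."""
    res = variation_partition(y, groups)
    unique_p, unique_F = {}, {}
    for i, g in enumerate(res.group_names):
        others = [h for h in res.group_names if h != g]
        Xc = pd.concat([groups[h] for h in others], axis=1).to_numpy(dtype=float)
        F, p = test_unique_fraction(
            y, groups[g].to_numpy(dtype=float), Xc, n_perm=n_perm, seed=seed + i
        )
        unique_F[g], unique_p[g] = F, p
    res.unique_F, res.unique_p = unique_F, unique_p
    return res


def euler_venn_areas(result: PartitionResult) -> dict[str, float]:
    """Display areas for a proportional Euler–Venn export: negative shared
    fractions are clamped to 0 for drawing (the table itself is never
    clamped)."""
    return {k: max(float(v), 0.0) for k, v in result.fractions.items()}
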