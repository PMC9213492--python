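"""Redundancy analysis (RDA) with permutation tests of the constrained axes.

RDA is the PCA of the fitted values of a multivariate linear regression of a
(column-centred) site x species matrix on the explanatory variables: the
constrained axes are the orthogonal directions of species space best
explained by the drivers.  Implemented directly from least squares and the
singular value decomposition; eigenvalues, axis proportions, scores and
triplot scalings follow the standard conventions (inertia = covariance
trace, divisor n - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .varpart import adjusted_r2

logger = logging.getLogger(__name__)


def hellinger(Y: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-relative abundances."""
    Y = np.asarray(Y, dtype=float)
    totals = Y.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.sqrt(Y / totals)


@dataclass
class RDAResult:
    eigenvalues: np.ndarray  # constrained axes, non-increasing
    residual_eigenvalues: np.ndarray
    total_inertia: float
    proportion: np.ndarray  # variance proportion per constrained axis
    r2: float
    adj_r2: float
    rank: int  # rank of the constraint matrix
    site_scores: pd.DataFrame  # linear-combination (LC) site scores
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame  # driver arrows (correlation with LC axes)
    axis_F: np.ndarray | None = None
    axis_p: np.ndarray | None = None

    @property
    def constrained_proportion(self) -> float:
        return float(self.proportion.sum())


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def rda_fit(
    Y: pd.DataFrame | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    scaling: int = 2,
    transform: str | None = None,
) -> RDAResult:
    """Fit an RDA of the species matrix ``Y`` on the driver matrix ``X``.

    ``transform="hellinger"`` applies the Hellinger transform to Y before
    centring.  ``scaling`` 1 (distance triplot) or 2 (correlation triplot,
    default) controls how the singular values are shared between site and
    species scores.  Rank-deficient X is handled by the pseudo-inverse with a
    logged reduced rank.
    """
    Ydf = pd.DataFrame(Y)
    Xdf = pd.DataFrame(X)
    n = len(Ydf)
    if len(Xdf) != n:
        raise ValueError("Y and X must have the same number of sites")
    Ymat = Ydf.to_numpy(dtype=float)
    if transform == "hellinger":
        Ymat = hellinger(Ymat)
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform: {transform}")
    Yc = _center(Ymat)
    Xc = _center(Xdf.to_numpy(dtype=float))
    rank = int(np.linalg.matrix_rank(Xc))
    if rank < Xc.shape[1]:
        logger.warning(
            "constraint matrix rank-deficient: rank %d < %d columns",
            rank,
            Xc.shape[1],
        )
    if n <= rank:
        raise ValueError("need more sites than constraint rank")

    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    Yres = Yc - Yhat

    total = float((Yc**2).sum()) / (n - 1)
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > max(eig[0] if eig.size else 0, 1.0) * 1e-12
    eig, U, s, Vt = eig[keep], U[:, keep], s[keep], Vt[keep]
    k = len(eig)

    res_eig = np.linalg.svd(Yres, compute_uv=False) ** 2 / (n - 1)
    res_eig = res_eig[res_eig > total * 1e-12]

    r2 = float(eig.sum() / total)
    adj = adjusted_r2(r2, n, rank)

    axes = [f"RDA{i+1}" for i in range(k)]
    if scaling == 1:
        site = U * s  # sites in species-distance space
        spec = Vt.T
    elif scaling == 2:
        site = U * np.sqrt(s**2 / (n - 1))
        spec = Vt.T * np.sqrt(s**2 / (n - 1))
    else:
        raise ValueError("scaling must be 1 or 2")
    site_scores = pd.DataFrame(site, index=Ydf.index, columns=axes)
    species_scores = pd.DataFrame(spec, index=Ydf.columns, columns=axes)
    # driver arrows: correlations of each (centred) driver with the LC axes
    lc = U  # orthonormal axis coordinates
    bip = np.zeros((Xc.shape[1], k))
    for j in range(Xc.shape[1]):
        sx = Xc[:, j].std()
        if sx > 0:
            bip[j] = [np.corrcoef(Xc[:, j], lc[:, a])[0, 1] for a in range(k)]
    biplot_scores = pd.DataFrame(bip, index=Xdf.columns, columns=axes)

    return RDAResult(
        eigenvalues=eig,
        residual_eigenvalues=res_eig,
        total_inertia=total,
        proportion=eig / total,
        r2=r2,
        adj_r2=adj,
        rank=rank,
        site_scores=site_scores,
        species_scores=species_scores,
        biplot_scores=biplot_scores,
    )


def _first_eig_f(Yc: np.ndarray, Xc: np.ndarray, df_resid: int) -> float:
    """Pseudo-F of the leading constrained axis of Yc ~ Xc."""
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    s = np.linalg.svd(Yhat, compute_uv=False)
    lam1 = s[0] ** 2
    rss = float(((Yc - Yhat) ** 2).sum())
    return lam1 / (rss / df_resid)


def rda_axis_test(
    Y: pd.DataFrame | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    n_perm: int = 499,
    seed: int = 0,
    transform: str | None = None,
    max_axes: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential permutation test of each constrained axis.

    Axis k is tested marginally, conditioning on the preceding axes: the
    response and constraints are residualized on the first k-1 (observed) LC
    axes, rows of the residualized response are permuted, and the pseudo-F of
    the leading remaining axis is recomputed; p = (exceedances + 1)/(n_perm + 1).
    Returns (F, p) arrays over the constrained axes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fit = rda_fit(Y, X, transform=transform)
    Ymat = pd.DataFrame(Y).to_numpy(dtype=float)
    if transform == "hellinger":
        Ymat = hellinger(Ymat)
    Yc = _center(Ymat)
    Xc = _center(pd.DataFrame(X).to_numpy(dtype=float))
    n = len(Yc)
    df_resid = n - 1 - fit.rank
    k = len(fit.eigenvalues)
    if max_axes is not None:
        k = min(k, max_axes)
    # orthonormal LC axis coordinates of the observed fit
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    U, s, _ = np.linalg.svd(Xc @ B, full_matrices=False)
    U = U[:, : len(fit.eigenvalues)]

    rng = np.random.default_rng(seed)
    F = np.empty(k)
    p = np.empty(k)
    for axis in range(k):
        Z = U[:, :axis]
        if axis:
            proj = Z @ Z.T
            Yr = Yc - proj @ Yc
            Xr = Xc - proj @ Xc
        else:
            Yr, Xr = Yc, Xc
        F_obs = _first_eig_f(Yr, Xr, df_resid)
        count = 0
        for _ in range(n_perm):
            Yp = Yr[rng.permutation(n)]
            if _first_eig_f(Yp, Xr, df_resid) >= F_obs:
                count += 1
        F[axis] = F_obs
        p[axis] = (count + 1) / (n_perm + 1)
    return F, p
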