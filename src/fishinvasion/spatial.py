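"""Spatial autocorrelation machinery: Voronoi-adjacency weights, Moran's I
and the neighbourhood autocovariate.

Neighbourhoods are the Voronoi (Thiessen) adjacencies of the site
coordinates, obtained as the Delaunay-triangulation dual; degenerate
(collinear) geometries fall back to k-nearest-neighbour graphs.  Moran's I is
computed from the weights matrix with its analytic expectation -1/(n-1) and
either a normal-approximation or a permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.stats import norm

logger = logging.getLogger(__name__)


def voronoi_neighbors(coords: np.ndarray, knn_fallback: int = 4) -> list[set[int]]:
    """Adjacency sets of the Voronoi tessellation (Delaunay dual).

    Collinear/degenerate geometry falls back to symmetrized k-nearest
    neighbours (logged).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3:
        return [set(range(n)) - {i} for i in range(n)]
    try:
        tri = Delaunay(coords)
    except QhullError:
        logger.warning("degenerate geometry; falling back to %d-NN", knn_fallback)
        return _knn_neighbors(coords, knn_fallback)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    neighbors[i].add(int(j))
    return neighbors


def _knn_neighbors(coords: np.ndarray, k: int) -> list[set[int]]:
    tree = cKDTree(coords)
    k = min(k + 1, len(coords))
    _, idx = tree.query(coords, k=k)
    neighbors: list[set[int]] = [set() for _ in range(len(coords))]
    for i, row in enumerate(np.atleast_2d(idx)):
        for j in row:
            if j != i:
                neighbors[i].add(int(j))
                neighbors[int(j)].add(i)  # symmetrize
    return neighbors


def neighbor_weight_matrix(
    coords: np.ndarray,
    neighbors: list[set[int]] | None = None,
    scheme: str = "row",
    inverse_distance: bool = False,
) -> np.ndarray:
    """Spatial weights matrix from an adjacency structure.

    ``scheme``: "row" row-standardizes each site's weights to sum 1;
    "binary" leaves raw (0/1 or 1/d) weights.  ``inverse_distance`` weights
    each neighbour by 1/distance before standardization.
    """
    coords = np.asarray(coords, dtype=float)
    if neighbors is None:
        neighbors = voronoi_neighbors(coords)
    n = len(coords)
    w = np.zeros((n, n))
    for i, nb in enumerate(neighbors):
        for j in nb:
            if inverse_distance:
                d = np.linalg.norm(coords[i] - coords[j])
                w[i, j] = 1.0 / max(d, 1e-12)
            else:
                w[i, j] = 1.0
    if scheme == "row":
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    elif scheme != "binary":
        raise ValueError(f"unknown weights scheme: {scheme}")
    return w


@dataclass
class MoranResult:
    I: float
    expected_I: float
    z: float
    p_norm: float
    p_perm: float | None
    n_perm: int


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    n_perm: int = 0,
    seed: int = 0,
    two_sided: bool = True,
) -> MoranResult:
    """Moran's I with analytic expectation and normal / permutation p-values.

    The permutation p is two-sided around the analytic expectation
    -1/(n-1), so negative autocorrelation is detected as well.
    """
    z = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("Moran's I needs n >= 4")
    dev = z - z.mean()
    ss = float(dev @ dev)
    if ss == 0:
        raise ValueError("zero-variance values: Moran's I undefined")
    s0 = w.sum()
    i_obs = (n / s0) * float(dev @ w @ dev) / ss
    e_i = -1.0 / (n - 1)
    # normal approximation under randomization (Cliff & Ord moments)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (dev**4).sum() / ss**2
    var_i = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    zscore = (i_obs - e_i) / np.sqrt(var_i) if var_i > 0 else 0.0
    p_norm = 2 * norm.sf(abs(zscore)) if two_sided else norm.sf(zscore)

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(dev)
            i_p = (n / s0) * float(perm @ w @ perm) / ss
            if two_sided:
                if abs(i_p - e_i) >= abs(i_obs - e_i):
                    count += 1
            elif i_p >= i_obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
    return MoranResult(
        I=float(i_obs),
        expected_I=e_i,
        z=float(zscore),
        p_norm=float(p_norm),
        p_perm=p_perm,
        n_perm=n_perm,
    )


def build_autocovariate(
    y: np.ndarray, coords: np.ndarray, neighbors: list[set[int]] | None = None
) -> np.ndarray:
    """Per-site autocovariate: inverse-distance-weighted mean of the response
    over the site's Voronoi neighbours.

    Needs at least 3 non-collinear sites for the tessellation; degenerate
    geometry falls back to k-NN neighbourhoods (via :func:`voronoi_neighbors`).
    """
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(y) != len(coords):
        raise ValueError("y and coords must align")
    if len(y) < 3:
        raise ValueError("autocovariate needs >= 3 sites")
    if neighbors is None:
        neighbors = voronoi_neighbors(coords)
    out = np.empty(len(y))
    for i, nb in enumerate(neighbors):
        if not nb:
            out[i] = y.mean()
            continue
        idx = np.fromiter(nb, dtype=int)
        d = np.linalg.norm(coords[idx] - coords[i], axis=1)
        w = 1.0 / np.maximum(d, 1e-12)
        out[i] = float(np.average(y[idx], weights=w))
    return out
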