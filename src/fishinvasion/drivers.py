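"""Per-site driver covariate engineering.

Livestock-unit conversion, the bounded river-fragmentation index over
reachable migration barriers, inverse-distance-weighted interpolation of
point-monitored covariates, radius aggregation of fine-scale fields, and a
composite eutrophication proxy from seven water-quality parameters.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import EutrophicationConfig, FragmentationConfig
from .rivers import BarrierSet, NetworkPosition, RiverNetwork

logger = logging.getLogger(__name__)

#: standard livestock-unit coefficients
LSU_WEIGHTS = {"poultry": 0.01, "cattle": 1.0, "sheep": 0.1, "pigs": 0.5}


def livestock_units(
    poultry: float = 0, cattle: float = 0, sheep: float = 0, pigs: float = 0
) -> float:
    """Combine animal counts into livestock units (poultry 0.01, cattle 1,
    sheep 0.1, pigs 0.5)."""
    counts = {"poultry": poultry, "cattle": cattle, "sheep": sheep, "pigs": pigs}
    for name, n in counts.items():
        if n < 0:
            raise ValueError(f"negative {name} count: {n}")
    return sum(LSU_WEIGHTS[k] * v for k, v in counts.items())


def reachable_barriers(
    site: NetworkPosition,
    network: RiverNetwork,
    barriers: BarrierSet,
    cutoff: float = 10.0,
) -> list[tuple]:
    """Barriers within ``cutoff`` km of the site along the network (both
    directions), as (barrier, distance) pairs sorted by distance."""
    network.validate_position(site)
    out = []
    for b in barriers.barriers:
        d = network.distance(site, b.position)
        if d <= cutoff:
            out.append((b, d))
    out.sort(key=lambda t: t[1])
    return out


def fragmentation_index(
    reachable: list[tuple], config: FragmentationConfig | None = None
) -> float:
    """Bounded fragmentation score (2/pi) * arctan(sum category/distance).

    0 for no reachable barriers (least fragmented); approaches 1 as barriers
    get closer or more severe.  Distances are floored at a configured epsilon
    so a barrier sitting on the site stays finite.  Alternative aggregation
    modes: "nearest" uses only the closest barrier; "mean_max" uses
    max-category / mean-distance.
    """
    cfg = config or FragmentationConfig()
    if not reachable:
        return 0.0
    cats = np.array([b.category for b, _ in reachable], dtype=float)
    dists = np.array([max(d, cfg.min_distance_km) for _, d in reachable])
    if cfg.mode == "sum":
        arg = float(np.sum(cats / dists))
    elif cfg.mode == "nearest":
        i = int(np.argmin(dists))
        arg = cats[i] / dists[i]
    elif cfg.mode == "mean_max":
        arg = float(cats.max() / dists.mean())
    else:
        raise ValueError(f"unknown fragmentation mode: {cfg.mode}")
    return (2.0 / math.pi) * math.atan(arg)


def fragmentation_summary(
    site: NetworkPosition,
    network: RiverNetwork,
    barriers: BarrierSet,
    config: FragmentationConfig | None = None,
) -> dict:
    """The three fragmentation variables used as site covariates: reachable
    barrier count, their mean network distance, and the bounded index."""
    cfg = config or FragmentationConfig()
    reach = reachable_barriers(site, network, barriers, cfg.cutoff_km)
    return {
        "n_reachable": len(reach),
        "mean_distance": float(np.mean([d for _, d in reach])) if reach else float("nan"),
        "index": fragmentation_index(reach, cfg),
    }


def interpolate_driver(
    sample_coords: np.ndarray,
    sample_values: np.ndarray,
    site_coords: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Deterministic inverse-distance-weighted interpolation.

    Exact at sample locations; a single sample yields a constant surface.
    """
    sample_coords = np.atleast_2d(np.asarray(sample_coords, dtype=float))
    sample_values = np.asarray(sample_values, dtype=float)
    site_coords = np.atleast_2d(np.asarray(site_coords, dtype=float))
    if len(sample_coords) == 0:
        raise ValueError("at least one sample point is required")
    d = np.sqrt(
        ((site_coords[:, None, :] - sample_coords[None, :, :]) ** 2).sum(axis=2)
    )
    out = np.empty(len(site_coords))
    exact = d < 1e-12
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    for i in range(len(site_coords)):
        hit = np.flatnonzero(exact[i])
        if hit.size:
            out[i] = sample_values[hit[0]]
        else:
            out[i] = np.average(sample_values, weights=w[i])
    return out


def aggregate_radius(
    point_coords: np.ndarray,
    point_values: np.ndarray,
    site: np.ndarray,
    radius: float = 10.0,
    stat: str = "mean",
) -> float:
    """Aggregate a fine-scale field over a disc of ``radius`` km around a site.

    ``stat`` is one of mean, min, max, sum_density (sum divided by the disc
    area, km^-2).  NaN (logged) when no points fall inside the radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(np.atleast_2d(point_coords))
    idx = tree.query_ball_point(np.asarray(site, dtype=float), r=radius)
    if not idx:
        logger.warning("no points within %.1f km of site %s", radius, site)
        return float("nan")
    vals = np.asarray(point_values, dtype=float)[idx]
    if stat == "mean":
        return float(vals.mean())
    if stat == "min":
        return float(vals.min())
    if stat == "max":
        return float(vals.max())
    if stat == "sum_density":
        return float(vals.sum() / (math.pi * radius**2))
    raise ValueError(f"unknown stat: {stat}")


def eutrophication_proxy(
    stations: pd.DataFrame, config: EutrophicationConfig | None = None
) -> pd.Series:
    """Composite 0-100 water-quality score per station; high = clean.

    Each of the seven parameters (oxygen saturation, BOD, COD, NH4, NO3,
    total P, E. coli) is scored by linear interpolation between its pristine
    (score 100) and degraded (score 0) reference concentration, clipped to
    [0, 100]; the station index is the mean of the available subscores.  A
    station with all parameters missing gets NaN.
    """
    cfg = config or EutrophicationConfig()
    missing = [p for p in cfg.references if p not in stations.columns]
    if missing:
        raise ValueError(f"stations table missing parameters: {missing}")
    subscores = pd.DataFrame(index=stations.index)
    for param, (pristine, degraded) in cfg.references.items():
        x = stations[param].astype(float)
        score = 100.0 * (x - degraded) / (pristine - degraded)
        subscores[param] = score.clip(0.0, 100.0)
    return subscores.mean(axis=1, skipna=True)
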