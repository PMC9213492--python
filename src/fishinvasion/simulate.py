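"""Synthetic landscapes, species pools, communities and barrier networks.

The generators reproduce the statistical structure the downstream analyses
assume: driver fields with deterministic lowland/upland gradients plus
spatially autocorrelated residuals, a species pool of natives and exotics with
Gaussian niche responses (exotics biased toward warm, nutrient-enriched
lowland optima), Moyle-class abundance sampling with overdispersion, and
Poisson-placed categorized barriers on a dendritic river network.  Every
generator is deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import (
    BarrierConfig,
    CommunityConfig,
    LandscapeConfig,
    RiverConfig,
    SpeciesPoolConfig,
    config_hash,
)
from .rivers import Barrier, BarrierSet, NetworkPosition, RiverNetwork, dendritic_network

logger = logging.getLogger(__name__)


@dataclass
class SpeciesSpec:
    """Niche definition of one species.

    ``niche_optimum``/``niche_breadth`` map driver names to the optimum and
    Gaussian breadth of the response; drivers absent from the maps do not
    constrain the species (infinite breadth).
    """

    name: str
    origin: str  # "native" | "exotic"
    niche_optimum: dict[str, float] = field(default_factory=dict)
    niche_breadth: dict[str, float] = field(default_factory=dict)
    body_size_class: str = "medium"  # small | medium | large
    max_expected_abundance: float = 500.0

    def __post_init__(self):
        if self.origin not in ("native", "exotic"):
            raise ValueError(f"origin must be native/exotic, got {self.origin}")
        for d, b in self.niche_breadth.items():
            if b <= 0:
                raise ValueError(f"niche_breadth must be > 0 ({d}: {b})")

    def expected_abundance(self, drivers: pd.DataFrame) -> np.ndarray:
        """Gaussian niche response over the constrained drivers, per site."""
        log_resp = np.zeros(len(drivers))
        for d, opt in self.niche_optimum.items():
            if d not in drivers.columns:
                continue
            b = self.niche_breadth.get(d)
            if b is None:
                continue
            z = (drivers[d].to_numpy() - opt) / b
            log_resp -= 0.5 * z**2
        return self.max_expected_abundance * np.exp(log_resp)


def gaussian_random_field(
    coords: np.ndarray, sac_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-variance GRF with exponential covariance exp(-d/range)."""
    d = cdist(coords, coords)
    cov = np.exp(-d / sac_range)
    # jitter for numerical positive-definiteness of the Cholesky factor
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(len(coords))


def generate_landscape(config: LandscapeConfig) -> pd.DataFrame:
    """Generate a site table: coordinates, altitude and one column per driver.

    Each driver is ``intercept + cx*x + cy*y + ca*altitude`` plus
    ``noise_sd`` times a unit GRF with correlation length ``sac_range``.
    Altitude is generated first so other drivers can load on it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    x = rng.uniform(0, config.extent[0], config.n_sites)
    y = rng.uniform(0, config.extent[1], config.n_sites)
    coords = np.column_stack([x, y])
    table = pd.DataFrame(
        {"site_id": [f"S{i:04d}" for i in range(config.n_sites)], "x_km": x, "y_km": y}
    )

    def trend(name: str, altitude: np.ndarray | None) -> np.ndarray:
        c0, cx, cy, ca = config.driver_gradients.get(name, (0.0, 0.0, 0.0, 0.0))
        out = c0 + cx * x + cy * y
        if altitude is not None:
            out = out + ca * altitude
        return out

    # altitude first; it feeds the other drivers' trends
    order = list(config.driver_gradients)
    if "altitude" in order:
        order.remove("altitude")
        order.insert(0, "altitude")
    altitude = None
    for name in order:
        sd = config.noise_sd.get(name, 0.0)
        values = trend(name, altitude)
        if sd > 0:
            values = values + sd * gaussian_random_field(coords, config.sac_range, rng)
        else:
            # keep the stream position identical whether or not noise is used
            rng.standard_normal(config.n_sites)
        table[name] = values
        if name == "altitude":
            altitude = table["altitude"].to_numpy()
    logger.info(
        "generated landscape: %d sites, seed=%d, config=%s",
        config.n_sites,
        config.seed,
        config_hash(config),
    )
    return table


def generate_species_pool(
    n_native: int,
    n_exotic: int,
    seed: int = 0,
    config: SpeciesPoolConfig | None = None,
    landscape: pd.DataFrame | None = None,
) -> list[SpeciesSpec]:
    """Species pool with exotics biased toward lowland (warm, enriched) optima.

    Optima are drawn in the units of the landscape's driver fields: natives
    uniformly across mean +/- 1.5 sd of each of their niche drivers, exotics
    centred ``exotic_bias`` sd above the mean of theirs (the low-altitude end
    of every default gradient).  Altitude optima are recorded for both origins
    so the low-altitude bias of exotics is an explicit, testable property.
    """
    if n_native < 0 or n_exotic < 0:
        raise ValueError("species counts must be >= 0")
    cfg = config or SpeciesPoolConfig(n_native=n_native, n_exotic=n_exotic, seed=seed)
    rng = np.random.default_rng(seed)

    # reference scale for optima: landscape moments if given, else the default
    # scenario's nominal means/sds
    def moments(driver: str) -> tuple[float, float]:
        if landscape is not None and driver in landscape.columns:
            col = landscape[driver]
            return float(col.mean()), float(col.std())
        nominal = {
            "altitude": (700.0, 400.0),
            "temperature": (11.5, 3.0),
            "precipitation": (1000.0, 200.0),
            "drought": (37.0, 8.0),
            "eutrophication": (36.0, 16.0),
        }
        return nominal.get(driver, (0.0, 1.0))

    sizes = ["small", "medium", "large"]
    pool: list[SpeciesSpec] = []
    for i in range(n_native):
        opt, br = {}, {}
        mu_a, sd_a = moments("altitude")
        alt_opt = float(rng.uniform(mu_a - 1.5 * sd_a, mu_a + 1.5 * sd_a))
        if cfg.native_altitude_niche:
            opt["altitude"] = alt_opt
            br["altitude"] = 2.0 * sd_a * cfg.niche_breadth_factor
        for d in cfg.native_niche_drivers:
            mu, sd = moments(d)
            opt[d] = float(rng.uniform(mu - 1.5 * sd, mu + 1.5 * sd))
            br[d] = 1.5 * sd * cfg.niche_breadth_factor
        pool.append(
            SpeciesSpec(
                name=f"native_{i:02d}",
                origin="native",
                niche_optimum=opt,
                niche_breadth=br,
                body_size_class=sizes[rng.integers(0, 3)],
                max_expected_abundance=cfg.max_expected_abundance,
            )
        )
    for i in range(n_exotic):
        opt, br = {}, {}
        mu_a, sd_a = moments("altitude")
        # lowland bias: optimum below the mean altitude
        alt_opt = float(rng.normal(mu_a - cfg.exotic_bias * sd_a, 0.5 * sd_a))
        if cfg.exotic_altitude_niche:
            opt["altitude"] = alt_opt
            br["altitude"] = 2.0 * sd_a * cfg.niche_breadth_factor
        for d in cfg.exotic_niche_drivers:
            mu, sd = moments(d)
            # lowland end = high temperature / high eutrophication
            opt[d] = float(rng.normal(mu + cfg.exotic_bias * sd, 0.5 * sd))
            br[d] = (
                cfg.exotic_breadth_scale.get(d, 1.0) * sd * cfg.niche_breadth_factor
            )
        pool.append(
            SpeciesSpec(
                name=f"exotic_{i:02d}",
                origin="exotic",
                niche_optimum=opt,
                niche_breadth=br,
                body_size_class=sizes[rng.integers(0, 3)],
                max_expected_abundance=cfg.max_expected_abundance,
            )
        )
    return pool


def abundance_to_moyle(abundance: np.ndarray, breakpoints) -> np.ndarray:
    """Map realized abundances to Moyle classes 0 (absent) .. len(breakpoints)."""
    bp = np.asarray(breakpoints, dtype=float)
    return np.searchsorted(bp, abundance, side="right").astype(int)


def sample_communities(
    sites: pd.DataFrame,
    pool: list[SpeciesSpec],
    seed: int = 0,
    config: CommunityConfig | None = None,
) -> pd.DataFrame:
    """Sample a long-format community table (site_id, species, moyle_class).

    Expected abundance is the Gaussian niche response; realized abundance
    multiplies it by gamma noise with unit mean and variance ``dispersion``
    (negative-binomial-style overdispersion), then is binned to Moyle classes
    by the configured breakpoints.
    """
    if len(sites) == 0 or len(pool) == 0:
        raise ValueError("sites and species pool must be non-empty")
    cfg = config or CommunityConfig(seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for sp in pool:
        lam = sp.expected_abundance(sites)
        if cfg.dispersion > 0:
            shape = 1.0 / cfg.dispersion
            noise = rng.gamma(shape, scale=cfg.dispersion, size=len(sites))
            realized = lam * noise
        else:
            realized = lam
        classes = abundance_to_moyle(realized, cfg.moyle_breakpoints)
        rows.append(
            pd.DataFrame(
                {
                    "site_id": sites["site_id"].to_numpy(),
                    "species": sp.name,
                    "origin": sp.origin,
                    "body_size_class": sp.body_size_class,
                    "moyle_class": classes,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    logger.info("sampled communities: %d records, seed=%d", len(out), seed)
    return out


def generate_river(config: RiverConfig) -> RiverNetwork:
    """Synthetic dendritic binary-tree river network with random edge lengths."""
    rng = np.random.default_rng(config.seed)
    n_edges = 2 ** (config.depth + 1) - 2
    lo, hi = config.edge_length_km
    lengths = rng.uniform(lo, hi, n_edges)
    return dendritic_network(config.depth, lengths)


def generate_barriers(network: RiverNetwork, config: BarrierConfig) -> BarrierSet:
    """Place Poisson(density x length) barriers per edge with categorical types."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.category_probs, dtype=float)
    barriers = []
    for u, v, data in sorted(network.graph.edges(data=True)):
        length = data["length"]
        k = rng.poisson(config.density_per_km * length)
        offsets = rng.uniform(0, length, k)
        cats = rng.choice([1, 2, 3, 4], size=k, p=probs)
        for off, cat in zip(offsets, cats):
            barriers.append(Barrier(NetworkPosition(u, v, float(off)), int(cat)))
    return BarrierSet(network, barriers)
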