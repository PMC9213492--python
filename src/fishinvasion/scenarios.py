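"""Canonical synthetic scenarios used by the tests and the acceptance runs.

Three study designs, all built from the standard generators:

* ``default_config`` — the realistic landscape: driver fields share the
  lowland/upland gradient (warm, nutrient-enriched, farmed lowlands), exotics
  prefer lowlands, so drivers are mutually correlated as in real surveys.
* ``planted_recovery_config`` — parameter-recovery design: eutrophication and
  temperature are generated as independent spatial fields (no altitude
  loading) and exotic niches load on those two drivers only, with
  eutrophication given the stronger effect; a correct modelling chain must
  rank them at the top of the variable-importance scores with positive
  directions.
* ``planted_sac_dataset`` — residual-autocorrelation design: a response built
  from two drivers plus a spatially smooth residual field that no driver can
  absorb, which the autocovariate refit must soak up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import LandscapeConfig, PipelineConfig
from .simulate import gaussian_random_field, generate_landscape


def default_config(seed: int = 0, n_sites: int = 400) -> PipelineConfig:
    cfg = PipelineConfig().reseed(seed)
    cfg.landscape.n_sites = n_sites
    return cfg


def planted_recovery_config(seed: int = 0, n_sites: int = 300) -> PipelineConfig:
    """Exotic abundance driven by eutrophication (stronger) and temperature."""
    cfg = PipelineConfig().reseed(seed)
    cfg.landscape.n_sites = n_sites
    # decouple the planted drivers from the altitude gradient so the effect
    # is attributable: pure intercept + spatially correlated field
    cfg.landscape.driver_gradients["eutrophication"] = (36.0, 0.0, 0.0, 0.0)
    cfg.landscape.driver_gradients["temperature"] = (11.5, 0.0, 0.0, 0.0)
    cfg.landscape.noise_sd["eutrophication"] = 16.0
    cfg.landscape.noise_sd["temperature"] = 3.0
    cfg.species.exotic_niche_drivers = ("eutrophication", "temperature")
    cfg.species.exotic_altitude_niche = False
    # natives form a broad, weakly structured background community
    cfg.species.native_niche_drivers = ()
    cfg.species.native_altitude_niche = True
    cfg.species.niche_breadth_factor = 2.0
    # optima beyond the upper end of the observed fields: the planted effects
    # are monotone increasing (a positive direction), not bell-shaped
    cfg.species.exotic_bias = 2.5
    # eutrophication sharper than temperature: the stronger planted effect
    cfg.species.exotic_breadth_scale = {"eutrophication": 0.7, "temperature": 1.3}
    return cfg


def planted_sac_dataset(
    seed: int = 0,
    n_sites: int = 300,
    sac_sd: float = 0.8,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """(X, y, coords) with a smooth spatial residual planted in the response.

    y = f(eutrophication, temperature) + GRF(sac_range) * sac_sd + white
    noise; the GRF term is independent of every column of X, so it shows up
    as residual spatial autocorrelation that only the autocovariate can
    absorb.
    """
    lc = LandscapeConfig(n_sites=n_sites, seed=seed)
    sites = generate_landscape(lc)
    rng = np.random.default_rng(seed + 1)
    coords = sites[["x_km", "y_km"]].to_numpy()
    X = sites[
        ["eutrophication", "temperature", "precipitation", "livestock", "forest_cover"]
    ].copy()
    z = (X - X.mean()) / X.std()
    signal = 1.0 * z["eutrophication"] + 0.6 * z["temperature"]
    sac = gaussian_random_field(coords, lc.sac_range, rng) * sac_sd
    y = signal.to_numpy() + sac + rng.normal(0, noise_sd, n_sites)
    return X, y, coords
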