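import numpy as np
import pandas as pd
import pytest

from fishinvasion import metrics, pipeline
from fishinvasion.config import LandscapeConfig, PipelineConfig
from fishinvasion.simulate import generate_landscape


@pytest.fixture(scope="session")
def small_landscape() -> pd.DataFrame:
    return generate_landscape(LandscapeConfig(n_sites=120, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """Simulated dataset with merged drivers + invasion degree (session-wide)."""
    cfg = PipelineConfig().reseed(5)
    cfg.landscape.n_sites = 250
    sites, pool, community = pipeline.simulate_dataset(cfg)
    community = metrics.add_abundance(community, cfg.moyle)
    invasion = metrics.invasion_degree_table(community)
    merged = sites.merge(invasion, on="site_id").dropna(subset=["invasion_degree"])
    merged = merged.reset_index(drop=True)
    return cfg, merged, community


@pytest.fixture()
def toy_community() -> pd.DataFrame:
    """Hand-written 3-site community with known tallies."""
    rows = [
        # site A: native 8, exotic 8 -> degree 0.5
        ("A", "chub", "native", 3, "small"),
        ("A", "carp", "exotic", 3, "small"),
        # site B: natives only
        ("B", "chub", "native", 2, "medium"),
        ("B", "trout", "native", 1, "small"),
        # site C: exotic only
        ("C", "carp", "exotic", 4, "large"),
        ("C", "chub", "native", 0, "small"),
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "species", "origin", "moyle_class", "body_size_class"]
    )
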