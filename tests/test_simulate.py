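"""Synthetic-data generators: determinism, planted structure, distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson, spearmanr

from fishinvasion import metrics
from fishinvasion.config import (
    BarrierConfig,
    CommunityConfig,
    LandscapeConfig,
    RiverConfig,
)
from fishinvasion.simulate import (
    abundance_to_moyle,
    generate_barriers,
    generate_landscape,
    generate_river,
    generate_species_pool,
    sample_communities,
)
from fishinvasion.spatial import morans_i, neighbor_weight_matrix
from fishinvasion.simulate import SpeciesSpec


class TestLandscape:
    def test_zero_noise_is_deterministic_function_of_coordinates(self):
        cfg = LandscapeConfig(n_sites=50, seed=3)
        cfg.noise_sd = {k: 0.0 for k in cfg.noise_sd}
        table = generate_landscape(cfg)
        c0, cx, cy, ca = cfg.driver_gradients["altitude"]
        expected_alt = c0 + cx * table["x_km"] + cy * table["y_km"]
        np.testing.assert_allclose(table["altitude"], expected_alt)
        c0, cx, cy, ca = cfg.driver_gradients["temperature"]
        np.testing.assert_allclose(
            table["temperature"],
            c0 + cx * table["x_km"] + cy * table["y_km"] + ca * table["altitude"],
        )

    def test_same_seed_is_bit_identical(self):
        cfg = LandscapeConfig(n_sites=40, seed=9)
        pd.testing.assert_frame_equal(generate_landscape(cfg), generate_landscape(cfg))

    def test_different_seed_differs(self):
        a = generate_landscape(LandscapeConfig(n_sites=40, seed=1))
        b = generate_landscape(LandscapeConfig(n_sites=40, seed=2))
        assert not np.allclose(a["altitude"], b["altitude"])

    def test_generated_field_is_spatially_autocorrelated(self):
        """A 50-km-range field over 400 sites on 200x200 km has Moran's I
        significantly above its expectation (999 permutations)."""
        cfg = LandscapeConfig(n_sites=400, seed=21, sac_range=50.0)
        table = generate_landscape(cfg)
        coords = table[["x_km", "y_km"]].to_numpy()
        w = neighbor_weight_matrix(coords)
        field = table["eutrophication"].to_numpy()
        res = morans_i(field, w, n_perm=999, seed=0)
        assert res.I > 0
        assert res.p_perm < 0.05

    @pytest.mark.parametrize("bad", [dict(n_sites=1), dict(sac_range=0.0)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_landscape(LandscapeConfig(**bad))


class TestSpeciesPool:
    def test_empty_pool(self):
        assert generate_species_pool(0, 0, seed=0) == []

    def test_count_conservation(self):
        pool = generate_species_pool(5, 3, seed=0)
        assert len(pool) == 8
        assert sum(s.origin == "exotic" for s in pool) == 3

    def test_exotics_biased_to_low_altitude(self):
        """Monte Carlo over 100 seeds: exotic altitude optima sit below the
        native ones under the default bias."""
        diffs = []
        for seed in range(100):
            pool = generate_species_pool(6, 6, seed=seed)
            nat = np.mean(
                [s.niche_optimum["altitude"] for s in pool if s.origin == "native"]
            )
            exo = np.mean(
                [s.niche_optimum["altitude"] for s in pool if s.origin == "exotic"]
            )
            diffs.append(exo - nat)
        assert np.mean(diffs) < 0
        assert np.mean(np.array(diffs) < 0) > 0.8

    def test_nonpositive_breadth_rejected(self):
        with pytest.raises(ValueError):
            SpeciesSpec(
                name="x",
                origin="native",
                niche_optimum={"temperature": 10},
                niche_breadth={"temperature": 0.0},
            )


class TestCommunities:
    def test_distant_species_absent_everywhere(self, small_landscape):
        sp = SpeciesSpec(
            name="ghost",
            origin="exotic",
            niche_optimum={"temperature": 1e9},
            niche_breadth={"temperature": 1.0},
        )
        comm = sample_communities(small_landscape, [sp], seed=0)
        assert (comm["moyle_class"] == 0).all()

    def test_site_at_optimum_attains_max_class_without_noise(self, small_landscape):
        row = small_landscape.iloc[0]
        sp = SpeciesSpec(
            name="local",
            origin="native",
            niche_optimum={"temperature": float(row["temperature"])},
            niche_breadth={"temperature": 1.0},
            max_expected_abundance=500.0,
        )
        cfg = CommunityConfig(dispersion=0.0)
        comm = sample_communities(small_landscape, [sp], seed=0, config=cfg)
        at_site = comm[comm["site_id"] == row["site_id"]]
        assert int(at_site["moyle_class"].iloc[0]) == 5

    def test_moyle_binning_breakpoints(self):
        out = abundance_to_moyle(np.array([0.0, 0.5, 1.0, 5.0, 300.0]), (1, 4, 16, 64, 256))
        np.testing.assert_array_equal(out, [0, 0, 1, 2, 5])

    def test_lowland_exotic_drives_invasion_down_with_altitude(self):
        """With a single low-altitude exotic, the downstream per-site invasion
        degree is negatively rank-correlated with altitude (n = 400)."""
        cfg = LandscapeConfig(n_sites=400, seed=31)
        sites = generate_landscape(cfg)
        alt = sites["altitude"]
        pool = [
            SpeciesSpec(
                name="bg",
                origin="native",
                niche_optimum={},
                niche_breadth={},
                max_expected_abundance=100.0,
            ),
            SpeciesSpec(
                name="low_exo",
                origin="exotic",
                niche_optimum={"altitude": float(alt.min())},
                niche_breadth={"altitude": float(alt.std())},
                max_expected_abundance=500.0,
            ),
        ]
        comm = sample_communities(sites, pool, seed=1)
        comm = metrics.add_abundance(comm)
        inv = metrics.invasion_degree_table(comm)
        merged = sites.merge(inv, on="site_id").dropna(subset=["invasion_degree"])
        rho = spearmanr(merged["altitude"], merged["invasion_degree"])
        assert rho.statistic < 0
        assert rho.pvalue < 0.01

    def test_determinism(self, small_landscape):
        pool = generate_species_pool(3, 2, seed=4)
        a = sample_communities(small_landscape, pool, seed=7)
        b = sample_communities(small_landscape, pool, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_inputs_rejected(self, small_landscape):
        with pytest.raises(ValueError):
            sample_communities(small_landscape, [], seed=0)


class TestBarriers:
    def test_zero_density_empty(self):
        net = generate_river(RiverConfig(depth=3, seed=0))
        assert len(generate_barriers(net, BarrierConfig(density_per_km=0.0))) == 0

    def test_degenerate_category_probs(self):
        net = generate_river(RiverConfig(depth=3, seed=0))
        bs = generate_barriers(
            net, BarrierConfig(density_per_km=0.5, category_probs=(1, 0, 0, 0), seed=1)
        )
        assert len(bs) > 0
        assert all(b.category == 1 for b in bs.barriers)

    def test_malformed_probs_rejected(self):
        net = generate_river(RiverConfig(depth=2, seed=0))
        with pytest.raises(ValueError):
            generate_barriers(net, BarrierConfig(category_probs=(0.5, 0.5, 0.5, 0.5)))

    def test_counts_follow_poisson_over_seeds(self):
        """Counts across 200 seeds stay inside the Poisson 99% interval of
        density x network length at the nominal rate."""
        net = generate_river(RiverConfig(depth=6, seed=2))
        lam = 0.1 * net.total_length()
        lo, hi = poisson.interval(0.99, lam)
        counts = [
            len(generate_barriers(net, BarrierConfig(density_per_km=0.1, seed=s)))
            for s in range(200)
        ]
        inside = np.mean([(lo <= c <= hi) for c in counts])
        assert inside >= 0.95
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / 200)
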