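"""Driver engineering: LSU, barriers, fragmentation, IDW, radius stats."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishinvasion.config import EutrophicationConfig, FragmentationConfig
from fishinvasion.drivers import (
    aggregate_radius,
    eutrophication_proxy,
    fragmentation_index,
    interpolate_driver,
    livestock_units,
    reachable_barriers,
)
from fishinvasion.rivers import (
    Barrier,
    BarrierSet,
    NetworkPosition,
    RiverNetwork,
    dendritic_network,
)


class TestLivestockUnits:
    def test_zero(self):
        assert livestock_units(0, 0, 0, 0) == 0.0

    def test_hundred_poultry_equal_one_cattle(self):
        assert livestock_units(poultry=100) == livestock_units(cattle=1) == 1.0

    def test_linear_arithmetic(self):
        assert livestock_units(100, 10, 20, 4) == pytest.approx(15.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            livestock_units(cattle=-1)

    @given(
        a=st.floats(0, 1e4), b=st.floats(0, 1e4), s=st.floats(1, 10)
    )
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, a, b, s):
        assert livestock_units(poultry=a + b) == pytest.approx(
            livestock_units(poultry=a) + livestock_units(poultry=b)
        )
        assert livestock_units(pigs=s * a) == pytest.approx(s * livestock_units(pigs=a))


def _single_reach(length=20.0) -> RiverNetwork:
    g = nx.Graph()
    g.add_edge(0, 1, length=length)
    return RiverNetwork(g)


class TestReachableBarriers:
    def test_no_barriers(self):
        net = _single_reach()
        site = NetworkPosition(0, 1, 2.0)
        assert reachable_barriers(site, net, BarrierSet(net, [])) == []

    def test_single_barrier_distance(self):
        net = _single_reach()
        bs = BarrierSet(net, [Barrier(NetworkPosition(0, 1, 5.0), 2)])
        site = NetworkPosition(0, 1, 0.0)
        out = reachable_barriers(site, net, bs, cutoff=10.0)
        assert len(out) == 1
        assert out[0][1] == pytest.approx(5.0)

    def test_off_network_site_rejected(self):
        net = _single_reach()
        with pytest.raises(ValueError):
            reachable_barriers(NetworkPosition(3, 4, 1.0), net, BarrierSet(net, []))

    def test_matches_breadth_first_oracle(self):
        """Dendritic toy network, 6 barriers: set equals an exhaustive
        path-search oracle built on an expanded node graph."""
        net = dendritic_network(2, [4.0, 6.0, 3.0, 5.0, 7.0, 2.0])
        barrier_specs = [
            (0, 1, 1.0, 1),
            (0, 1, 3.5, 4),
            (0, 2, 2.0, 2),
            (1, 3, 1.5, 3),
            (1, 4, 4.0, 2),
            (2, 6, 0.5, 1),
        ]
        barriers = BarrierSet(
            net, [Barrier(NetworkPosition(u, v, o), c) for u, v, o, c in barrier_specs]
        )
        site = NetworkPosition(1, 3, 0.5)
        cutoff = 8.0
        got = {
            (b.position.u, b.position.v, b.position.offset): d
            for b, d in reachable_barriers(site, net, barriers, cutoff)
        }

        # oracle: split every edge at its marked points and run Dijkstra
        g = nx.Graph()
        points: dict = {}
        marks: dict = {}
        for u, v, o, _ in barrier_specs:
            marks.setdefault((u, v), []).append(("b", u, v, o))
        marks.setdefault((site.u, site.v), []).append(("s", site.u, site.v, site.offset))
        for u, v, data in net.graph.edges(data=True):
            chain = sorted(
                marks.get((u, v), []) + marks.get((v, u), []), key=lambda t: t[3]
            )
            prev, prev_off = f"n{u}", 0.0
            for kind, mu, mv, off in chain:
                node = (kind, mu, mv, off)
                g.add_edge(prev, node, weight=off - prev_off)
                prev, prev_off = node, off
            g.add_edge(prev, f"n{v}", weight=data["length"] - prev_off)
        dist = nx.single_source_dijkstra_path_length(
            g, ("s", site.u, site.v, site.offset), weight="weight"
        )
        expected = {
            (mu, mv, off): d
            for (kind, mu, mv, off), d in (
                (k, v) for k, v in dist.items() if isinstance(k, tuple)
            )
            if kind == "b" and d <= cutoff
        }
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k])


class TestFragmentationIndex:
    def test_empty_is_zero(self):
        assert fragmentation_index([]) == 0.0

    def test_closed_form_category4_at_1km(self):
        b = Barrier(NetworkPosition(0, 1, 1.0), 4)
        val = fragmentation_index([(b, 1.0)])
        assert val == pytest.approx((2 / math.pi) * math.atan(4.0), abs=1e-12)
        assert round(val, 3) == 0.844

    def test_zero_distance_floored(self):
        b = Barrier(NetworkPosition(0, 1, 0.0), 4)
        val = fragmentation_index([(b, 0.0)])
        assert val < 1.0
        assert val == pytest.approx(
            (2 / math.pi) * math.atan(4.0 / FragmentationConfig().min_distance_km)
        )

    @given(
        data=st.lists(
            st.tuples(st.integers(1, 4), st.floats(0.0, 10.0)), min_size=0, max_size=8
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_bounded_in_unit_interval(self, data):
        reach = [(Barrier(NetworkPosition(0, 1, 0.0), c), d) for c, d in data]
        val = fragmentation_index(reach)
        assert 0.0 <= val < 1.0
        assert (val == 0.0) == (len(reach) == 0)

    def test_monotone_in_category_and_distance(self):
        def idx(cat, dist):
            return fragmentation_index([(Barrier(NetworkPosition(0, 1, 0), cat), dist)])

        assert idx(1, 2.0) < idx(2, 2.0) < idx(3, 2.0) < idx(4, 2.0)
        assert idx(3, 1.0) > idx(3, 2.0) > idx(3, 8.0)

    def test_alternative_modes(self):
        b1 = (Barrier(NetworkPosition(0, 1, 0), 1), 1.0)
        b4 = (Barrier(NetworkPosition(0, 1, 0), 4), 3.0)
        nearest = fragmentation_index([b1, b4], FragmentationConfig(mode="nearest"))
        assert nearest == pytest.approx((2 / math.pi) * math.atan(1.0))
        mm = fragmentation_index([b1, b4], FragmentationConfig(mode="mean_max"))
        assert mm == pytest.approx((2 / math.pi) * math.atan(4.0 / 2.0))


class TestInterpolation:
    def test_single_sample_constant_surface(self):
        out = interpolate_driver([[0, 0]], [7.5], [[10, 10], [-3, 2]])
        np.testing.assert_allclose(out, 7.5)

    def test_exact_at_sample_locations(self):
        samples = np.array([[0.0, 0.0], [5.0, 5.0]])
        vals = np.array([1.0, 9.0])
        out = interpolate_driver(samples, vals, samples)
        np.testing.assert_allclose(out, vals)

    def test_linear_field_recovery(self):
        """100 samples of a linear field, IDW power 2: RMSE under 5% of range."""
        rng = np.random.default_rng(0)
        samples = rng.uniform(0, 100, size=(100, 2))
        truth = lambda p: 2.0 + 0.03 * p[:, 0] + 0.05 * p[:, 1]
        queries = rng.uniform(10, 90, size=(50, 2))
        est = interpolate_driver(samples, truth(samples), queries)
        rmse = np.sqrt(np.mean((est - truth(queries)) ** 2))
        field_range = truth(samples).max() - truth(samples).min()
        assert rmse < 0.05 * field_range

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            interpolate_driver(np.empty((0, 2)), [], [[0, 0]])


class TestAggregateRadius:
    def test_uniform_field_mean(self):
        pts = np.random.default_rng(1).uniform(0, 10, size=(50, 2))
        assert aggregate_radius(pts, np.full(50, 3.3), [5, 5], radius=20) == pytest.approx(3.3)

    def test_max_finds_peak(self):
        pts = np.array([[0, 0], [1, 1], [2, 2]])
        vals = np.array([1.0, 99.0, 2.0])
        assert aggregate_radius(pts, vals, [1, 1], radius=3, stat="max") == 99.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 50, size=(200, 2))
        vals = rng.normal(size=200)
        site = np.array([25.0, 25.0])
        radius = 12.0
        mask = np.linalg.norm(pts - site, axis=1) <= radius
        assert aggregate_radius(pts, vals, site, radius, "mean") == pytest.approx(
            vals[mask].mean()
        )
        assert aggregate_radius(pts, vals, site, radius, "min") == vals[mask].min()
        assert aggregate_radius(pts, vals, site, radius, "sum_density") == pytest.approx(
            vals[mask].sum() / (math.pi * radius**2)
        )

    def test_empty_disc_is_missing(self):
        pts = np.array([[100.0, 100.0]])
        assert np.isnan(aggregate_radius(pts, [1.0], [0, 0], radius=5))


class TestEutrophicationProxy:
    PARAMS = list(EutrophicationConfig().references)

    def _station(self, **overrides):
        cfg = EutrophicationConfig()
        row = {p: cfg.references[p][0] for p in self.PARAMS}  # pristine
        row.update(overrides)
        return pd.DataFrame([row])

    def test_pristine_reference_is_maximal(self):
        assert eutrophication_proxy(self._station()).iloc[0] == pytest.approx(100.0)

    def test_worsening_never_increases_score(self):
        cfg = EutrophicationConfig()
        base = eutrophication_proxy(self._station()).iloc[0]
        for p in self.PARAMS:
            pristine, degraded = cfg.references[p]
            mid = 0.5 * (pristine + degraded)
            worse = eutrophication_proxy(self._station(**{p: mid})).iloc[0]
            worst = eutrophication_proxy(self._station(**{p: degraded})).iloc[0]
            assert worse <= base
            assert worst <= worse

    def test_identical_stations_identical_scores(self):
        df = pd.concat([self._station(nh4=0.7), self._station(nh4=0.7)])
        scores = eutrophication_proxy(df)
        assert scores.iloc[0] == scores.iloc[1]

    def test_all_missing_station_is_missing(self):
        df = self._station()
        df.loc[:, :] = np.nan
        assert np.isnan(eutrophication_proxy(df).iloc[0])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            eutrophication_proxy(pd.DataFrame({"nh4": [1.0]}))
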