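"""Dependency-network topology, hub selection and overlap testing."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from gdnet.dependency import DependencyPair
from gdnet.io import GeneSet
from gdnet.network import (
    HubParams,
    build_network,
    degree_distribution,
    fit_power_law,
    main_component,
    overlap_test,
    read_network,
    select_hubs,
    write_network,
)


def _pairs(*edges):
    return [DependencyPair(u, v, 0.5, 0.01) for u, v in edges]


class TestBuild:
    def test_reciprocal_edges_allowed(self):
        net = build_network(_pairs(("B", "A"), ("A", "B")))
        assert net.number_of_nodes() == 2 and net.number_of_edges() == 2

    def test_empty(self):
        assert build_network([]).number_of_nodes() == 0

    def test_degree_conservation(self):
        net = build_network(_pairs(("a", "b"), ("c", "b"), ("d", "a")))
        assert sum(d for _, d in net.out_degree()) == 3
        assert sum(d for _, d in net.in_degree()) == 3

    def test_duplicate_directed_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_network(_pairs(("B", "A"), ("B", "A")))

    def test_edge_table_round_trip(self, tmp_path):
        net = build_network(_pairs(("B", "A"), ("C", "A")))
        write_network(net, tmp_path / "e.tsv", tmp_path / "n.tsv")
        back = read_network(tmp_path / "e.tsv")
        assert set(back.edges()) == set(net.edges())


class TestMainComponent:
    def test_largest_weak_component_kept(self):
        net = build_network(_pairs(("a", "b"), ("b", "c"), ("x", "y")))
        comp = main_component(net)
        assert set(comp.nodes()) == {"a", "b", "c"}

    def test_connected_net_is_identity(self):
        net = build_network(_pairs(("a", "b"), ("b", "c")))
        assert set(main_component(net).nodes()) == set(net.nodes())

    def test_tie_broken_by_smallest_gene_id(self):
        net = build_network(_pairs(("m", "n"), ("a", "b")))
        assert set(main_component(net).nodes()) == {"a", "b"}


class TestDegreeDistribution:
    def test_star_out_and_total(self):
        net = build_network(_pairs(*[("hub", f"leaf{i}") for i in range(4)]))
        assert dict(degree_distribution(net, "out")) == {4: 1, 0: 4}
        assert dict(degree_distribution(net, "total")) == {4: 1, 1: 4}
        mean_total = sum(k * f for k, f in degree_distribution(net, "total")) / 5
        assert mean_total == pytest.approx(2 * 4 / 5)

    def test_empty(self):
        assert degree_distribution(nx.DiGraph()) == []


class TestPowerLaw:
    def test_exact_law_recovered(self):
        dist = [(k, 1000 * k**-2) for k in range(1, 11)]
        dist = [(k, int(f)) for k, f in dist if int(f) == f]
        fit = fit_power_law([(k, 1000 // k**2) for k in (1, 2, 5, 10)])
        # frequencies 1000, 250, 40, 10 are exactly 1000 k^-2
        assert fit.exponent == pytest.approx(2.0, abs=1e-12)
        assert fit.correlation == pytest.approx(1.0, abs=1e-12)
        assert fit.r_square == pytest.approx(1.0, abs=1e-12)

    def test_flat_distribution(self):
        fit = fit_power_law([(1, 7), (2, 7), (4, 7)])
        assert fit.exponent == 0.0 and fit.r_square == 0.0

    def test_scale_invariance(self):
        base = [(1, 100), (2, 30), (3, 11), (6, 3)]
        scaled = [(k, 10 * f) for k, f in base]
        assert fit_power_law(base).exponent == pytest.approx(
            fit_power_law(scaled).exponent, abs=1e-12
        )

    def test_noisy_law_fits_well(self, rng):
        ks = np.arange(1, 30)
        freqs = np.maximum(1, np.round(500 * ks**-1.8 * rng.lognormal(0, 0.1, ks.size)))
        fit = fit_power_law(list(zip(ks, freqs.astype(int))))
        assert 0.8 <= fit.r_square <= 1.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_power_law([(1, 5), (2, 2)])


def _net_with_out_degrees(degrees):
    """Network on exactly len(degrees) nodes where node i has out-degree degrees[i]."""
    if max(degrees) > len(degrees) - 1:
        raise ValueError("degree sequence not realizable without extra nodes")
    names = [f"n{i:02d}" for i in range(len(degrees))]
    net = nx.DiGraph()
    net.add_nodes_from(names)
    for i, d in enumerate(degrees):
        targets = [names[j] for j in range(len(names)) if j != i][:d]
        net.add_edges_from((names[i], t) for t in targets)
    return net


class TestHubSelection:
    def test_descending_run_takes_top_fraction(self):
        net = _net_with_out_degrees([9, 8, 7, 6, 5, 4, 3, 2, 1, 0])
        hubs = select_hubs(net, HubParams(hub_fraction=0.20, min_out_degree=4))
        # 20% of 10 nodes = 2: the out-degree cutoff lands at 8
        assert hubs.members == {"n00", "n01"}

    def test_min_out_degree_floor(self):
        net = _net_with_out_degrees([3, 3, 3, 3])
        hubs = select_hubs(net, HubParams(hub_fraction=0.5, min_out_degree=4))
        assert hubs.members == set()

    def test_ties_never_split(self):
        net = _net_with_out_degrees([9, 5, 5, 5, 1, 0, 0, 0, 0, 0])
        hubs = select_hubs(net, HubParams(hub_fraction=0.20, min_out_degree=4))
        # taking degree >= 5 would select 4 nodes > 20% of 10, so cutoff is above 5
        assert hubs.members == {"n00"}

    def test_size_and_degree_invariants(self, rng):
        degrees = rng.integers(0, 12, size=40).tolist()
        net = _net_with_out_degrees(degrees)
        params = HubParams()
        hubs = select_hubs(net, params)
        assert len(hubs) <= params.hub_fraction * net.number_of_nodes()
        out_deg = dict(net.out_degree())
        assert all(out_deg[g] >= params.min_out_degree for g in hubs.members)
        # membership is monotone in out-degree
        if hubs.members:
            cutoff = min(out_deg[g] for g in hubs.members)
            assert all(g in hubs.members for g, d in out_deg.items() if d >= cutoff)

    def test_empty_net_rejected(self):
        with pytest.raises(ValueError):
            select_hubs(nx.DiGraph())


def brute_force_overlap_p(universe, a_size, b_size, observed):
    """Enumerate every draw of a_size elements; independent oracle."""
    items = list(range(universe))
    b = set(items[:b_size])
    total = hits = 0
    for draw in itertools.combinations(items, a_size):
        total += 1
        if len(b & set(draw)) >= observed:
            hits += 1
    return hits / total


class TestOverlap:
    def test_worked_example(self):
        universe = GeneSet("u", {f"g{i}" for i in range(10)})
        a = GeneSet("a", {"g0", "g1", "g2", "g3"})
        b = GeneSet("b", {"g0", "g1", "g2", "g3", "g4"})
        res = overlap_test(a, b, universe)
        assert res.overlap == 4
        assert res.p_value == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = GeneSet("u", {"a", "b", "c", "d"})
        res = overlap_test(GeneSet("x", {"a"}), GeneSet("y", {"b"}), universe)
        assert res.p_value == 1.0

    def test_degenerate_full_sets(self):
        u = GeneSet("u", {"a", "b"})
        res = overlap_test(u, u, u)
        assert res.overlap == 2 and res.p_value == pytest.approx(1.0)

    def test_outside_universe_rejected(self):
        u = GeneSet("u", {"a"})
        with pytest.raises(ValueError):
            overlap_test(GeneSet("x", {"z"}), GeneSet("y", {"a"}), u)

    @pytest.mark.parametrize("m,na,nb", [(6, 3, 2), (8, 4, 5), (12, 5, 6)])
    def test_matches_enumeration(self, m, na, nb):
        ids = [f"g{i}" for i in range(m)]
        universe = GeneSet("u", set(ids))
        b = GeneSet("b", set(ids[:nb]))
        for k in range(min(na, nb) + 1):
            a_members = set(ids[:k]) | set(ids[nb:nb + na - k])
            if len(a_members) != na:
                continue
            res = overlap_test(GeneSet("a", a_members), b, universe)
            assert res.p_value == pytest.approx(
                brute_force_overlap_p(m, na, nb, k), abs=1e-12
            )
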