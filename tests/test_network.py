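"""Graph construction, centralities against exhaustive oracles, hubs."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netpharm.network import (
    HubCriteria,
    build_bipartite,
    build_ppi,
    centralities,
    extract_hubs,
    intersect_networks,
    merge_networks,
)

# -- exhaustive oracles (independent of networkx) ----------------------------


def _all_shortest_paths_counts(g, s, t):
    """(number of shortest s-t paths, dict v -> number passing through v)."""
    if s == t:
        return 0, {}
    try:
        d = nx.shortest_path_length(g, s, t)
    except nx.NetworkXNoPath:
        return 0, {}
    paths = [p for p in nx.all_simple_paths(g, s, t, cutoff=d) if len(p) - 1 == d]
    through = {}
    for p in paths:
        for v in p[1:-1]:
            through[v] = through.get(v, 0) + 1
    return len(paths), through


def brute_betweenness(g):
    """Normalised betweenness by enumerating every shortest path."""
    n = g.number_of_nodes()
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        sigma, through = _all_shortest_paths_counts(g, s, t)
        if sigma == 0:
            continue
        for v, cnt in through.items():
            bc[v] += cnt / sigma
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    return {v: bc[v] * scale for v in g.nodes}


def brute_closeness(g):
    """Wasserman-Faust closeness from Floyd-Warshall distances."""
    n = g.number_of_nodes()
    dist = dict(nx.floyd_warshall(g))
    cc = {}
    for v in g.nodes:
        reach = [d for u, d in dist[v].items() if u != v and d < np.inf]
        if not reach or n == 1:
            cc[v] = 0.0
            continue
        r = len(reach)
        cc[v] = (r / sum(reach)) * (r / (n - 1))
    return cc


def brute_neighbor_degree(g):
    deg = dict(g.degree())
    return {
        v: (sum(deg[u] for u in g.neighbors(v)) / deg[v]) if deg[v] else 0.0
        for v in g.nodes
    }


# -- construction ------------------------------------------------------------


def test_bipartite_nodes_edges_and_kinds():
    g = build_bipartite(["c1", "c2"], {"c1": {"A", "B"}, "c2": {"B"}})
    assert g.number_of_nodes() == 4 and g.number_of_edges() == 3
    assert g.nodes["c1"]["kind"] == "compound" and g.nodes["B"]["kind"] == "target"
    assert not any(
        g.nodes[u]["kind"] == g.nodes[v]["kind"] for u, v in g.edges
    ), "bipartite: no compound-compound or target-target edge"


def test_bipartite_empty_mapping_gives_empty_network():
    g = build_bipartite(["c1"], {})
    assert g.number_of_nodes() == 0 and g.number_of_edges() == 0


def test_ppi_first_neighbor_expansion():
    edges = [("A", "B"), ("B", "C")]
    g = build_ppi({"A"}, edges, expand_neighbors=True)
    assert set(g.nodes) == {"A", "B"} and set(map(frozenset, g.edges)) == {
        frozenset({"A", "B"})
    }
    g2 = build_ppi({"A"}, edges, expand_neighbors=False)
    assert set(g2.nodes) == {"A"} and g2.number_of_edges() == 0


def test_ppi_orphan_seed_kept_isolated_with_warning():
    with pytest.warns(UserWarning, match="isolated"):
        g = build_ppi({"Z", "A"}, [("A", "B")], expand_neighbors=True)
    assert "Z" in g.nodes and g.degree["Z"] == 0


def test_ppi_drops_self_loops_and_duplicates():
    g = build_ppi({"A"}, [("A", "A"), ("A", "B"), ("B", "A")], expand_neighbors=True)
    assert g.number_of_edges() == 1


def test_ppi_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(4, 12))
        full = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        full = nx.relabel_nodes(full, {i: f"N{i}" for i in full.nodes})
        seeds = set(
            rng.choice(sorted(full.nodes), size=int(rng.integers(1, n)), replace=False)
        )
        g = build_ppi(seeds, list(full.edges), expand_neighbors=True)
        expected_nodes = set(seeds)
        for s in seeds:
            expected_nodes.update(full.neighbors(s))
        assert set(g.nodes) == expected_nodes
        expected_edges = {
            frozenset(e)
            for e in full.edges
            if e[0] in expected_nodes and e[1] in expected_nodes
        }
        assert {frozenset(e) for e in g.edges} == expected_edges


# -- intersection / merge ----------------------------------------------------


def _random_named_graph(rng, n, p):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})


def test_intersect_identity_commutative_idempotent():
    rng = np.random.default_rng(5)
    a = _random_named_graph(rng, 10, 0.4)
    b = _random_named_graph(rng, 12, 0.3)
    ab = intersect_networks(a, b)
    ba = intersect_networks(b, a)
    assert nx.utils.graphs_equal(ab, ba)
    assert nx.utils.graphs_equal(intersect_networks(a, a), a)
    assert nx.utils.graphs_equal(intersect_networks(ab, ab), ab)
    assert set(ab.nodes) <= set(a.nodes) and set(ab.nodes) <= set(b.nodes)


def test_intersect_equals_brute_force_set_intersection():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = _random_named_graph(rng, 9, 0.35)
        b = _random_named_graph(rng, 11, 0.35)
        got = intersect_networks(a, b)
        nodes = set(a.nodes) & set(b.nodes)
        edges = {frozenset(e) for e in a.edges} & {frozenset(e) for e in b.edges}
        edges = {e for e in edges if e <= nodes}
        assert set(got.nodes) == nodes
        assert {frozenset(e) for e in got.edges} == edges


def test_intersect_disjoint_networks_is_empty():
    a = nx.path_graph(["a", "b", "c"])
    b = nx.path_graph(["x", "y"])
    g = intersect_networks(a, b)
    assert g.number_of_nodes() == 0 and g.number_of_edges() == 0


def test_merge_is_union_of_nodes_and_edges():
    a = nx.path_graph(["a", "b"])
    b = nx.path_graph(["b", "c"])
    g = merge_networks(a, b)
    assert set(g.nodes) == {"a", "b", "c"} and g.number_of_edges() == 2


# -- centralities ------------------------------------------------------------


def test_centralities_path_graph_betweenness():
    g = nx.path_graph(["A", "B", "C"])
    t = centralities(g)
    assert t.loc["B", "bc"] == pytest.approx(1.0)
    assert t.loc["A", "bc"] == 0.0 and t.loc["C", "bc"] == 0.0


def test_centralities_complete_graph_closeness_is_one():
    t = centralities(nx.complete_graph(4))
    assert np.allclose(t["cc"], 1.0)


def test_centralities_star_degree_and_neighbor_degree():
    g = nx.star_graph(4)  # center 0, leaves 1..4
    t = centralities(g)
    assert t.loc[0, "dc"] == 4
    assert t.loc[1, "nc"] == pytest.approx(4.0)
    assert t.loc[0, "nc"] == pytest.approx(1.0)


def test_centralities_empty_graph_raises():
    with pytest.raises(ValueError):
        centralities(nx.Graph())


def test_degree_sum_is_twice_edge_count():
    rng = np.random.default_rng(3)
    for _ in range(10):
        g = _random_named_graph(rng, 12, 0.3)
        if g.number_of_nodes() == 0:
            continue
        t = centralities(g)
        assert t["dc"].sum() == 2 * g.number_of_edges()


def test_all_centralities_match_exhaustive_oracles_on_random_graphs():
    """DC/BC/CC/NC equal brute-force enumeration on 200 random graphs <= 8 nodes."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(2, 9))
        p = float(rng.uniform(0.15, 0.9))
        g = _random_named_graph(rng, n, p)
        t = centralities(g)
        bc = brute_betweenness(g)
        cc = brute_closeness(g)
        ncd = brute_neighbor_degree(g)
        deg = dict(g.degree())
        for v in g.nodes:
            assert t.loc[v, "dc"] == deg[v]
            assert t.loc[v, "bc"] == pytest.approx(bc[v], abs=1e-12)
            assert t.loc[v, "cc"] == pytest.approx(cc[v], abs=1e-12)
            assert t.loc[v, "nc"] == pytest.approx(ncd[v], abs=1e-12)


# -- hub extraction ----------------------------------------------------------


def test_star_hubs_are_the_center():
    t = centralities(nx.star_graph(6))
    hubs, cuts = extract_hubs(t)
    assert hubs == {0}
    assert cuts["bc"] == 0.0  # leaf median


def test_regular_graph_has_no_hubs_under_strict_median():
    t = centralities(nx.cycle_graph(6))
    hubs, _ = extract_hubs(t)
    assert hubs == set()


def test_hub_set_matches_brute_force_filter_and_shrinks_with_cutoffs(default_spec):
    from netpharm.simulate import gen_ppi

    g, _ = gen_ppi(default_spec)
    t = centralities(g)
    hubs, cuts = extract_hubs(t)
    expected = {
        v
        for v in t.index
        if t.loc[v, "dc"] > cuts["dc"]
        and t.loc[v, "bc"] > cuts["bc"]
        and t.loc[v, "cc"] > cuts["cc"]
    }
    assert hubs == expected
    tighter, _ = extract_hubs(t, HubCriteria(dc_cutoff=cuts["dc"] + 2))
    assert tighter <= hubs
    with_nc, _ = extract_hubs(t, HubCriteria(include_nc=True))
    assert with_nc <= hubs


def test_extract_hubs_empty_table_raises():
    import pandas as pd

    with pytest.raises(ValueError):
        extract_hubs(pd.DataFrame(columns=["dc", "bc", "cc", "nc"]))
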