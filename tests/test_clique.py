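"""Product graph construction and exact maximum-clique search."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cliquescreen import (FixtureSpec, build_graph, build_product_graph,
                          brute_force_clique, brute_force_clique_indices,
                          make_molecule, max_clique, maximum_clique_indices,
                          random_rotation, rigid_transform)
from cliquescreen.fixtures import _assemble


def chain3():
    coords = np.array([[0.0, 0, 0], [1.54, 0, 0], [3.08, 0, 0]])
    return _assemble("C3", ["C.3"] * 3, coords, [(0, 1), (1, 2)])


def er_adjacency(rng, n, p):
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T


# ---------------------------------------------------------------------------
# product graph construction
# ---------------------------------------------------------------------------

def test_self_comparison_contains_identity_clique():
    g = build_graph(chain3())
    pg = build_product_graph(g, g, 2, 0)
    assert pg.n == 9  # 3x3 type-matched pairs
    clique = max_clique(pg)
    assert clique.size == 3
    # injectivity invariants
    rs = [v.r for v in clique.members]
    ts = [v.t for v in clique.members]
    assert len(set(rs)) == len(rs) and len(set(ts)) == len(ts)


def test_benzene_self_3d_threshold_zero(benzene_mol):
    g = build_graph(benzene_mol)
    pg = build_product_graph(g, g, 3, 0.0)
    assert max_clique(pg).size == 6


def test_no_shared_type_gives_empty_graph(benzene_mol, propane_mol):
    pg = build_product_graph(build_graph(benzene_mol),
                             build_graph(propane_mol), 2, 0)
    assert pg.n == 0
    assert max_clique(pg).size == 0
    assert brute_force_clique(pg).size == 0


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 5_000), dimension=st.sampled_from([2, 3]))
def test_edge_rule_matches_double_loop_oracle(seed, dimension):
    """Vectorised edge construction equals a literal re-evaluation."""
    sp = FixtureSpec(seed=seed, n_heavy=(3, 8), topology="tree",
                     type_alphabet=("C.3", "N.3", "O.3"))
    a = make_molecule(sp)
    b = make_molecule(FixtureSpec(seed=seed + 7, n_heavy=(3, 8),
                                  topology="tree",
                                  type_alphabet=("C.3", "N.3", "O.3")))
    ga, gb = build_graph(a), build_graph(b)
    thr = 1 if dimension == 2 else 0.8
    pg = build_product_graph(ga, gb, dimension, thr)
    dist_a = ga.topo_dist if dimension == 2 else ga.geo_dist
    dist_b = gb.topo_dist if dimension == 2 else gb.geo_dist
    for u, (i, ip) in enumerate(pg.vertices):
        assert ga.sybyl[i] == gb.sybyl[ip]
        for v, (j, jp) in enumerate(pg.vertices):
            da, db = dist_a[i, j], dist_b[ip, jp]
            expect = (u != v and i != j and ip != jp
                      and np.isfinite(da) and np.isfinite(db)
                      and abs(da - db) <= thr)
            assert bool(pg.adjacency[u, v]) == expect


def test_inf_vs_inf_comparison_fails():
    # two disconnected fragments: C-C pair plus a lone C, compared to itself
    coords = np.array([[0.0, 0, 0], [1.54, 0, 0], [40.0, 0, 0]])
    m = _assemble("FRAG", ["C.3"] * 3, coords, [(0, 1)])
    g = build_graph(m)
    pg = build_product_graph(g, g, 2, 5)
    # vertex (2,2) pairs the lone atom with itself; its relation to any
    # vertex in the other fragment involves inf on both sides and must fail
    idx = {v: k for k, v in enumerate(pg.vertices)}
    assert not pg.adjacency[idx[(2, 2)], idx[(0, 0)]]
    # so the best mapping is the connected pair, not all three atoms
    assert max_clique(pg).size == 2


# ---------------------------------------------------------------------------
# solver vs oracles
# ---------------------------------------------------------------------------

def test_known_small_graphs():
    ring5 = nx.to_numpy_array(nx.cycle_graph(5), dtype=bool)
    assert len(maximum_clique_indices(ring5)) == 2  # triangle-free
    k6 = ~np.eye(6, dtype=bool)
    assert len(brute_force_clique_indices(k6)) == 6
    edgeless = np.zeros((4, 4), dtype=bool)
    assert len(brute_force_clique_indices(edgeless)) == 1
    assert maximum_clique_indices(np.zeros((0, 0), dtype=bool)) == []


def test_brute_force_guard():
    with pytest.raises(ValueError, match="guarded"):
        brute_force_clique_indices(np.zeros((25, 25), dtype=bool))


@pytest.mark.parametrize("p", [0.3, 0.5, 0.7])
def test_solver_equals_enumeration_on_random_graphs(p):
    rng = np.random.default_rng(int(p * 100))
    for _ in range(40):
        n = int(rng.integers(1, 19))
        adj = er_adjacency(rng, n, p)
        ours = maximum_clique_indices(adj)
        oracle = brute_force_clique_indices(adj)
        assert len(ours) == len(oracle)
        # and the returned set really is a clique
        for a in ours:
            for b in ours:
                assert a == b or adj[a, b]


def test_solver_agrees_with_networkx():
    """Third, fully external route for the clique number."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(2, 22))
        adj = er_adjacency(rng, n, 0.5)
        _, w = nx.max_weight_clique(nx.from_numpy_array(adj), weight=None)
        assert len(maximum_clique_indices(adj)) == w


def test_solver_is_deterministic():
    rng = np.random.default_rng(7)
    adj = er_adjacency(rng, 16, 0.5)
    first = maximum_clique_indices(adj)
    assert all(maximum_clique_indices(adj) == first for _ in range(3))


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------

@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 5_000))
def test_threshold_monotonicity(seed):
    """Raising the threshold only ever adds product-graph edges."""
    a = make_molecule(FixtureSpec(seed=seed, topology="tree"))
    b = make_molecule(FixtureSpec(seed=seed + 1, topology="tree"))
    ga, gb = build_graph(a), build_graph(b)
    prev_edges, prev_size = -1, -1
    for thr in (0, 1, 2, 3, 4):
        pg = build_product_graph(ga, gb, 2, thr)
        edges = int(pg.adjacency.sum())
        size = max_clique(pg).size
        assert edges >= prev_edges and size >= prev_size
        prev_edges, prev_size = edges, size


@settings(max_examples=15, derandomize=True, deadline=None)
@given(seed=st.integers(0, 5_000))
def test_3d_graph_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    a = make_molecule(FixtureSpec(seed=seed, topology="ring+substituent",
                                  n_heavy=(4, 8)))
    b = make_molecule(FixtureSpec(seed=seed + 3, topology="chain",
                                  n_heavy=(4, 8)))
    moved = rigid_transform(b, random_rotation(rng), rng.uniform(-8, 8, 3))
    ga = build_graph(a)
    pg0 = build_product_graph(ga, build_graph(b), 3, 1.0)
    pg1 = build_product_graph(ga, build_graph(moved), 3, 1.0)
    assert np.array_equal(pg0.adjacency, pg1.adjacency)
    assert max_clique(pg0).members == max_clique(pg1).members


def test_2d_graph_ignores_coordinates():
    rng = np.random.default_rng(11)
    m = make_molecule(FixtureSpec(seed=11, topology="tree"))
    scrambled = _assemble(m.name, [a.sybyl_type for a in m.atoms],
                          rng.uniform(-20, 20, (len(m.atoms), 3)),
                          [(b.a_serial - 1, b.b_serial - 1) for b in m.bonds])
    ga = build_graph(make_molecule(FixtureSpec(seed=12, topology="tree")))
    pg0 = build_product_graph(ga, build_graph(m), 2, 1)
    pg1 = build_product_graph(ga, build_graph(scrambled), 2, 1)
    assert np.array_equal(pg0.adjacency, pg1.adjacency)


@settings(max_examples=15, derandomize=True, deadline=None)
@given(seed=st.integers(0, 5_000))
def test_swap_symmetry(seed):
    a = make_molecule(FixtureSpec(seed=seed, topology="chain"))
    b = make_molecule(FixtureSpec(seed=seed + 5, topology="tree"))
    ga, gb = build_graph(a), build_graph(b)
    fwd = max_clique(build_product_graph(ga, gb, 2, 1)).size
    rev = max_clique(build_product_graph(gb, ga, 2, 1)).size
    assert fwd == rev
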