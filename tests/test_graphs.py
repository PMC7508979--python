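import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from structforms import graphs as G


# ---------------------------------------------------------------------------
# Generators


def test_hex_torus_structure():
    g = G.make_hex_torus(6, 6)
    assert g.n_nodes == 36
    assert g.form_label == "hexagonal"
    assert tuple(g.degree_sequence()) == (6,) * 36
    assert len(g.edges) == 36 * 6 // 2
    assert g.is_connected()


def test_hex_torus_neighbours_match_offsets():
    rows, cols = 5, 7
    g = G.make_hex_torus(rows, cols)
    nbrs = g.neighbors()
    for i, j in itertools.product(range(rows), range(cols)):
        u = i * cols + j
        expected = {
            ((i + di) % rows) * cols + (j + dj) % cols
            for di, dj in G.HEX_NEIGHBOR_OFFSETS
        }
        assert set(nbrs[u]) == expected


def test_hex_torus_rejects_small_lattices():
    with pytest.raises(ValueError):
        G.make_hex_torus(2, 6)
    with pytest.raises(ValueError):
        G.make_hex_torus(6, 2)


def test_community_ring_structure():
    g = G.make_community_ring(5, 7)
    assert g.n_nodes == 35
    assert g.form_label == "community"
    assert tuple(g.degree_sequence()) == (6,) * 35
    assert g.is_connected()
    assert sum(g.is_connecting) == 10
    assert g.community_of == tuple(i // 7 for i in range(35))


def test_community_ring_connector_wiring():
    n_comm, size = 5, 7
    g = G.make_community_ring(n_comm, size)
    nbrs = {u: set(vs) for u, vs in enumerate(g.neighbors())}
    for c in range(n_comm):
        c0, c1 = c * size, c * size + 1
        assert g.is_connecting[c0] and g.is_connecting[c1]
        # The two connecting nodes of one community are not adjacent.
        assert c1 not in nbrs[c0]
        # Connector 1 of community c links to connector 0 of community c+1.
        nxt0 = ((c + 1) % n_comm) * size
        assert nxt0 in nbrs[c1]
        # Connecting nodes have exactly one out-of-community neighbour.
        for conn in (c0, c1):
            outside = [v for v in nbrs[conn] if g.community_of[v] != c]
            assert len(outside) == 1
        # Non-connecting members are adjacent to every other member.
        for u in range(c * size + 2, (c + 1) * size):
            assert nbrs[u] == {v for v in range(c * size, (c + 1) * size) if v != u}


def test_community_ring_rejects_small_inputs():
    with pytest.raises(ValueError):
        G.make_community_ring(2, 7)
    with pytest.raises(ValueError):
        G.make_community_ring(5, 2)


def test_edges_stored_lower_first():
    for g in (G.make_hex_torus(5, 5), G.make_community_ring(4, 7)):
        assert all(u < v for u, v in g.edges)


# ---------------------------------------------------------------------------
# Missing links


def test_remove_edges_records_omission():
    g = G.make_hex_torus(6, 6)
    omitted = sorted(g.edges)[:2]
    obs = G.remove_edges(g, omitted)
    assert obs.edges == g.edges - frozenset(omitted)
    assert obs.omitted == frozenset(omitted)
    assert g.edges == G.make_hex_torus(6, 6).edges  # original untouched


def test_remove_edges_rejects_non_edges_and_disconnection():
    g = G.make_hex_torus(6, 6)
    with pytest.raises(ValueError):
        G.remove_edges(g, [(0, 7)] if (0, 7) not in g.edges else [(0, 9)])
    # Removing all six edges of node 0 isolates it.
    isolating = [e for e in g.edges if 0 in e]
    with pytest.raises(G.GraphConnectivityError):
        G.remove_edges(g, isolating)


def test_fixture_omitted_edges_valid():
    g = G.make_hex_torus(6, 6)
    assert len(G.FIXTURE_HEX_OMITTED_EDGES) == 8
    assert G.FIXTURE_HEX_OMITTED_EDGES <= g.edges
    obs = G.remove_edges(g, G.FIXTURE_HEX_OMITTED_EDGES)
    assert obs.is_connected()
    triples = G.enumerate_question_triples(g, obs, inference_only=True)
    assert len(triples) >= 40


def test_sample_omitted_edges_contract(rng):
    g = G.make_hex_torus(6, 6)
    omitted = G.sample_omitted_edges(g, 8, rng, min_inference_questions=40)
    assert len(omitted) == 8
    obs = G.remove_edges(g, omitted)
    assert obs.is_connected()
    assert len(G.enumerate_question_triples(g, obs, True)) >= 40


# ---------------------------------------------------------------------------
# Distances oracle


@pytest.mark.parametrize(
    "g", [G.make_hex_torus(5, 6), G.make_community_ring(4, 7)], ids=["hex", "community"]
)
def test_bfs_distances_match_networkx(g):
    d = G.bfs_distances(g)
    expected = dict(nx.all_pairs_shortest_path_length(g.to_networkx()))
    for u in range(g.n_nodes):
        for v in range(g.n_nodes):
            assert d[u, v] == expected[u][v]
    assert np.array_equal(d, d.T)
    assert np.all(np.diag(d) == 0)


def test_bfs_distances_disconnected_inf():
    g = G.Graph(n_nodes=4, edges=frozenset({(0, 1), (2, 3)}), form_label="hexagonal")
    d = G.bfs_distances(g)
    assert d[0, 1] == 1 and np.isinf(d[0, 2])


# ---------------------------------------------------------------------------
# Sequence sampling


def test_random_walk_steps_are_edges(rng):
    g = G.make_community_ring(5, 7)
    seq = G.sample_random_walk(g, 200, rng)
    assert seq.mode == "walk" and len(seq.items) == 200
    assert seq.n_observations == 200
    for u, v in zip(seq.items, seq.items[1:]):
        assert (min(u, v), max(u, v)) in g.edges


@given(seed=st.integers(0, 2**31 - 1))
def test_random_walk_deterministic_under_seed(seed):
    g = G.make_hex_torus(5, 5)
    s1 = G.sample_random_walk(g, 30, np.random.default_rng(seed))
    s2 = G.sample_random_walk(g, 30, np.random.default_rng(seed))
    assert s1.items == s2.items


def test_pair_sequence_contract(rng):
    g = G.make_hex_torus(6, 6)
    seq = G.sample_pair_sequence(g, 150, rng)
    assert seq.mode == "pairs" and len(seq.items) == 150
    assert seq.n_observations == 300  # each pair shows two stimuli
    for u, v in seq.items:
        assert (min(u, v), max(u, v)) in g.edges
    for (a, b), (c, d) in zip(seq.items, seq.items[1:]):
        assert not {a, b} & {c, d}  # consecutive pairs share no node


def test_pair_sequence_unsatisfiable_constraint(rng):
    triangle = G.Graph(
        n_nodes=3, edges=frozenset({(0, 1), (0, 2), (1, 2)}), form_label="community"
    )
    with pytest.raises(ValueError):
        G.sample_pair_sequence(triangle, 10, rng)
    seq = G.sample_pair_sequence(triangle, 10, rng, allow_successive_overlap=True)
    assert len(seq.items) == 10


def test_sequence_concat_preserves_mode(rng):
    g = G.make_hex_torus(5, 5)
    a = G.sample_random_walk(g, 10, rng)
    b = G.sample_random_walk(g, 5, rng)
    assert a.concat(b).items == a.items + b.items
    p = G.sample_pair_sequence(g, 4, rng)
    with pytest.raises(ValueError):
        a.concat(p)


def test_hex_torus_3x3_has_six_distinct_neighbours():
    g = G.make_hex_torus(3, 3)
    assert g.n_nodes == 9
    assert tuple(g.degree_sequence()) == (6,) * 9


def test_random_walk_stationary_distribution_uniform(rng):
    triangle = G.Graph(
        n_nodes=3, edges=frozenset({(0, 1), (0, 2), (1, 2)}), form_label="community"
    )
    seq = G.sample_random_walk(triangle, 10_000, rng)
    freq = np.bincount(seq.items, minlength=3) / len(seq.items)
    se = np.sqrt((1 / 3) * (2 / 3) / len(seq.items))
    assert np.all(np.abs(freq - 1 / 3) < 3 * se + 1e-9)


def test_pair_sequence_matches_constrained_chain_stationary(rng):
    """Empirical edge frequencies against the stationary distribution of the
    exhaustively enumerated edge-to-edge chain (uniform over disjoint next
    edges) on a small path graph."""
    g = G.Graph(
        n_nodes=5,
        edges=frozenset({(0, 1), (1, 2), (2, 3), (3, 4)}),
        form_label="community",
    )
    edges = sorted(g.edges)
    disjoint = np.array(
        [[not (set(e) & set(f)) for f in edges] for e in edges], dtype=float
    )
    chain = disjoint / disjoint.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(chain.T)
    stat = np.real(evecs[:, np.argmax(np.real(evals))])
    stat = stat / stat.sum()
    n = 30_000
    seq = G.sample_pair_sequence(g, n, rng)
    idx = {e: i for i, e in enumerate(edges)}
    counts = np.zeros(len(edges))
    for u, v in seq.items:
        counts[idx[(min(u, v), max(u, v))]] += 1
    freq = counts / n
    se = np.sqrt(stat * (1 - stat) / n)
    assert np.all(np.abs(freq - stat) < 4 * se + 1e-3)


# ---------------------------------------------------------------------------
# Questions


def _fixture_task():
    full = G.make_hex_torus(6, 6)
    observed = G.remove_edges(full, G.FIXTURE_HEX_OMITTED_EDGES)
    return full, observed


def test_enumerate_question_triples_invariants():
    full, observed = _fixture_task()
    d_full = G.bfs_distances(full)
    d_obs = G.bfs_distances(observed)
    triples = G.enumerate_question_triples(full, observed, inference_only=True)
    assert triples
    for a, b, t in triples:
        assert a < b and len({a, b, t}) == 3
        assert d_obs[a, t] == d_obs[b, t]  # tied on the observed graph
        assert d_full[a, t] != d_full[b, t]  # resolved by the complete graph


def test_make_distance_questions_answer_key_matches_bfs(rng):
    full, observed = _fixture_task()
    d_full = G.bfs_distances(full)
    qs = G.make_distance_questions(full, observed, 40, True, rng)
    assert len(qs) == 40
    assert len({(q.option_a, q.option_b, q.target) for q in qs}) == 40
    for q in qs:
        assert q.is_inference
        assert q.d_obs_a == q.d_obs_b
        better = q.option_a if d_full[q.option_a, q.target] < d_full[q.option_b, q.target] else q.option_b
        assert q.answer == better


def test_make_distance_questions_reports_achievable_count(rng):
    full, observed = _fixture_task()
    n_valid = len(G.enumerate_question_triples(full, observed, True))
    with pytest.raises(ValueError, match=str(n_valid)):
        G.make_distance_questions(full, observed, n_valid + 1, True, rng)


def test_question_invariant_rejects_degenerate_nodes():
    with pytest.raises(ValueError):
        G.Question(1, 1, 2, 1, 1, 1, 2, True)


# ---------------------------------------------------------------------------
# Serialization


def test_graph_roundtrip(tmp_path):
    full = G.make_community_ring(5, 7)
    edge, meta = tmp_path / "g.tsv", tmp_path / "g.json"
    G.save_graph(full, edge, meta)
    loaded = G.load_graph(edge, meta)
    assert loaded == full


def test_sequence_and_question_frames(rng):
    full, observed = _fixture_task()
    walk = G.sample_random_walk(full, 20, rng)
    assert list(G.sequence_to_frame(walk)["node"]) == list(walk.items)
    pairs = G.sample_pair_sequence(full, 5, rng)
    assert G.sequence_to_frame(pairs).shape == (5, 2)
    qs = G.make_distance_questions(full, observed, 5, True, rng)
    frame = G.questions_to_frame(qs)
    assert list(frame.columns) == [
        "a", "b", "target", "d_obs_a", "d_obs_b", "d_full_a", "d_full_b", "is_inference",
    ]
    assert len(frame) == 5
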