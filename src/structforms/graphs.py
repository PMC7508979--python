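"""Graph families, observation sampling, missing links and distance questions.

Two six-regular graph families are generated here: triangular-lattice tori
("hexagonal" graphs, so called because each node has six neighbours arranged
hexagonally) and ring-of-communities graphs in which fully connected
communities are joined in a ring through designated connecting nodes.
Observation sequences are produced either as random walks or as pseudo-random
presentations of adjacent node pairs; key edges can be omitted from the
observed graph to probe inference of unobserved links.  Distance-comparison
questions ask which of two nodes has fewer links to a target; *inference*
questions are those whose two options are tied under the observed edges but
differ under the complete graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Graph",
    "ObservationSequence",
    "Question",
    "QuestionSet",
    "GraphConnectivityError",
    "make_hex_torus",
    "make_community_ring",
    "remove_edges",
    "sample_omitted_edges",
    "bfs_distances",
    "sample_random_walk",
    "sample_pair_sequence",
    "enumerate_question_triples",
    "make_distance_questions",
    "save_graph",
    "load_graph",
    "sequence_to_frame",
    "questions_to_frame",
    "HEX_NEIGHBOR_OFFSETS",
    "FIXTURE_HEX_OMITTED_EDGES",
]


class GraphConnectivityError(ValueError):
    """Raised when an operation would require or produce a disconnected graph."""


# Canonical triangular-lattice neighbour offsets (row, col), 0-based row-major.
HEX_NEIGHBOR_OFFSETS = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, -1), (-1, 1))


@dataclass(frozen=True)
class Graph:
    """An undirected graph with structural-form annotations.

    Edges are stored with the lower node index first.  ``coords`` is set for
    hexagonal graphs (per-node lattice position), ``community_of`` and
    ``is_connecting`` for community graphs.  ``omitted`` records edges removed
    from a parent graph by :func:`remove_edges`.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    form_label: str
    coords: tuple[tuple[int, int], ...] | None = None
    community_of: tuple[int, ...] | None = None
    is_connecting: tuple[bool, ...] | None = None
    shape: tuple[int, int] | None = None
    omitted: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return [sorted(a) for a in adj]

    def degree_sequence(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            a[u, v] = a[v, u] = 1.0
        return a

    def transition_matrix(self) -> np.ndarray:
        """Row-normalized adjacency: the uniform random-walk kernel."""
        a = self.adjacency_matrix()
        deg = a.sum(axis=1)
        if np.any(deg == 0):
            raise GraphConnectivityError("graph has isolated nodes")
        return a / deg[:, None]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


@dataclass(frozen=True)
class ObservationSequence:
    """Either a random walk (node indices) or a pair presentation sequence."""

    mode: str  # "walk" | "pairs"
    items: tuple  # tuple[int, ...] or tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.mode not in ("walk", "pairs"):
            raise ValueError(f"unknown observation mode {self.mode!r}")

    @property
    def n_observations(self) -> int:
        """Number of individual stimulus observations (pairs count twice)."""
        return len(self.items) * (2 if self.mode == "pairs" else 1)

    def concat(self, other: "ObservationSequence") -> "ObservationSequence":
        if other.mode != self.mode:
            raise ValueError("cannot concatenate sequences of different modes")
        return ObservationSequence(self.mode, self.items + other.items)


@dataclass(frozen=True)
class Question:
    option_a: int
    option_b: int
    target: int
    d_obs_a: int
    d_obs_b: int
    d_full_a: int
    d_full_b: int
    is_inference: bool

    def __post_init__(self):
        if len({self.option_a, self.option_b, self.target}) != 3:
            raise ValueError("option nodes and target must be distinct")
        if self.is_inference and self.d_obs_a != self.d_obs_b:
            raise ValueError("inference questions must be tied on the observed graph")
        if self.d_full_a == self.d_full_b:
            raise ValueError("full-graph distances must differ to define an answer")

    @property
    def answer(self) -> int:
        """Correct option under the complete graph (smaller link count)."""
        return self.option_a if self.d_full_a < self.d_full_b else self.option_b


@dataclass(frozen=True)
class QuestionSet:
    questions: tuple[Question, ...]

    def __len__(self) -> int:
        return len(self.questions)

    def __iter__(self):
        return iter(self.questions)


def _norm_edge(u: int, v: int) -> tuple[int, int]:
    if u == v:
        raise ValueError(f"self-loop ({u},{v}) is not a valid edge")
    return (u, v) if u < v else (v, u)


def make_hex_torus(rows: int, cols: int) -> Graph:
    """Six-regular triangular-lattice torus with periodic boundaries.

    Node (i, j) maps to index ``i * cols + j`` and is adjacent to the six
    offsets in :data:`HEX_NEIGHBOR_OFFSETS`, all modulo (rows, cols).
    """
    if rows < 3 or cols < 3:
        raise ValueError(
            f"hex torus needs rows, cols >= 3 (got {rows}x{cols}); smaller "
            "tori make distinct neighbour offsets coincide"
        )
    edges = set()
    for i in range(rows):
        for j in range(cols):
            u = i * cols + j
            for di, dj in HEX_NEIGHBOR_OFFSETS:
                v = ((i + di) % rows) * cols + (j + dj) % cols
                edges.add(_norm_edge(u, v))
    coords = tuple((i, j) for i in range(rows) for j in range(cols))
    return Graph(
        n_nodes=rows * cols,
        edges=frozenset(edges),
        form_label="hexagonal",
        coords=coords,
        shape=(rows, cols),
    )


def make_community_ring(n_comm: int, comm_size: int) -> Graph:
    """Fully connected communities joined in a ring through connecting nodes.

    Within each community every pair of nodes is connected except the two
    designated connecting nodes (local indices 0 and 1), which are not
    adjacent to each other.  Connecting node 1 of community c links to
    connecting node 0 of community (c+1) mod n_comm, so each connecting node
    has exactly one out-of-community neighbour.  With comm_size = 7 every
    node has degree six.
    """
    if n_comm < 3 or comm_size < 3:
        raise ValueError(
            f"community ring needs n_comm, comm_size >= 3 (got {n_comm},{comm_size})"
        )
    edges = set()
    for c in range(n_comm):
        base = c * comm_size
        for a in range(comm_size):
            for b in range(a + 1, comm_size):
                if a == 0 and b == 1:
                    continue  # connecting nodes are not adjacent to each other
                edges.add((base + a, base + b))
        nxt = ((c + 1) % n_comm) * comm_size
        edges.add(_norm_edge(base + 1, nxt + 0))
    n = n_comm * comm_size
    community_of = tuple(i // comm_size for i in range(n))
    is_connecting = tuple(i % comm_size in (0, 1) for i in range(n))
    return Graph(
        n_nodes=n,
        edges=frozenset(edges),
        form_label="community",
        community_of=community_of,
        is_connecting=is_connecting,
        shape=(n_comm, comm_size),
    )


def remove_edges(graph: Graph, omitted) -> Graph:
    """Return the observed graph with ``omitted`` edges removed.

    The original graph is untouched.  Raises if a pair is not an edge or if
    the removal disconnects the graph.
    """
    omitted = frozenset(_norm_edge(u, v) for u, v in omitted)
    missing = omitted - graph.edges
    if missing:
        raise ValueError(f"pairs not in graph edges: {sorted(missing)}")
    observed = replace(
        graph, edges=graph.edges - omitted, omitted=graph.omitted | omitted
    )
    if omitted and not observed.is_connected():
        comps = [sorted(c) for c in nx.connected_components(observed.to_networkx())]
        raise GraphConnectivityError(
            f"removing {sorted(omitted)} disconnects the graph into "
            f"{len(comps)} components: {comps}"
        )
    return observed


def bfs_distances(graph: Graph) -> np.ndarray:
    """All-pairs shortest-path link counts (breadth-first search oracle).

    Unreachable pairs are returned as ``inf``; callers requiring finiteness
    must check.
    """
    n = graph.n_nodes
    if not graph.edges:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    rows, cols = zip(*graph.edges)
    data = np.ones(len(rows))
    a = csr_matrix(
        (np.r_[data, data], (np.r_[rows, cols], np.r_[cols, rows])), shape=(n, n)
    )
    return shortest_path(a, method="D", unweighted=True)


def sample_random_walk(
    graph: Graph, n_steps: int, rng: np.random.Generator
) -> ObservationSequence:
    """Uniform random walk of ``n_steps`` nodes; start node uniform."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not graph.is_connected():
        raise GraphConnectivityError("random walk requires a connected graph")
    adj = graph.neighbors()
    node = int(rng.integers(graph.n_nodes))
    items = [node]
    for _ in range(n_steps - 1):
        node = adj[node][int(rng.integers(len(adj[node])))]
        items.append(node)
    return ObservationSequence("walk", tuple(items))


def sample_pair_sequence(
    observed: Graph,
    n_pairs: int,
    rng: np.random.Generator,
    allow_successive_overlap: bool = False,
) -> ObservationSequence:
    """Pseudo-random adjacent-pair presentations from the observed graph.

    Each item is an edge sampled uniformly with replacement, subject to the
    constraint that consecutive pairs share no node (neighbouring pairs are
    never sampled in succession); within-pair presentation order is
    randomized.  Pass ``allow_successive_overlap=True`` to relax the
    constraint explicitly on graphs where it is unsatisfiable.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    edges = sorted(observed.edges)
    if not edges:
        raise ValueError("observed graph has no edges")
    if not allow_successive_overlap and n_pairs > 1:
        nodes_of = [set(e) for e in edges]
        for e, ns in zip(edges, nodes_of):
            if not any(ns.isdisjoint(other) for other in nodes_of if other != ns):
                raise ValueError(
                    f"edge {e} shares a node with every other edge; the "
                    "non-succession constraint is unsatisfiable — pass "
                    "allow_successive_overlap=True to sample pairs i.i.d."
                )
    items = []
    prev: tuple[int, int] | None = None
    for _ in range(n_pairs):
        while True:
            u, v = edges[int(rng.integers(len(edges)))]
            if (
                allow_successive_overlap
                or prev is None
                or (u not in prev and v not in prev)
            ):
                break
        prev = (u, v)
        if rng.integers(2):
            u, v = v, u
        items.append((u, v))
    return ObservationSequence("pairs", tuple(items))


def enumerate_question_triples(
    full: Graph, observed: Graph, inference_only: bool
) -> list[tuple[int, int, int]]:
    """All valid (option_a, option_b, target) triples with option_a < option_b.

    A triple is valid when the three nodes are distinct and the two options'
    link counts to the target differ on the full graph; inference triples must
    additionally be tied on the observed graph.
    """
    d_full = bfs_distances(full)
    d_obs = bfs_distances(observed)
    if not np.all(np.isfinite(d_full)) or not np.all(np.isfinite(d_obs)):
        raise GraphConnectivityError("question generation requires connected graphs")
    n = full.n_nodes
    triples = []
    for a in range(n):
        for b in range(a + 1, n):
            for t in range(n):
                if t == a or t == b:
                    continue
                if d_full[a, t] == d_full[b, t]:
                    continue
                if inference_only and d_obs[a, t] != d_obs[b, t]:
                    continue
                triples.append((a, b, t))
    return triples


def make_distance_questions(
    full: Graph,
    observed: Graph,
    n: int,
    inference_only: bool,
    rng: np.random.Generator,
) -> QuestionSet:
    """Sample ``n`` distinct distance-comparison questions.

    The answer key is the option with the smaller full-graph link count.
    Option presentation order is randomized.  Raises if fewer than ``n``
    valid triples exist, reporting the achievable count.
    """
    if not (observed.edges <= full.edges):
        raise ValueError("observed graph must be a subgraph of the full graph")
    triples = enumerate_question_triples(full, observed, inference_only)
    if len(triples) < n:
        raise ValueError(
            f"only {len(triples)} valid "
            f"{'inference ' if inference_only else ''}questions exist, {n} requested"
        )
    d_full = bfs_distances(full)
    d_obs = bfs_distances(observed)
    chosen = rng.choice(len(triples), size=n, replace=False)
    questions = []
    for idx in chosen:
        a, b, t = triples[int(idx)]
        if rng.integers(2):
            a, b = b, a
        questions.append(
            Question(
                option_a=a,
                option_b=b,
                target=t,
                d_obs_a=int(d_obs[a, t]),
                d_obs_b=int(d_obs[b, t]),
                d_full_a=int(d_full[a, t]),
                d_full_b=int(d_full[b, t]),
                is_inference=bool(d_obs[a, t] == d_obs[b, t]),
            )
        )
    return QuestionSet(tuple(questions))


def sample_omitted_edges(
    graph: Graph,
    k: int,
    rng: np.random.Generator,
    min_inference_questions: int = 40,
    max_tries: int = 200,
) -> frozenset[tuple[int, int]]:
    """Draw a set of ``k`` edges whose removal keeps the graph connected and
    leaves at least ``min_inference_questions`` valid tied-distance questions.
    """
    edges = sorted(graph.edges)
    for _ in range(max_tries):
        idx = rng.choice(len(edges), size=k, replace=False)
        omitted = frozenset(edges[int(i)] for i in idx)
        try:
            observed = remove_edges(graph, omitted)
        except GraphConnectivityError:
            continue
        n_valid = len(enumerate_question_triples(graph, observed, inference_only=True))
        if n_valid >= min_inference_questions:
            return omitted
    raise RuntimeError(
        f"no admissible {k}-edge omission set found in {max_tries} tries"
    )


# Frozen omission set for the 6x6 hexagonal torus: the eight vertical and
# diagonal links crossing the row-2/row-3 boundary in columns 0-3.  Key edges
# are removed together so that tied-distance questions cannot be answered from
# the observed co-occurrence statistics alone (the detour routes around the
# cut are few), only from structural knowledge or heavy spectral smoothing.
FIXTURE_HEX_OMITTED_EDGES: frozenset[tuple[int, int]] = frozenset(
    [(12, 18), (12, 23), (13, 18), (13, 19), (14, 19), (14, 20), (15, 20), (15, 21)]
)


# ---------------------------------------------------------------------------
# Serialization: TSV edge list + JSON sidecar; sequences/questions as CSV.

def save_graph(graph: Graph, edge_path, sidecar_path) -> None:
    pd.DataFrame(sorted(graph.edges), columns=["u", "v"]).to_csv(
        edge_path, sep="\t", index=False
    )
    meta = {
        "n_nodes": graph.n_nodes,
        "form_label": graph.form_label,
        "shape": list(graph.shape) if graph.shape else None,
        "coords": [list(c) for c in graph.coords] if graph.coords else None,
        "community_of": list(graph.community_of) if graph.community_of else None,
        "is_connecting": list(graph.is_connecting) if graph.is_connecting else None,
        "omitted": sorted([list(e) for e in graph.omitted]),
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_graph(edge_path, sidecar_path) -> Graph:
    df = pd.read_csv(edge_path, sep="\t")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return Graph(
        n_nodes=meta["n_nodes"],
        edges=frozenset(_norm_edge(int(u), int(v)) for u, v in df.itertuples(index=False)),
        form_label=meta["form_label"],
        coords=tuple(tuple(c) for c in meta["coords"]) if meta.get("coords") else None,
        community_of=tuple(meta["community_of"]) if meta.get("community_of") else None,
        is_connecting=tuple(meta["is_connecting"]) if meta.get("is_connecting") else None,
        shape=tuple(meta["shape"]) if meta.get("shape") else None,
        omitted=frozenset(_norm_edge(int(u), int(v)) for u, v in meta.get("omitted", [])),
    )


def sequence_to_frame(seq: ObservationSequence) -> pd.DataFrame:
    if seq.mode == "walk":
        return pd.DataFrame({"node": list(seq.items)})
    return pd.DataFrame(seq.items, columns=["first", "second"])


def questions_to_frame(qs: QuestionSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "a": q.option_a,
                "b": q.option_b,
                "target": q.target,
                "d_obs_a": q.d_obs_a,
                "d_obs_b": q.d_obs_b,
                "d_full_a": q.d_full_a,
                "d_full_b": q.d_full_b,
                "is_inference": q.is_inference,
            }
            for q in qs
        ]
    )
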