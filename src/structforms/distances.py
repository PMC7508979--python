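"""From an inferred model to distances between observations and decisions.

Once a transition matrix A and an emission estimate B̂ are in hand, the
abstract state-to-state link-count matrix D is obtained by thresholding A
into an adjacency matrix and running breadth-first search.  The Bayesian
inversion of the emission matrix, B̃ (columns of B̂ normalized over states,
valid because the state prior is uniform), maps observations back to states,
and the observation-level distance matrix is D̃(Oᵢ,Oⱼ) = Σₘₖ B̃ₘᵢ D(zₘ,zₖ) B̃ₖⱼ.
Closer-to-target questions are answered by the smaller D̃ entry; connecting
node identification is scored as the emission mass that connector states
place on the true connector symbols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .basis import TransitionMatrix
from .graphs import GraphConnectivityError
from .inference import EmissionMatrix

__all__ = [
    "AbstractDistanceMatrix",
    "ObservationDistanceMatrix",
    "ConnectingNodeReport",
    "abstract_distances",
    "invert_emission",
    "observation_distances",
    "answer_closer_question",
    "connecting_node_report",
    "DEFAULT_ADJACENCY_THRESHOLD",
]

#: Fraction of the per-row maximum below which transition entries are not
#: treated as edges (shared with the basis module's reconstruction threshold).
DEFAULT_ADJACENCY_THRESHOLD = 0.5


@dataclass(frozen=True)
class AbstractDistanceMatrix:
    """Link counts between abstract graph states (symmetric, zero diagonal)."""

    d: np.ndarray


@dataclass(frozen=True)
class ObservationDistanceMatrix:
    """Estimated link counts between observation symbols."""

    d: np.ndarray


@dataclass(frozen=True)
class ConnectingNodeReport:
    """Fractions of emission mass identifying connecting nodes.

    ``fc`` is the mass that inferred connector states place on true connector
    symbols; ``fIc`` the mass that non-connector states place there; both are
    divided by the number of connecting nodes in the inferred graph.
    """

    fc: float
    fIc: float
    nIc: int
    inferred_connector_states: tuple[int, ...]
    true_connector_symbols: tuple[int, ...]


def abstract_distances(
    a: TransitionMatrix | np.ndarray,
    adjacency_threshold: float = DEFAULT_ADJACENCY_THRESHOLD,
) -> AbstractDistanceMatrix:
    """BFS link counts on the adjacency implied by a transition matrix.

    An entry counts as an edge when it reaches ``adjacency_threshold`` times
    its row's maximum; the adjacency is symmetrized by union before BFS.
    """
    p = a.probs if isinstance(a, TransitionMatrix) else np.asarray(a, float)
    row_max = p.max(axis=1, keepdims=True)
    adj = (p >= adjacency_threshold * row_max) & (p > 0)
    adj = adj | adj.T
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    if n_comp > 1:
        comps = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise GraphConnectivityError(
            f"thresholded adjacency is disconnected; components: {comps}"
        )
    d = shortest_path(csr_matrix(adj.astype(float)), method="D", unweighted=True)
    return AbstractDistanceMatrix(d)


def invert_emission(b: EmissionMatrix | np.ndarray, unseen: str = "error") -> np.ndarray:
    """Bayesian inversion of the emission matrix under a uniform state prior.

    Returns B̃ with B̃[m, i] = p(state m | symbol i): each symbol's column of
    B normalized to sum to one over states.  A symbol emitted by no state has
    no likelihood; with ``unseen="error"`` this raises, with
    ``unseen="uniform"`` the posterior falls back to the uniform state prior.
    """
    if unseen not in ("error", "uniform"):
        raise ValueError("unseen must be 'error' or 'uniform'")
    p = b.probs if isinstance(b, EmissionMatrix) else np.asarray(b, float)
    col = p.sum(axis=0, keepdims=True)
    bad = np.flatnonzero(p.sum(axis=0) <= 0)
    if bad.size:
        if unseen == "error":
            raise ValueError(f"symbols {bad.tolist()} are never emitted by any state")
        p = p.copy()
        p[:, bad] = 1.0 / p.shape[0]
        col = p.sum(axis=0, keepdims=True)
    return p / col


def observation_distances(
    b_tilde: np.ndarray, d: AbstractDistanceMatrix | np.ndarray
) -> ObservationDistanceMatrix:
    """Expected link counts between symbols: D̃ᵢⱼ = Σₘₖ B̃ₘᵢ Dₘₖ B̃ₖⱼ."""
    dd = d.d if isinstance(d, AbstractDistanceMatrix) else np.asarray(d, float)
    b_tilde = np.asarray(b_tilde, float)
    if b_tilde.shape[0] != dd.shape[0]:
        raise ValueError("B̃ rows must index the same states as D")
    return ObservationDistanceMatrix(b_tilde.T @ dd @ b_tilde)


def answer_closer_question(
    d_tilde: ObservationDistanceMatrix | np.ndarray,
    a: int,
    b: int,
    target: int,
    rng: np.random.Generator,
) -> int:
    """Pick the option with the smaller estimated link count to the target.

    Exact ties are resolved by a seeded fair coin.
    """
    if len({a, b, target}) != 3:
        raise ValueError("option and target symbols must be distinct")
    dd = d_tilde.d if isinstance(d_tilde, ObservationDistanceMatrix) else np.asarray(d_tilde)
    da, db = dd[a, target], dd[b, target]
    if da == db:
        return a if rng.integers(2) == 0 else b
    return a if da < db else b


def connecting_node_report(
    b: EmissionMatrix | np.ndarray,
    inferred_connector_states,
    true_connector_symbols,
) -> ConnectingNodeReport:
    """Score connecting-node identification through the emission matrix.

    fc  = (Is_c · B · Ip_cᵀ) / nIc — mass from inferred connector states to
    true connector symbols; fIc uses the complementary state indicator.
    """
    p = b.probs if isinstance(b, EmissionMatrix) else np.asarray(b, float)
    states = sorted(int(i) for i in inferred_connector_states)
    symbols = sorted(int(i) for i in true_connector_symbols)
    n_ic = len(states)
    if n_ic == 0:
        raise ValueError("inferred graph has no connecting nodes")
    if states and (max(states) >= p.shape[0] or min(states) < 0):
        raise IndexError("connector state index out of range")
    if symbols and (max(symbols) >= p.shape[1] or min(symbols) < 0):
        raise IndexError("connector symbol index out of range")
    is_c = np.zeros(p.shape[0])
    is_c[states] = 1.0
    ip_c = np.zeros(p.shape[1])
    ip_c[symbols] = 1.0
    fc = float(is_c @ p @ ip_c) / n_ic
    fic = float((1.0 - is_c) @ p @ ip_c) / n_ic
    return ConnectingNodeReport(
        fc=fc,
        fIc=fic,
        nIc=n_ic,
        inferred_connector_states=tuple(states),
        true_connector_symbols=tuple(symbols),
    )
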