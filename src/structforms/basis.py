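"""Structural-form basis sets and basis-approximated transition matrices.

A basis set is a small collection of vectors U with diagonal weights S that
approximately spans the transition structures of one graph family.  For
hexagonal tori the basis is the 12 most informative eigenvectors (largest
|eigenvalue|, excluding the constant) of a large native torus's random-walk
transition matrix; these resemble entorhinal grid-cell firing maps and can be
stretched or compressed by lattice interpolation to fit candidate graph
sizes.  For community-ring graphs the basis is built directly at each
candidate size from binary community-membership vectors plus connector link
vectors with Gaussian-decaying probability over candidate connector slots.

A transition matrix is recovered from a basis as f(U S Uᵀ) where f rectifies
at zero and discards entries below a fraction of each row's maximum; the
diagonal is then zeroed and rows are normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .graphs import make_hex_torus

__all__ = [
    "BasisSet",
    "TransitionMatrix",
    "DegenerateBasisError",
    "build_hex_basis",
    "resize_basis",
    "build_community_basis",
    "approximate_transition",
    "exact_transition",
    "candidate_transitions",
    "DEFAULT_HEX_CANDIDATE_SHAPES",
    "DEFAULT_COMMUNITY_CANDIDATE_SHAPES",
    "DEFAULT_F_THRESHOLD_FRAC",
    "DEFAULT_CONNECTOR_SIGMA",
    "DEFAULT_CONNECTOR_GAIN",
    "N_HEX_BASIS_VECTORS",
]

N_HEX_BASIS_VECTORS = 12
DEFAULT_NATIVE_HEX_SHAPE = (10, 10)
#: Entries below this fraction of their row's maximum are discarded by the
#: threshold-linear function f; calibrated to reproduce the six-neighbour
#: sparsity of the true 36-node torus kernel.
DEFAULT_F_THRESHOLD_FRAC = 0.5
#: Spread (in connector-slot units) of the Gaussian connector profile.
DEFAULT_CONNECTOR_SIGMA = 0.5
#: Amplitude of connector link vectors relative to membership vectors.
DEFAULT_CONNECTOR_GAIN = 1.2


#: Candidate graph dimensions considered during inference: three sizes per
#: structural form (25/36/49 hexagonal nodes; 28/35/42 community nodes).
DEFAULT_HEX_CANDIDATE_SHAPES = ((5, 5), (6, 6), (7, 7))
DEFAULT_COMMUNITY_CANDIDATE_SHAPES = ((4, 7), (5, 7), (6, 7))


class DegenerateBasisError(ValueError):
    """Raised when a basis yields a transition row with no mass."""


@dataclass(frozen=True)
class BasisSet:
    """Ordered basis vectors with diagonal weights for one structural form."""

    form: str  # "hexagonal" | "community"
    vectors: np.ndarray  # [n_nodes, n_basis]
    weights: np.ndarray  # [n_basis]
    native_shape: tuple[int, int]

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_basis(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class TransitionMatrix:
    probs: np.ndarray  # [states, states], row-stochastic
    provenance: str  # "exact" | "basis-approximated"

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    def __post_init__(self):
        p = self.probs
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(p < -1e-12):
            raise ValueError("transition matrix has negative entries")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")


def _fix_signs(vectors: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Deterministic sign convention: first component of magnitude > tol positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def exact_transition(graph) -> TransitionMatrix:
    """The uniform random-walk kernel of a graph, as a TransitionMatrix."""
    return TransitionMatrix(graph.transition_matrix(), provenance="exact")


def build_hex_basis(
    native_rows: int = DEFAULT_NATIVE_HEX_SHAPE[0],
    native_cols: int = DEFAULT_NATIVE_HEX_SHAPE[1],
    n_vectors: int = N_HEX_BASIS_VECTORS,
) -> BasisSet:
    """Eigenvector basis of a large native hexagonal torus.

    The random-walk kernel of a regular graph is symmetric, so its
    eigenvectors are orthonormal and its eigenvalues real.  The constant
    eigenvector (eigenvalue 1) is removed and the ``n_vectors`` eigenvectors
    of largest |eigenvalue| are retained with their eigenvalues as weights.
    Ties in |eigenvalue| are resolved by the stable sort order of the
    decomposition plus a deterministic sign convention.
    """
    graph = make_hex_torus(native_rows, native_cols)
    a = graph.transition_matrix()
    evals, evecs = np.linalg.eigh(a)
    # Drop the constant mode: eigenvalue 1 is the top of the spectrum.
    const_idx = int(np.argmax(evals))
    keep = np.ones(len(evals), dtype=bool)
    keep[const_idx] = False
    evals, evecs = evals[keep], evecs[:, keep]
    order = np.argsort(-np.abs(evals), kind="stable")[:n_vectors]
    return BasisSet(
        form="hexagonal",
        vectors=_fix_signs(evecs[:, order]),
        weights=evals[order].copy(),
        native_shape=(native_rows, native_cols),
    )


def resize_basis(
    basis: BasisSet, target_rows: int, target_cols: int, order: int = 3
) -> BasisSet:
    """Stretch/compress a hexagonal basis to a new lattice size.

    Each vector is reshaped to its native 2-D lattice, resampled to the
    target lattice by spline interpolation with periodic (torus) boundary
    handling, flattened, and the set is re-orthonormalized by QR (preserving
    vector order and orientation).  Weights are carried over.  Community
    bases are rebuilt at each size, not resized.
    """
    if basis.form != "hexagonal":
        raise ValueError("only hexagonal bases are resized; rebuild community bases")
    if target_rows < 3 or target_cols < 3:
        raise ValueError("target lattice must be at least 3x3")
    nr, nc = basis.native_shape
    zoom = (target_rows / nr, target_cols / nc)
    cols = []
    for j in range(basis.n_basis):
        img = basis.vectors[:, j].reshape(nr, nc)
        out = ndimage.zoom(img, zoom, order=order, mode="grid-wrap", grid_mode=True)
        assert out.shape == (target_rows, target_cols)
        cols.append(out.ravel())
    u = np.column_stack(cols)
    q, r = np.linalg.qr(u)
    # QR may flip orientations; re-align each vector with its pre-QR direction.
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return BasisSet(
        form="hexagonal",
        vectors=q,
        weights=basis.weights.copy(),
        native_shape=(target_rows, target_cols),
    )


def _connector_profile(comm_size: int, peak_slot: int, sigma: float) -> np.ndarray:
    """Gaussian-decaying probability over candidate connector slots.

    Slot 0 is the first candidate connecting node, slot 1 the second, and so
    on; the profile peaks at ``peak_slot`` and decays with slot distance, so
    the probability of further connecting-node candidates is lower.
    """
    slots = np.arange(comm_size)
    return np.exp(-((slots - peak_slot) ** 2) / (2.0 * sigma**2))


def build_community_basis(
    n_comm: int,
    comm_size: int,
    sigma: float = DEFAULT_CONNECTOR_SIGMA,
    connector_gain: float = DEFAULT_CONNECTOR_GAIN,
) -> BasisSet:
    """Membership and connector link vectors for a ring of communities.

    One binary assignment vector per community (weight 1) marks its members.
    One connector link vector per ring edge (c, c+1) carries a
    Gaussian-decaying probability profile over candidate connector slots on
    each side: the outgoing slot of community c and the incoming slot of
    community c+1 receive the highest probability, later candidate slots
    lower.  Weights are all one.
    """
    if n_comm < 3 or comm_size < 3:
        raise ValueError("community basis needs n_comm, comm_size >= 3")
    n = n_comm * comm_size
    membership = np.zeros((n, n_comm))
    for c in range(n_comm):
        membership[c * comm_size : (c + 1) * comm_size, c] = 1.0
    link = np.zeros((n, n_comm))
    out_profile = connector_gain * _connector_profile(comm_size, peak_slot=1, sigma=sigma)
    in_profile = connector_gain * _connector_profile(comm_size, peak_slot=0, sigma=sigma)
    for c in range(n_comm):
        nxt = (c + 1) % n_comm
        link[c * comm_size : (c + 1) * comm_size, c] += out_profile
        link[nxt * comm_size : (nxt + 1) * comm_size, c] += in_profile
    vectors = np.concatenate([membership, link], axis=1)
    return BasisSet(
        form="community",
        vectors=vectors,
        weights=np.ones(2 * n_comm),
        native_shape=(n_comm, comm_size),
    )


def approximate_transition(
    basis: BasisSet, f_threshold_frac: float = DEFAULT_F_THRESHOLD_FRAC
) -> TransitionMatrix:
    """Reconstruct a transition matrix from a basis: f(U S Uᵀ), zero diagonal,
    row-normalize.

    f is threshold-linear: negative entries are rectified to zero and
    off-diagonal entries below ``f_threshold_frac`` of their row's maximum
    are discarded before normalization.
    """
    w = basis.vectors @ np.diag(basis.weights) @ basis.vectors.T
    w = np.maximum(w, 0.0)
    np.fill_diagonal(w, 0.0)
    row_max = w.max(axis=1, keepdims=True)
    if np.any(row_max <= 0):
        bad = np.flatnonzero(w.max(axis=1) <= 0)
        raise DegenerateBasisError(f"rows {bad.tolist()} have no positive mass")
    w = np.where(w >= f_threshold_frac * row_max, w, 0.0)
    sums = w.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        bad = np.flatnonzero(w.sum(axis=1) <= 0)
        raise DegenerateBasisError(f"rows {bad.tolist()} empty after thresholding")
    return TransitionMatrix(w / sums, provenance="basis-approximated")


def candidate_transitions(
    forms=("hexagonal", "community"),
    hex_shapes=DEFAULT_HEX_CANDIDATE_SHAPES,
    community_shapes=DEFAULT_COMMUNITY_CANDIDATE_SHAPES,
    f_threshold_frac: float = DEFAULT_F_THRESHOLD_FRAC,
    sigma: float = DEFAULT_CONNECTOR_SIGMA,
    connector_gain: float = DEFAULT_CONNECTOR_GAIN,
) -> list[tuple[str, int, TransitionMatrix]]:
    """Basis-approximated transition matrices for every (form, size) hypothesis.

    Hexagonal candidates share one native basis resized per shape; community
    candidates are rebuilt per shape.  Returns (form, n_nodes, matrix) tuples.
    """
    out: list[tuple[str, int, TransitionMatrix]] = []
    if "hexagonal" in forms:
        native = build_hex_basis()
        for rows, cols in hex_shapes:
            resized = resize_basis(native, rows, cols)
            out.append(
                ("hexagonal", rows * cols, approximate_transition(resized, f_threshold_frac))
            )
    if "community" in forms:
        for n_comm, comm_size in community_shapes:
            cb = build_community_basis(n_comm, comm_size, sigma, connector_gain)
            out.append(
                ("community", n_comm * comm_size, approximate_transition(cb, f_threshold_frac))
            )
    return out
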