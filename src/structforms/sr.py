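"""Associative baselines: successor representations and their variants.

The successor representation (SR) M = Σₜ γᵗAᵗ = (I − γA)⁻¹ holds discounted
expected future state occupancies under transition matrix A and discount γ.
It can be computed in closed form from a learnt transition matrix, or learnt
online by temporal-difference updates on observed transitions.  Because
occupancy decays with graph distance on these regular graphs, the entry
M(option, target) serves as a closeness score for distance-comparison
questions.  Spectral regularization reconstructs the symmetrized SR from its
m largest-eigenvalue components, smoothing occupancy over edges that were
never observed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .basis import TransitionMatrix
from .graphs import ObservationSequence

__all__ = [
    "SuccessorModel",
    "sr_closed_form",
    "td_sr_update",
    "td_sr_learn",
    "symmetrize",
    "spectral_regularize",
    "estimate_transition_counts",
    "sr_answer_question",
    "DEFAULT_GAMMA",
    "DEFAULT_ALPHA",
    "DEFAULT_N_COMPONENTS",
]

DEFAULT_GAMMA = 0.8
DEFAULT_ALPHA = 0.1
DEFAULT_N_COMPONENTS = 7


@dataclass(frozen=True)
class SuccessorModel:
    """Discounted expected-occupancy matrix with its learning metadata."""

    m: np.ndarray  # [states, states]
    gamma: float
    alpha: float | None = None
    variant: str = "analytic"  # analytic | td | regularized | transition-count

    @property
    def n_states(self) -> int:
        return self.m.shape[0]


def sr_closed_form(
    a: TransitionMatrix | np.ndarray, gamma: float = DEFAULT_GAMMA
) -> SuccessorModel:
    """Closed-form SR: M = (I − γA)⁻¹."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must be in [0, 1); the series diverges at 1")
    p = a.probs if isinstance(a, TransitionMatrix) else np.asarray(a, float)
    n = p.shape[0]
    m = np.linalg.solve(np.eye(n) - gamma * p, np.eye(n))
    return SuccessorModel(m=m, gamma=gamma, variant="analytic")


def td_sr_update(
    model: SuccessorModel,
    s_t: int,
    s_t1: int,
    alpha: float = DEFAULT_ALPHA,
    gamma: float | None = None,
) -> SuccessorModel:
    """One temporal-difference update after observing s_t → s_t1.

    M(s_t, ·) ← M(s_t, ·) + α·[1(s_t = ·) + γ·M(s_t1, ·) − M(s_t, ·)],
    applied simultaneously across successor states.
    """
    gamma = model.gamma if gamma is None else gamma
    m = model.m.copy()
    onehot = np.zeros(model.n_states)
    onehot[s_t] = 1.0
    m[s_t] = m[s_t] + alpha * (onehot + gamma * m[s_t1] - m[s_t])
    return replace(model, m=m, gamma=gamma, alpha=alpha, variant="td")


def td_sr_learn(
    model: SuccessorModel,
    obs: ObservationSequence,
    alpha: float = DEFAULT_ALPHA,
) -> SuccessorModel:
    """Run TD updates over an observation sequence (in-place batch wrapper).

    Walks trigger one update per step.  Presented pairs are bidirectional
    edges and trigger one update in each direction; there is no
    cross-pair bootstrapping because consecutive pairs are unrelated.
    """
    m = model.m.copy()
    gamma = model.gamma
    if obs.mode == "walk":
        transitions = zip(obs.items[:-1], obs.items[1:])
    else:
        transitions = (t for u, v in obs.items for t in ((u, v), (v, u)))
    for s_t, s_t1 in transitions:
        delta = gamma * m[s_t1] - m[s_t]
        delta[s_t] += 1.0
        m[s_t] += alpha * delta
    return replace(model, m=m, alpha=alpha, variant="td")


def symmetrize(model: SuccessorModel) -> SuccessorModel:
    """(M + Mᵀ)/2; idempotent."""
    return replace(model, m=0.5 * (model.m + model.m.T))


def spectral_regularize(
    model: SuccessorModel, n_components: int = DEFAULT_N_COMPONENTS
) -> SuccessorModel:
    """Reconstruct the symmetrized SR from its largest-eigenvalue components.

    The symmetrized SR is positive semidefinite in practice, so the largest
    algebraic eigenvalues are the most informative components; if negative
    eigenvalues of larger magnitude appear, |eigenvalue| ordering is used
    instead.  ``n_components`` at or above the rank returns the full matrix.
    """
    m = model.m
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("spectral regularization expects a symmetric SR")
    evals, evecs = np.linalg.eigh(m)
    if evals.min() >= -1e-8 * max(1.0, abs(evals.max())):
        order = np.argsort(-evals)
    else:
        order = np.argsort(-np.abs(evals))
    k = min(n_components, m.shape[0])
    idx = order[:k]
    rec = (evecs[:, idx] * evals[idx]) @ evecs[:, idx].T
    return replace(model, m=rec, variant="regularized")


def estimate_transition_counts(
    obs: ObservationSequence, n_states: int | None = None
) -> TransitionMatrix:
    """Row-normalized transition counts from observed transitions or pairs.

    Pairs count in both directions; rows never visited fall back to a
    uniform distribution.  ``n_states`` fixes the matrix size; by default it
    is inferred from the largest observed index.
    """
    items = np.asarray(obs.items, int)
    if items.size == 0:
        raise ValueError("empty observation sequence")
    n = int(items.max()) + 1 if n_states is None else int(n_states)
    if items.max() >= n:
        raise ValueError("observed state index exceeds n_states")
    counts = np.zeros((n, n))
    if obs.mode == "walk":
        np.add.at(counts, (items[:-1], items[1:]), 1.0)
    else:
        np.add.at(counts, (items[:, 0], items[:, 1]), 1.0)
        np.add.at(counts, (items[:, 1], items[:, 0]), 1.0)
    sums = counts.sum(axis=1, keepdims=True)
    probs = np.where(sums > 0, counts / np.maximum(sums, 1.0), 1.0 / n)
    probs /= probs.sum(axis=1, keepdims=True)
    return TransitionMatrix(probs, provenance="exact")


def sr_answer_question(
    model: SuccessorModel | np.ndarray,
    a: int,
    b: int,
    target: int,
    rng: np.random.Generator,
) -> int:
    """Choose the option with the larger discounted occupancy of the target.

    Higher expected future occupancy means fewer links on these regular
    graphs.  Exact ties are resolved by a seeded fair coin.
    """
    if len({a, b, target}) != 3:
        raise ValueError("option and target states must be distinct")
    m = model.m if isinstance(model, SuccessorModel) else np.asarray(model)
    ma, mb = m[a, target], m[b, target]
    if ma == mb:
        return a if rng.integers(2) == 0 else b
    return a if ma > mb else b
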