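"""Inverting the generative model: emission-only EM and structure posteriors.

The generative model treats a task as a hidden Markov model whose transition
matrix A is fixed by a structural form and a graph size (built by the basis
module), and whose emission matrix B maps abstract graph states to sensory
symbols.  Inference estimates B by expectation–maximization with the M-step
restricted to emissions (A is never updated), scores each (form, size)
hypothesis by a BIC approximation of the model evidence,
log L̂ − (N/2)·log k, and combines the scores with categorical priors into a
posterior over structural form and graph size.  The structural form is read
off the size-marginalized posterior; the size is then the conditional MAP
within that form, and that hypothesis's emission estimate is adopted.

Random-walk data is scored as one long sequence; pair-presentation data as
independent two-observation segments (pairs are sampled independently by
design).  All arithmetic is in the log domain with the standard scaling
tricks; the long-sequence E-step has a numba-compiled kernel with a
pure-numpy reference implementation kept for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .basis import TransitionMatrix
from .graphs import ObservationSequence

__all__ = [
    "InferencePriors",
    "EmissionMatrix",
    "EMOptions",
    "EMResult",
    "Candidate",
    "HypothesisScore",
    "StructurePosterior",
    "forward_log_likelihood",
    "estimate_emission",
    "bic_evidence",
    "infer_structure",
]


@dataclass(frozen=True)
class EmissionMatrix:
    """Row-stochastic state → symbol probability table."""

    probs: np.ndarray  # [n_states, n_symbols]

    def __post_init__(self):
        p = self.probs
        if p.ndim != 2:
            raise ValueError("emission matrix must be 2-D")
        if np.any(p < -1e-12) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("emission rows must be non-negative and sum to 1")

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class Candidate:
    """One structure hypothesis: a form, a size, and its transition matrix."""

    form: str
    size: int
    transition: TransitionMatrix


@dataclass(frozen=True)
class InferencePriors:
    """Categorical priors over structural forms and sizes within each form."""

    form_prior: dict[str, float]
    size_prior: dict[str, dict[int, float]]

    def __post_init__(self):
        if abs(sum(self.form_prior.values()) - 1.0) > 1e-9:
            raise ValueError("form prior must sum to 1")
        for form, sizes in self.size_prior.items():
            if abs(sum(sizes.values()) - 1.0) > 1e-9:
                raise ValueError(f"size prior for {form!r} must sum to 1")

    @staticmethod
    def uniform(candidates: list[Candidate]) -> "InferencePriors":
        forms = sorted({c.form for c in candidates})
        form_prior = {f: 1.0 / len(forms) for f in forms}
        size_prior = {}
        for f in forms:
            sizes = sorted({c.size for c in candidates if c.form == f})
            size_prior[f] = {s: 1.0 / len(sizes) for s in sizes}
        return InferencePriors(form_prior, size_prior)


@dataclass(frozen=True)
class EMOptions:
    """Settings for the emission-only EM.

    ``restarts`` random Dirichlet(1) initializations are screened for
    ``screen_iters`` iterations each; the best ``finalists`` are then run to
    convergence (tolerance ``tol`` on the log-likelihood, at most
    ``max_iter`` iterations).  ``init_emission`` adds a warm-start
    initialization to the pool.
    """

    restarts: int = 5
    tol: float = 1e-6
    max_iter: int = 200
    screen_iters: int = 30
    finalists: int = 2
    seed: int | None = None
    init_emission: np.ndarray | None = None  # optional warm start, used once


@dataclass(frozen=True)
class EMResult:
    emission: EmissionMatrix
    log_likelihood: float
    converged: bool
    history: tuple[float, ...]  # per-iteration log-likelihood of the best restart


@dataclass(frozen=True)
class HypothesisScore:
    form: str
    size: int
    log_likelihood: float
    n_states: int
    n_observations: int
    log_evidence: float
    emission: EmissionMatrix


@dataclass(frozen=True)
class StructurePosterior:
    scores: tuple[HypothesisScore, ...]
    posterior: np.ndarray  # aligned with scores, sums to 1
    map_form: str
    map_size: int
    emission: EmissionMatrix

    def to_dict(self) -> dict:
        return {
            "map_form": self.map_form,
            "map_size": self.map_size,
            "hypotheses": [
                {
                    "form": s.form,
                    "size": s.size,
                    "log_likelihood": s.log_likelihood,
                    "log_evidence": s.log_evidence,
                    "posterior": float(p),
                }
                for s, p in zip(self.scores, self.posterior)
            ],
        }


def _as_array(x, cls):
    if isinstance(x, cls):
        return x.probs
    return np.asarray(x, dtype=float)


def _check_dims(obs: ObservationSequence, a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] != b.shape[0]:
        raise ValueError("A and B disagree on the number of states")
    items = np.asarray(obs.items)
    if items.size and items.max() >= b.shape[1]:
        raise ValueError("observation symbol index exceeds emission matrix width")


def _forward_walk_numpy(items, a, b, pi) -> float:
    """Scaled forward recursion for a single sequence (reference path)."""
    alpha = pi * b[:, items[0]]
    total = 0.0
    for t in range(len(items)):
        if t > 0:
            alpha = (a.T @ alpha) * b[:, items[t]]
        c = alpha.sum()
        if c <= 0.0:
            return -np.inf
        total += np.log(c)
        alpha = alpha / c
    return total


def _pairs_log_likelihood(o1, o2, a, b, pi) -> float:
    f1 = pi[:, None] * b[:, o1]
    lik = np.einsum("ip,ip->p", f1, a @ b[:, o2])
    if np.any(lik <= 0.0):
        return -np.inf
    return float(np.log(lik).sum())


def forward_log_likelihood(
    obs: ObservationSequence,
    a: TransitionMatrix | np.ndarray,
    b: EmissionMatrix | np.ndarray,
    initial: np.ndarray | None = None,
) -> float:
    """log p(O | A, B, initial) via the scaled forward recursion.

    Pair-mode sequences are scored as independent two-observation segments.
    A sequence with zero probability returns ``-inf``.
    """
    a = _as_array(a, TransitionMatrix)
    b = _as_array(b, EmissionMatrix)
    _check_dims(obs, a, b)
    pi = np.full(a.shape[0], 1.0 / a.shape[0]) if initial is None else np.asarray(initial, float)
    if obs.mode == "walk":
        return _forward_walk_numpy(np.asarray(obs.items, int), a, b, pi)
    pairs = np.asarray(obs.items, int)
    return _pairs_log_likelihood(pairs[:, 0], pairs[:, 1], a, b, pi)


@njit(cache=False)
def _walk_gamma_numba(a, b_obs, pi):  # pragma: no cover - exercised via wrapper
    """Scaled forward-backward state posteriors for one sequence.

    ``b_obs[t, i] = B[i, o_t]``.  Returns (gamma [T, N], log-likelihood).
    """
    t_len, n = b_obs.shape
    alpha = np.empty((t_len, n))
    c = np.empty(t_len)
    tmp = pi * b_obs[0]
    s = tmp.sum()
    if s <= 0.0:
        return np.zeros((t_len, n)), -np.inf
    alpha[0] = tmp / s
    c[0] = s
    for t in range(1, t_len):
        pred = a.T @ np.ascontiguousarray(alpha[t - 1])
        tmp = pred * b_obs[t]
        s = tmp.sum()
        if s <= 0.0:
            return np.zeros((t_len, n)), -np.inf
        alpha[t] = tmp / s
        c[t] = s
    beta = np.empty((t_len, n))
    beta[t_len - 1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[t] = (a @ np.ascontiguousarray(beta[t + 1] * b_obs[t + 1])) / c[t + 1]
    gamma = alpha * beta
    for t in range(t_len):
        gamma[t] /= gamma[t].sum()
    loglik = np.log(c).sum()
    return gamma, loglik


def _walk_gamma_numpy(a, b_obs, pi):
    """Pure-numpy twin of :func:`_walk_gamma_numba` (kept for verification)."""
    t_len, n = b_obs.shape
    alpha = np.empty((t_len, n))
    c = np.empty(t_len)
    tmp = pi * b_obs[0]
    s = tmp.sum()
    if s <= 0.0:
        return np.zeros((t_len, n)), -np.inf
    alpha[0], c[0] = tmp / s, s
    for t in range(1, t_len):
        tmp = (a.T @ alpha[t - 1]) * b_obs[t]
        s = tmp.sum()
        if s <= 0.0:
            return np.zeros((t_len, n)), -np.inf
        alpha[t], c[t] = tmp / s, s
    beta = np.empty((t_len, n))
    beta[-1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[t] = (a @ (beta[t + 1] * b_obs[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, float(np.log(c).sum())


def _e_step_walk(items, onehot, a, b, pi, use_numba=True):
    b_obs = np.ascontiguousarray(b[:, items].T)
    kernel = _walk_gamma_numba if use_numba else _walk_gamma_numpy
    gamma, loglik = kernel(a, b_obs, pi)
    if not np.isfinite(loglik):
        return None, -np.inf
    return gamma.T @ onehot, loglik


def _e_step_pairs(o1, o2, onehot1, onehot2, a, b, pi):
    b1 = b[:, o1]
    b2 = b[:, o2]
    f1 = pi[:, None] * b1
    beta1 = a @ b2
    lik = np.einsum("ip,ip->p", f1, beta1)
    if np.any(lik <= 0.0):
        return None, -np.inf
    g1 = f1 * beta1 / lik
    g2 = (a.T @ f1) * b2 / lik
    counts = g1 @ onehot1 + g2 @ onehot2
    return counts, float(np.log(lik).sum())


def estimate_emission(
    obs: ObservationSequence,
    a: TransitionMatrix | np.ndarray,
    n_symbols: int,
    opts: EMOptions = EMOptions(),
    rng: np.random.Generator | None = None,
) -> EMResult:
    """Maximum-likelihood emission matrix under a fixed transition matrix.

    Runs EM with a forward–backward E-step and an emission-only M-step from
    ``opts.restarts`` random Dirichlet(1) initializations (plus an optional
    warm start).  The per-iteration likelihood is non-decreasing; iteration
    stops when the improvement drops below ``opts.tol`` or at
    ``opts.max_iter`` (flagged as non-converged).
    """
    a = _as_array(a, TransitionMatrix)
    n = a.shape[0]
    items = np.asarray(obs.items, int)
    if items.size == 0:
        raise ValueError("empty observation sequence")
    if items.max() >= n_symbols:
        raise ValueError("observed symbol index exceeds n_symbols")
    if rng is None:
        rng = np.random.default_rng(opts.seed)
    pi = np.full(n, 1.0 / n)
    if obs.mode == "walk":
        onehot = np.zeros((len(items), n_symbols))
        onehot[np.arange(len(items)), items] = 1.0

        def e_step(b):
            return _e_step_walk(items, onehot, a, b, pi)

    else:
        o1, o2 = items[:, 0], items[:, 1]
        onehot1 = np.zeros((len(o1), n_symbols))
        onehot1[np.arange(len(o1)), o1] = 1.0
        onehot2 = np.zeros((len(o2), n_symbols))
        onehot2[np.arange(len(o2)), o2] = 1.0

        def e_step(b):
            return _e_step_pairs(o1, o2, onehot1, onehot2, a, b, pi)

    def run_em(b, n_iter):
        history: list[float] = []
        prev = -np.inf
        converged = False
        for _ in range(n_iter):
            counts, loglik = e_step(b)
            history.append(loglik)
            if counts is None:
                break
            row = counts.sum(axis=1, keepdims=True)
            b = np.where(row > 1e-300, counts / np.maximum(row, 1e-300), 1.0 / n_symbols)
            if np.isfinite(prev) and loglik - prev < opts.tol:
                converged = True
                break
            prev = loglik
        final = history[-1] if history else -np.inf
        return final, b, converged, history

    inits = []
    if opts.init_emission is not None:
        init = np.asarray(opts.init_emission, float)
        if init.shape != (n, n_symbols):
            raise ValueError("warm-start emission has wrong shape")
        inits.append(init)
    for _ in range(opts.restarts):
        inits.append(rng.dirichlet(np.ones(n_symbols), size=n))

    # Screen all initializations briefly, then run the best few to convergence.
    screened = [run_em(b0.copy(), min(opts.screen_iters, opts.max_iter)) for b0 in inits]
    screened.sort(key=lambda r: -r[0])
    best: tuple[float, np.ndarray, bool, list[float]] | None = None
    for final, b, converged, history in screened[: max(1, opts.finalists)]:
        if not converged and opts.max_iter > opts.screen_iters:
            final2, b2, converged2, history2 = run_em(b, opts.max_iter - len(history))
            if final2 >= final:
                final, b, converged = final2, b2, converged2
                history = history + history2
        if best is None or final > best[0]:
            best = (final, b, converged, history)
    loglik, b, converged, history = best
    # Guard rows that renormalized to uniform exactly (unoccupied states).
    b = b / b.sum(axis=1, keepdims=True)
    return EMResult(
        emission=EmissionMatrix(b),
        log_likelihood=float(loglik),
        converged=converged,
        history=tuple(history),
    )


def bic_evidence(log_likelihood: float, n_states: int, n_observations: int) -> float:
    """BIC-approximated log evidence: log L̂ − (N/2)·log(k).

    The penalty uses the state count N (not the free-parameter count),
    exactly as the model evidence approximation is defined here.
    """
    if n_observations < 1:
        raise ValueError("need at least one observation")
    return log_likelihood - 0.5 * n_states * np.log(n_observations)


def infer_structure(
    obs: ObservationSequence,
    candidates: list[Candidate],
    priors: InferencePriors | None = None,
    opts: EMOptions = EMOptions(),
    rng: np.random.Generator | None = None,
    n_symbols: int | None = None,
    warm_starts: dict[tuple[str, int], np.ndarray] | None = None,
) -> StructurePosterior:
    """Posterior over (structural form, graph size) given observations.

    For every candidate the emission matrix is fitted by
    :func:`estimate_emission`, the evidence approximated by
    :func:`bic_evidence`, and the log evidences are combined with the log
    priors and normalized by log-sum-exp.  The MAP form maximizes the
    size-marginalized posterior; the MAP size maximizes the posterior within
    that form; that hypothesis's emission estimate is returned.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if priors is None:
        priors = InferencePriors.uniform(candidates)
    if rng is None:
        rng = np.random.default_rng(opts.seed)
    if n_symbols is None:
        n_symbols = int(np.asarray(obs.items).max()) + 1
    k = obs.n_observations
    scores = []
    log_post = []
    for cand in candidates:
        cand_opts = opts
        if warm_starts and (cand.form, cand.size) in warm_starts:
            cand_opts = replace(opts, init_emission=warm_starts[(cand.form, cand.size)])
        res = estimate_emission(obs, cand.transition, n_symbols, cand_opts, rng=rng)
        ev = bic_evidence(res.log_likelihood, cand.transition.n_states, k)
        scores.append(
            HypothesisScore(
                form=cand.form,
                size=cand.size,
                log_likelihood=res.log_likelihood,
                n_states=cand.transition.n_states,
                n_observations=k,
                log_evidence=ev,
                emission=res.emission,
            )
        )
        log_post.append(
            ev
            + np.log(priors.form_prior[cand.form])
            + np.log(priors.size_prior[cand.form][cand.size])
        )
    log_post = np.asarray(log_post)
    if not np.any(np.isfinite(log_post)):
        raise ValueError("all candidate evidences are -inf; data impossible under every hypothesis")
    posterior = np.exp(log_post - logsumexp(log_post))
    posterior /= posterior.sum()
    forms = sorted({s.form for s in scores})
    form_marginal = {
        f: logsumexp(log_post[[i for i, s in enumerate(scores) if s.form == f]])
        for f in forms
    }
    map_form = max(form_marginal, key=form_marginal.get)
    within = [i for i, s in enumerate(scores) if s.form == map_form]
    map_idx = within[int(np.argmax(log_post[within]))]
    return StructurePosterior(
        scores=tuple(scores),
        posterior=posterior,
        map_form=map_form,
        map_size=scores[map_idx].size,
        emission=scores[map_idx].emission,
    )
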