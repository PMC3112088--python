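"""Continuous-time Markov chains for discrete characters on a tree.

Provides rate-matrix constructors, transition probabilities P(t) = exp(Qt),
and the pruning (post-order) log-likelihood with per-node rescaling.

A k-state character evolves along each branch of length t (substitutions
per site) with transition probabilities exp(Qt), where Q has non-negative
off-diagonal instantaneous rates and rows summing to zero. The three-state
all-rates-different (ARD) model used for rDNA-cluster states
(0 = absent, 1 = pericentromeric, 2 = distal) has six free rates.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .phylo_core import Tree, postorder

__all__ = [
    "build_ard_q",
    "build_q",
    "transition_probs",
    "branch_transition_probs",
    "uniform_prior",
    "stationary_prior",
    "tip_vector",
    "tips_to_array",
    "log_likelihood",
]

#: documented order of the six ARD rates
ARD_RATE_ORDER = ("0->1", "0->2", "1->0", "1->2", "2->0", "2->1")

_ROW_SUM_TOL = 1e-12


def build_q(k: int, rates: dict[tuple[int, int], float]) -> np.ndarray:
    """Generator matrix of dimension ``k`` from an off-diagonal rate map."""
    Q = np.zeros((k, k))
    for (i, j), r in rates.items():
        if i == j:
            raise ValueError("diagonal entries are determined by the row sums")
        if r < 0:
            raise ValueError(f"negative rate for {i}->{j}: {r}")
        Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_ard_q(rates) -> np.ndarray:
    """3-state all-rates-different generator.

    ``rates`` are the six off-diagonal rates in the order
    0->1, 0->2, 1->0, 1->2, 2->0, 2->1.
    """
    r = np.asarray(rates, dtype=float)
    if r.shape != (6,):
        raise ValueError("expected exactly 6 rates")
    pairs = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    return build_q(3, dict(zip(pairs, r)))


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a single branch length ``t`` >= 0."""
    if t < 0:
        raise ValueError(f"negative branch length: {t}")
    P = expm(np.asarray(Q, dtype=float) * t)
    return np.clip(P, 0.0, 1.0)


def branch_transition_probs(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for every t in ``ts`` at once, shape (len(ts), k, k).

    Uses the eigendecomposition of Q when it is well conditioned (the
    generic case for ARD-type matrices), falling back to scaling-and-
    squaring per distinct branch length otherwise. Q need not be
    symmetric or diagonalizable.
    """
    Q = np.asarray(Q, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("negative branch length")
    k = Q.shape[0]
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        # P(t) = V diag(e^{lam t}) V^-1, batched over t
        E = np.exp(np.outer(ts, lam))  # (n, k)
        P = np.einsum("ij,nj,jl->nil", V, E, Vinv)
        P = np.real_if_close(P, tol=1e6).real
    else:
        P = np.empty((len(ts), k, k))
        cache: dict[float, np.ndarray] = {}
        for idx, t in enumerate(ts):
            if t not in cache:
                cache[t] = expm(Q * t)
            P[idx] = cache[t]
    P = np.clip(P, 0.0, 1.0)
    return P


def uniform_prior(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


def stationary_prior(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0, by null-space extraction."""
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def tip_vector(state, k: int) -> np.ndarray:
    """Observation vector for one tip: unit vector, or all ones for '?'."""
    if state in ("?", None):
        return np.ones(k)
    s = int(state)
    if not 0 <= s < k:
        raise ValueError(f"state {state} outside 0..{k - 1}")
    v = np.zeros(k)
    v[s] = 1.0
    return v


def tips_to_array(tree: Tree, tip_data: dict[str, np.ndarray], k: int) -> np.ndarray:
    """Stack per-tip observation vectors into an (n_nodes, k) array.

    ``tip_data`` maps tip label -> length-k vector; its label set must
    equal the tree's tips exactly.
    """
    have = set(tip_data)
    want = set(tree.tip_labels)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValueError(f"tip data mismatch: missing {missing}, unexpected {extra}")
    obs = np.ones((tree.n_nodes, k))
    for v in tree.tips:
        vec = np.asarray(tip_data[tree.label[v]], dtype=float)
        if vec.shape != (k,) or vec.max() <= 0:
            raise ValueError(f"invalid observation vector for tip {tree.label[v]}")
        obs[v] = vec
    return obs


def _partials(tree: Tree, obs: np.ndarray, P: np.ndarray):
    """Post-order conditional likelihoods with per-node rescaling.

    Returns ``(L, logscale, order)`` where ``L[v, s]`` is the (rescaled)
    probability of the data below node v given state s at v, and
    ``logscale`` the accumulated log of the scaling factors.
    """
    n, k = obs.shape
    L = np.array(obs, dtype=float)
    logscale = 0.0
    order = postorder(tree)
    for v in order:
        for c in tree.children[v]:
            L[v] *= P[c] @ L[c]
        m = L[v].max()
        if m <= 0:
            raise FloatingPointError(f"zero partial likelihood at node {v}")
        if m < 1e-250:
            L[v] /= m
            logscale += np.log(m)
    return L, logscale, order


def log_likelihood(
    tree: Tree,
    tip_data: dict[str, np.ndarray],
    Q: np.ndarray,
    prior: np.ndarray,
) -> float:
    """Pruning log-likelihood of the tip observations under (Q, prior).

    The prior is the state distribution at the root. Missing data ('?')
    enter as all-ones observation vectors, so a fully missing character
    has log-likelihood 0.
    """
    Q = np.asarray(Q, dtype=float)
    prior = np.asarray(prior, dtype=float)
    k = Q.shape[0]
    if abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
        raise ValueError("root prior must be a probability vector")
    obs = tips_to_array(tree, tip_data, k)
    P = branch_transition_probs(Q, np.asarray(tree.length))
    L, logscale, _ = _partials(tree, obs, P)
    lik = float(prior @ L[tree.root])
    if lik <= 0 or not np.isfinite(lik):
        raise FloatingPointError("non-finite likelihood")
    return float(np.log(lik) + logscale)
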