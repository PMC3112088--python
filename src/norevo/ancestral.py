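"""ML ancestral reconstruction of rDNA-cluster states per segment.

For each orthologous segment the three-state character
(0 = absent, 1 = pericentromeric, 2 = distal) is fitted under the
all-rates-different (ARD) model by bounded multi-start maximum
likelihood; marginal (empirical-Bayes) posterior state probabilities are
then computed at every node by an up/down pass, states are called with
an inclusive probability threshold (default 75%), and cluster
insertion/deletion events are read off branches whose endpoints have
determinate, different presence status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import ctmc
from .phylo_core import Tree, preorder

__all__ = [
    "FittedARD",
    "AncestralTable",
    "EventCall",
    "fit_ard",
    "marginal_probs",
    "classify_states",
    "call_events",
]

STATE_NAMES = ("absent", "pericentromeric", "distal")
PRESENT = {"pericentromeric", "distal"}

RATE_BOUNDS = (1e-8, 100.0)  # on a tree rescaled to unit height


@dataclass
class FittedARD:
    """Result of a multi-start ARD fit."""

    rates: np.ndarray  # six rates, order ctmc.ARD_RATE_ORDER, original tree units
    log_likelihood: float
    converged: bool
    n_restarts: int
    prior: np.ndarray

    def q_matrix(self) -> np.ndarray:
        return ctmc.build_ard_q(self.rates)


@dataclass
class AncestralTable:
    """Per-node state probabilities and (optional) threshold calls."""

    tree: Tree
    probs: np.ndarray  # (n_nodes, 3), rows sum to 1
    calls: list[str] | None = None
    threshold: float | None = None
    segment: str | None = None
    _extra: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in range(self.tree.n_nodes):
            rows.append(
                {
                    "node": v,
                    "clade": "|".join(self.tree.clade_tips(v)),
                    "is_tip": self.tree.is_tip(v),
                    **{f"p_{name}": self.probs[v, s] for s, name in enumerate(STATE_NAMES)},
                    "call": self.calls[v] if self.calls is not None else "",
                }
            )
        return pd.DataFrame(rows)


@dataclass
class EventCall:
    """A cluster insertion or deletion on a branch of the tree.

    ``parent_node``/``child_node`` bound the determinate ancestor-
    descendant pair; ``node`` is the reporting node — the deepest
    (rootward-most) node at which the new state holds — and
    ``probability_pct`` the posterior support (%) of the new presence
    status there.
    """

    type: str  # "insertion" | "deletion"
    parent_node: int
    child_node: int
    node: int
    probability_pct: float
    terminal: bool
    segment: str | None = None


def _loglik_fn(tree: Tree, obs: np.ndarray, prior: np.ndarray):
    """Closure evaluating the pruning lnL from the 6 log-rates."""
    lengths = np.asarray(tree.length)

    def fn(log_rates: np.ndarray) -> float:
        Q = ctmc.build_ard_q(np.exp(log_rates))
        P = ctmc.branch_transition_probs(Q, lengths)
        try:
            L, logscale, _ = ctmc._partials(tree, obs, P)
        except FloatingPointError:
            return np.inf  # data impossible under these boundary rates
        lik = float(prior @ L[tree.root])
        if lik <= 0 or not np.isfinite(lik):
            return np.inf
        return -(np.log(lik) + logscale)

    return fn


def _scaled_copy(tree: Tree, factor: float) -> Tree:
    return Tree(
        parent=list(tree.parent),
        children=[list(c) for c in tree.children],
        length=[t * factor for t in tree.length],
        label=list(tree.label),
        root=tree.root,
    )


def _shrink_flat_rates(neg, x, f, lo, tol=1e-9):
    """Send each log-rate to the lower bound when the likelihood is flat in it.

    Rates the data carry no information about (e.g. loss rates of a state
    never observed) are unidentifiable: the optimizer leaves them at
    arbitrary values, which would smear ancestral posteriors. Preferring
    the smallest such rate is the determinate tie-break.
    """
    x = np.array(x, dtype=float)
    for i in range(len(x)):
        if x[i] <= lo:
            continue
        trial = x.copy()
        trial[i] = lo
        f_trial = neg(trial)
        if f_trial <= f + tol:
            x, f = trial, min(f, f_trial)
    return x, f


def fit_ard(
    tree: Tree,
    tip_data: dict[str, np.ndarray],
    *,
    prior: np.ndarray | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    initial_rates=None,
) -> FittedARD:
    """Fit the six ARD rates by bounded multi-start ML.

    The tree is internally rescaled to unit height so the rate bounds
    ``[1e-8, 100]`` are meaningful regardless of the branch-length scale;
    reported rates are per original branch-length unit. The fit is
    deterministic given ``seed``. ``initial_rates`` (original units) may
    supply extra starting points; the returned log-likelihood is the best
    over all tried starts.
    """
    prior = ctmc.uniform_prior(3) if prior is None else np.asarray(prior, float)
    obs = ctmc.tips_to_array(tree, tip_data, 3)
    informative = [v for v in tree.tips if obs[v].sum() < 3]
    if not informative:
        raise ValueError("all tips missing: nothing to fit")

    h = tree.height()
    if h <= 0:
        raise ValueError("tree has zero height")
    work = _scaled_copy(tree, 1.0 / h)
    neg = _loglik_fn(work, obs, prior)

    rng = np.random.default_rng(seed)
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
    starts = [np.full(6, np.log(0.5))]
    for _ in range(n_restarts):
        starts.append(rng.uniform(np.log(1e-3), np.log(10.0), size=6))
    if initial_rates is not None:
        r0 = np.clip(np.asarray(initial_rates, float) * h, *RATE_BOUNDS)
        starts.append(np.log(r0))

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * 6,
            options={"maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x, fbest = _shrink_flat_rates(neg, best.x, best.fun, lo)
    rates_unit = np.exp(x)
    return FittedARD(
        rates=rates_unit / h,
        log_likelihood=-float(fbest),
        converged=any_converged,
        n_restarts=n_restarts,
        prior=prior,
    )


def marginal_probs(
    tree: Tree,
    tip_data: dict[str, np.ndarray],
    model: FittedARD | np.ndarray,
    prior: np.ndarray | None = None,
    segment: str | None = None,
) -> AncestralTable:
    """Marginal posterior state probabilities at every node.

    Implements the two-pass (up/down) algorithm: the post-order pass
    yields the conditional likelihood of the data below each node, the
    pre-order pass the likelihood of everything outside its subtree;
    their product, renormalised per node, is the exact marginal posterior
    (it agrees with brute-force enumeration over all internal
    assignments). Tip rows carry the observation (or its posterior when
    the tip is missing).
    """
    if isinstance(model, FittedARD):
        Q = model.q_matrix()
        prior = model.prior if prior is None else prior
    else:
        Q = np.asarray(model, float)
    k = Q.shape[0]
    prior = ctmc.uniform_prior(k) if prior is None else np.asarray(prior, float)

    obs = ctmc.tips_to_array(tree, tip_data, k)
    P = ctmc.branch_transition_probs(Q, np.asarray(tree.length))
    L, _, _ = ctmc._partials(tree, obs, P)

    down = np.zeros_like(L)
    down[tree.root] = prior
    for v in preorder(tree):
        kids = tree.children[v]
        if not kids:
            continue
        msgs = {c: P[c] @ L[c] for c in kids}  # (k,) message from child c
        for c in kids:
            sib = down[v].copy()
            for b in kids:
                if b != c:
                    sib *= msgs[b]
            vec = sib @ P[c]
            s = vec.sum()
            down[c] = vec / s if s > 0 else vec

    post = down * L
    post /= post.sum(axis=1, keepdims=True)
    return AncestralTable(tree=tree, probs=post, segment=segment)


def classify_states(table: AncestralTable, threshold: float = 0.75) -> AncestralTable:
    """Call each node's state where its posterior reaches ``threshold``.

    The threshold is inclusive (a probability exactly at it counts as
    known) and must lie in (0.5, 1] so at most one state can qualify.
    Returns a new table with ``calls`` populated.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    calls = []
    for row in table.probs:
        s = int(np.argmax(row))
        calls.append(STATE_NAMES[s] if row[s] >= threshold else "unknown")
    return AncestralTable(
        tree=table.tree,
        probs=table.probs,
        calls=calls,
        threshold=threshold,
        segment=table.segment,
    )


def _status(call: str) -> str | None:
    if call == "unknown":
        return None
    return "present" if call in PRESENT else "absent"


def call_events(
    tree: Tree,
    table: AncestralTable,
    *,
    adjacent_only: bool = False,
) -> list[EventCall]:
    """Insertion/deletion events from a called ancestral table.

    An event is recorded for each determinate node whose presence status
    differs from its nearest determinate ancestor; intervening "unknown"
    nodes are skipped so the event is attributed to the deepest
    determinate ancestor-descendant pair (set ``adjacent_only`` to
    restrict to strictly adjacent pairs instead). Events reported at a
    tip sit on a terminal branch; all others are deep-node events.
    """
    if table.calls is None:
        raise ValueError("table has no calls; run classify_states first")
    status = [_status(c) for c in table.calls]
    events: list[EventCall] = []
    for v in preorder(tree):
        if v == tree.root or status[v] is None:
            continue
        a = tree.parent[v]
        if not adjacent_only:
            while a >= 0 and status[a] is None:
                a = tree.parent[a]
        if a < 0 or status[a] is None or status[a] == status[v]:
            continue
        etype = "insertion" if status[v] == "present" else "deletion"
        if status[v] == "present":
            support = table.probs[v, 1] + table.probs[v, 2]
        else:
            support = table.probs[v, 0]
        events.append(
            EventCall(
                type=etype,
                parent_node=a,
                child_node=v,
                node=v,
                probability_pct=100.0 * float(support),
                terminal=tree.is_tip(v),
                segment=table.segment,
            )
        )
    return events
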