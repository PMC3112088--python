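"""Correlated evolution of centromere/rDNA-cluster pairs (Pagel's test).

Two binary traits (centromere presence, cluster presence) on the same
tree are modelled jointly as a 4-state chain over the combined states
(0,0), (0,1), (1,0), (1,1). Under the independent model each trait flips
at rates that ignore the other trait (4 free parameters); under the
dependent model every single-trait flip rate is conditioned on the other
trait's current state (8 free parameters). Simultaneous double flips
have rate zero in both. Twice the log-likelihood gain of the dependent
model is referred to a chi-square distribution with 4 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from . import ctmc
from .phylo_core import Tree

__all__ = [
    "PairTrait",
    "LRTResult",
    "build_independent_q",
    "build_dependent_q",
    "fit_pair_model",
    "lrt",
    "retained_segments",
    "run_all_segments",
]

# combined state order: index = 2*trait1 + trait2
COMBINED_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))

#: dependent-model rate order: each single-trait flip conditioned on the other trait
DEPENDENT_RATE_ORDER = (
    "gain1|2=0",  # (0,0)->(1,0)
    "gain1|2=1",  # (0,1)->(1,1)
    "loss1|2=0",  # (1,0)->(0,0)
    "loss1|2=1",  # (1,1)->(0,1)
    "gain2|1=0",  # (0,0)->(0,1)
    "gain2|1=1",  # (1,0)->(1,1)
    "loss2|1=0",  # (0,1)->(0,0)
    "loss2|1=1",  # (1,1)->(1,0)
)

_DEP_TRANSITIONS = [
    (0, 2), (1, 3), (2, 0), (3, 1),  # trait-1 flips, conditioned on trait 2
    (0, 1), (2, 3), (1, 0), (3, 2),  # trait-2 flips, conditioned on trait 1
]

LRT_DF = 4
NESTING_TOL = 1e-6
RATE_BOUNDS = (1e-8, 100.0)


@dataclass
class PairTrait:
    """Per-taxon (centromere, cluster) binary observations; '?' allowed."""

    data: dict[str, tuple]  # taxon -> (trait1, trait2), entries in {0, 1, "?"}

    def observation_vectors(self) -> dict[str, np.ndarray]:
        out = {}
        for taxon, (t1, t2) in self.data.items():
            vec = np.zeros(4)
            for idx, (s1, s2) in enumerate(COMBINED_STATES):
                ok1 = t1 in ("?", None) or int(t1) == s1
                ok2 = t2 in ("?", None) or int(t2) == s2
                if ok1 and ok2:
                    vec[idx] = 1.0
            out[taxon] = vec
        return out

    def n_observed(self) -> int:
        return sum(
            1 for t1, t2 in self.data.values() if t1 not in ("?", None) and t2 not in ("?", None)
        )


@dataclass
class LRTResult:
    segment: str | None
    lnl_independent: float
    lnl_dependent: float
    statistic: float
    df: int
    p_value: float


def build_independent_q(a1: float, b1: float, a2: float, b2: float) -> np.ndarray:
    """4-state generator with trait-1 gain/loss (a1, b1) and trait-2 (a2, b2)."""
    return build_dependent_q([a1, a1, b1, b1, a2, a2, b2, b2])


def build_dependent_q(rates) -> np.ndarray:
    """4-state generator with the 8 conditioned flip rates.

    Rate order follows :data:`DEPENDENT_RATE_ORDER`; double transitions
    (both traits changing at once) keep rate zero.
    """
    r = np.asarray(rates, dtype=float)
    if r.shape != (8,):
        raise ValueError("expected exactly 8 rates")
    return ctmc.build_q(4, dict(zip(_DEP_TRANSITIONS, r)))


def _neg_loglik(tree: Tree, obs_vectors, builder, prior):
    obs = ctmc.tips_to_array(tree, obs_vectors, 4)
    lengths = np.asarray(tree.length)

    def fn(log_rates):
        Q = builder(np.exp(log_rates))
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


def _optimize(neg, starts, n_params):
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
    best = None
    converged = False
    for x0 in starts:
        res = minimize(
            neg,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * n_params,
            options={"maxiter": 500},
        )
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    from .ancestral import _shrink_flat_rates

    x, fbest = _shrink_flat_rates(neg, best.x, best.fun, lo)
    return np.exp(x), -float(fbest), converged


def fit_pair_model(
    tree: Tree,
    pair: PairTrait,
    kind: str,
    *,
    prior: np.ndarray | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    independent_mle: np.ndarray | None = None,
):
    """ML fit of the independent or dependent pair model.

    Returns ``(lnL, rates)``. The tree is rescaled internally to unit
    height (rates are reported per original branch-length unit). For the
    dependent model the search is warm-started from the independent MLE
    (when supplied) plus ``n_restarts`` jittered/random restarts, which
    keeps the fits nested up to optimizer tolerance.
    """
    if kind not in ("independent", "dependent"):
        raise ValueError(f"unknown model kind: {kind}")
    if pair.n_observed() < 1:
        raise ValueError("need at least one taxon with both traits observed")
    prior = ctmc.uniform_prior(4) if prior is None else np.asarray(prior, float)

    h = tree.height()
    from .ancestral import _scaled_copy  # shared tree utility

    work = _scaled_copy(tree, 1.0 / h)
    obs_vectors = pair.observation_vectors()
    rng = np.random.default_rng(seed)

    if kind == "independent":
        neg = _neg_loglik(work, obs_vectors, lambda r: build_independent_q(*r), prior)
        n_params = 4
        starts = [np.full(4, np.log(0.5))]
        for _ in range(n_restarts):
            starts.append(rng.uniform(np.log(1e-3), np.log(10.0), size=4))
    else:
        neg = _neg_loglik(work, obs_vectors, build_dependent_q, prior)
        n_params = 8
        starts = []
        if independent_mle is not None:
            a1, b1, a2, b2 = np.asarray(independent_mle, float) * h
            warm = np.log(np.clip([a1, a1, b1, b1, a2, a2, b2, b2], *RATE_BOUNDS))
            starts.append(warm)
            for _ in range(max(0, n_restarts - 1)):
                starts.append(warm + rng.normal(0.0, 0.5, size=8))
        else:
            starts.append(np.full(8, np.log(0.5)))
        for _ in range(n_restarts):
            starts.append(rng.uniform(np.log(1e-3), np.log(10.0), size=8))

    rates_unit, lnl, _ = _optimize(neg, starts, n_params)
    return lnl, rates_unit / h


def lrt(lnl_independent: float, lnl_dependent: float, segment: str | None = None) -> LRTResult:
    """Likelihood-ratio test of dependent (8p) vs independent (4p) evolution.

    statistic = 2 (lnL_dep - lnL_indep), referred to chi-square, df = 4.
    A statistic within ``NESTING_TOL`` below zero is clamped to 0; a
    larger violation signals an optimizer failure and raises.
    """
    if not (np.isfinite(lnl_independent) and np.isfinite(lnl_dependent)):
        raise ValueError("non-finite log-likelihood")
    stat = 2.0 * (lnl_dependent - lnl_independent)
    if stat < -2 * NESTING_TOL:
        raise ValueError(
            f"dependent lnL {lnl_dependent} below independent {lnl_independent}: "
            "nested-model violation (optimizer failure)"
        )
    stat = max(stat, 0.0)
    return LRTResult(
        segment=segment,
        lnl_independent=lnl_independent,
        lnl_dependent=lnl_dependent,
        statistic=stat,
        df=LRT_DF,
        p_value=float(chi2.sf(stat, LRT_DF)),
    )


def pair_lrt(
    tree: Tree,
    pair: PairTrait,
    *,
    n_restarts: int = 4,
    seed: int = 0,
    segment: str | None = None,
) -> LRTResult:
    """Fit both models and return the likelihood-ratio test."""
    lnl_ind, rates_ind = fit_pair_model(
        tree, pair, "independent", n_restarts=n_restarts, seed=seed
    )
    lnl_dep, _ = fit_pair_model(
        tree,
        pair,
        "dependent",
        n_restarts=n_restarts,
        seed=seed + 1,
        independent_mle=rates_ind,
    )
    return lrt(lnl_ind, max(lnl_dep, lnl_ind), segment=segment)


def retained_segments(matrix: pd.DataFrame) -> list[str]:
    """Segments kept for the correlated-evolution test.

    A segment is dropped when no taxon ever carries a cluster on it, or
    when the only clusters ever observed on it sit at the telomeric
    (distal) position; both cases leave the cluster trait uninformative
    about a centromere association.
    """
    keep = []
    for seg in matrix.columns:
        vals = {str(v) for v in matrix[seg] if str(v) in ("1", "2")}
        if "1" in vals:
            keep.append(seg)
    return keep


def run_all_segments(
    tree: Tree,
    matrix: pd.DataFrame,
    centromeres: pd.DataFrame,
    *,
    alpha: float = 0.05,
    n_restarts: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Pagel's test for every retained segment; one row each, sorted by p.

    ``matrix`` holds cluster states (taxa x segments, values 0/1/2/?);
    cluster presence is binarized (1 or 2 -> 1). ``centromeres`` holds
    0/1/? centromere presence with the same shape. Segments with no
    cluster anywhere or clusters only at the telomeric position are
    excluded before fitting.
    """
    segs = retained_segments(matrix)
    rows = []
    for i, seg in enumerate(segs):
        data = {}
        for taxon in matrix.index:
            c = str(centromeres.loc[taxon, seg])
            r = str(matrix.loc[taxon, seg])
            t1 = "?" if c == "?" else int(c)
            t2 = "?" if r == "?" else int(r in ("1", "2"))
            data[taxon] = (t1, t2)
        res = pair_lrt(
            tree,
            PairTrait(data),
            n_restarts=n_restarts,
            seed=seed + 1000 * i,
            segment=seg,
        )
        rows.append(
            {
                "segment": seg,
                "lnl_independent": res.lnl_independent,
                "lnl_dependent": res.lnl_dependent,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
            }
        )
    out = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    return out
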