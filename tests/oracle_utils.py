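"""Brute-force enumeration oracles, independent of the pruning code path.

Likelihood and marginals are computed by summing over every assignment of
states to internal nodes, with per-branch transition matrices obtained
directly from scipy's expm. Only feasible for tiny trees.
"""

from itertools import product

import numpy as np
from scipy.linalg import expm

from norevo.ctmc import tips_to_array
from norevo.phylo_core import Tree


def _branch_matrices(tree: Tree, Q: np.ndarray) -> dict[int, np.ndarray]:
    return {v: expm(np.asarray(Q, float) * tree.length[v]) for v in range(tree.n_nodes)}


def brute_force(tree: Tree, tip_data: dict, Q: np.ndarray, prior: np.ndarray):
    """(log-likelihood, internal-node marginals) by exhaustive enumeration."""
    k = Q.shape[0]
    obs = tips_to_array(tree, tip_data, k)
    P = _branch_matrices(tree, Q)
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    marg = {v: np.zeros(k) for v in internals}
    total = 0.0
    for assign in product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        w = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            pa = st[tree.parent[v]]
            if tree.children[v]:
                w *= P[v][pa, st[v]]
            else:
                w *= float(P[v][pa] @ obs[v])
        total += w
        for v in internals:
            marg[v][st[v]] += w
    marginals = np.zeros((tree.n_nodes, k))
    for v in internals:
        marginals[v] = marg[v] / total
    return float(np.log(total)), marginals


def random_tree_newick(n_tips: int, rng: np.random.Generator) -> str:
    """Random binary topology with exponential branch lengths."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.exponential(0.5, size=2) + 0.01
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    return nodes[0] + ";"
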