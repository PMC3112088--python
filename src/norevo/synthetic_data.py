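"""Simulators and the packaged study fixture.

Trees are generated under a Yule (pure-birth) process and discrete
characters by exact stochastic simulation (exponential waiting times)
of the continuous-time Markov chain along each branch, so every stage of
the analysis can be exercised, calibrated and power-tested without any
external data. The packaged study fixture bundles the 23-taxon reference
tree, the karyotype table, the homology map, centromere annotations and
the breakpoint list; tree branch lengths, the non-house homology map,
the centromere table and the breakpoint placements are synthetic
transcriptions (see the data files' headers).

Every simulator draws from a dedicated numpy Generator derived from
(seed, operation-code), so repeated or reordered calls with the same
seed are bit-reproducible and mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import ctmc
from .characters import (
    HomologyMap,
    SpeciesKaryotype,
    encode_matrix,
    load_homology_map,
    load_karyotypes,
)
from .cooccurrence import BreakpointRecord, load_breakpoints
from .pagel import PairTrait, build_dependent_q, build_independent_q
from .phylo_core import Tree, parse_newick, preorder

__all__ = [
    "simulate_tree",
    "simulate_character",
    "simulate_pair",
    "StudyFixture",
    "make_study_fixture",
]

_OP_CODES = {"simulate_tree": 11, "simulate_character": 12, "simulate_pair": 13}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _OP_CODES[op]]))


def simulate_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0) -> Tree:
    """Yule (pure-birth) tree with ``n_tips`` labelled tips.

    Lineages split at per-lineage rate ``birth_rate``; after the last
    (n-1th) branching event one further exponential waiting time is
    appended so terminal branches have positive length. Tips are
    labelled ``t1..tn`` in birth order. Deterministic per seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(seed, "simulate_tree")

    parent = [-1, 0, 0]
    children = [[1, 2], [], []]
    length = [0.0, 0.0, 0.0]
    active = [1, 2]
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for v in active:
            length[v] += wait
        split = active[rng.integers(len(active))]
        for _ in range(2):
            w = len(parent)
            parent.append(split)
            children[split].append(w)
            children.append([])
            length.append(0.0)
            active.append(w)
        active.remove(split)
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for v in active:
        length[v] += wait

    label: list[str | None] = [None] * len(parent)
    k = 0
    for v in range(len(parent)):
        if not children[v]:
            k += 1
            label[v] = f"t{k}"
    tree = Tree(parent=parent, children=children, length=length, label=label, root=0)
    tree.validate()
    return tree


def simulate_character(
    tree: Tree,
    Q: np.ndarray,
    root,
    seed: int = 0,
    *,
    return_history: bool = False,
):
    """Evolve one discrete character along the tree by Gillespie sampling.

    ``root`` is either a fixed root state (int) or a root-prior vector
    to draw from. Returns a dict tip-label -> state; with
    ``return_history`` also the per-node states and the list of logged
    transitions ``(node, time_along_branch, from_state, to_state)``.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    rng = _rng(seed, "simulate_character")
    if np.ndim(root) == 0:
        root_state = int(root)
    else:
        root_state = int(rng.choice(k, p=np.asarray(root, float)))

    state = np.empty(tree.n_nodes, dtype=int)
    state[tree.root] = root_state
    history: list[tuple[int, float, int, int]] = []
    for v in preorder(tree):
        if v == tree.root:
            continue
        s = state[tree.parent[v]]
        t = 0.0
        remaining = tree.length[v]
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if t + wait > remaining:
                break
            t += wait
            probs = np.clip(Q[s], 0.0, None)
            probs[s] = 0.0
            nxt = int(rng.choice(k, p=probs / probs.sum()))
            history.append((v, t, s, nxt))
            s = nxt
        state[v] = s

    tips = {tree.label[v]: int(state[v]) for v in tree.tips}
    if return_history:
        return tips, state, history
    return tips


def simulate_pair(
    tree: Tree,
    kind: str,
    rates,
    seed: int = 0,
    *,
    root=None,
    return_history: bool = False,
):
    """Simulate a (trait1, trait2) binary pair as one 4-state character.

    ``kind`` is "independent" (4 rates: gain1, loss1, gain2, loss2) or
    "dependent" (8 conditioned rates, order as in the pagel module).
    """
    rates = np.asarray(rates, dtype=float)
    if kind == "independent":
        if rates.shape != (4,):
            raise ValueError("independent model takes 4 rates")
        Q = build_independent_q(*rates)
    elif kind == "dependent":
        if rates.shape != (8,):
            raise ValueError("dependent model takes 8 rates")
        Q = build_dependent_q(rates)
    else:
        raise ValueError(f"unknown model kind: {kind}")
    if root is None:
        root = ctmc.uniform_prior(4)
    res = simulate_character(tree, Q, root, seed=seed, return_history=return_history)
    tips = res[0] if return_history else res
    pair = PairTrait({lab: (s // 2, s % 2) for lab, s in tips.items()})
    if return_history:
        return pair, res[1], res[2]
    return pair


@dataclass
class StudyFixture:
    """The packaged 23-taxon study inputs."""

    tree: Tree
    karyotypes: list[SpeciesKaryotype]
    homology_map: HomologyMap
    matrix: pd.DataFrame  # taxa x 30 segments, states 0/1/2/?
    centromeres: pd.DataFrame  # taxa x 30 segments, 0/1/?
    breakpoints: list[BreakpointRecord]


def _data_path(name: str):
    return resources.files("norevo.data").joinpath(name)


def make_study_fixture() -> StudyFixture:
    """Assemble the packaged study fixture.

    The character matrix is re-encoded at call time from the karyotype
    table and homology map (it is an output of the characters module,
    not a stored artifact).
    """
    tree = parse_newick(_data_path("reference_tree.nwk").read_text())
    karyotypes = load_karyotypes(_data_path("karyotypes.tsv"))
    hmap = load_homology_map(_data_path("homology_map.tsv"))
    matrix = encode_matrix(karyotypes, hmap)
    centromeres = pd.read_csv(
        _data_path("centromeres.tsv"), sep="\t", dtype=str, comment="#"
    ).set_index("taxon")
    breakpoints = load_breakpoints(_data_path("breakpoints.tsv"))

    taxa = set(tree.tip_labels)
    if set(matrix.index) != taxa or set(centromeres.index) != taxa:
        raise ValueError("fixture taxon sets disagree between tree, matrix and annotations")
    return StudyFixture(
        tree=tree,
        karyotypes=karyotypes,
        homology_map=hmap,
        matrix=matrix,
        centromeres=centromeres,
        breakpoints=breakpoints,
    )
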