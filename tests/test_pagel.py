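"""Independent vs dependent pair models and the chi-square LRT."""

import numpy as np
import pytest

from norevo import ctmc
from norevo.pagel import (
    LRT_DF,
    PairTrait,
    build_dependent_q,
    build_independent_q,
    fit_pair_model,
    lrt,
    pair_lrt,
    retained_segments,
    run_all_segments,
)
from norevo.phylo_core import parse_newick
from norevo.synthetic_data import simulate_pair, simulate_tree

from oracle_utils import random_tree_newick


def test_independent_q_unit_rates():
    Q = build_independent_q(1, 1, 1, 1)
    assert np.allclose(np.diag(Q), -2)
    # double flips forbidden: (0,0)<->(1,1) and (0,1)<->(1,0)
    for i, j in [(0, 3), (3, 0), (1, 2), (2, 1)]:
        assert Q[i, j] == 0


def test_independent_q_frozen_second_trait_reduces_to_two_state():
    a1, b1 = 0.7, 0.4
    Q = build_independent_q(a1, b1, 0, 0)
    # restricted to states (0,0) and (1,0): the 2-state chain of trait 1
    sub = Q[np.ix_([0, 2], [0, 2])]
    expected = ctmc.build_q(2, {(0, 1): a1, (1, 0): b1})
    assert np.allclose(sub, expected)


def test_dependent_q_has_8_free_parameters_and_nests_independent(rng):
    rates = rng.uniform(0.1, 2, size=8)
    Q = build_dependent_q(rates)
    off = Q[~np.eye(4, dtype=bool)]
    assert (off > 0).sum() == 8
    # distinct rates are not forced equal
    assert len(np.unique(off[off > 0])) == 8
    a1, b1, a2, b2 = 0.3, 0.9, 1.1, 0.2
    nested = build_dependent_q([a1, a1, b1, b1, a2, a2, b2, b2])
    assert np.allclose(nested, build_independent_q(a1, b1, a2, b2))
    assert LRT_DF == 8 - 4


def test_independent_likelihood_factorizes(rng):
    """4-state independent-pair lnL = sum of the two 2-state trait lnLs."""
    for _ in range(25):
        tree = parse_newick(random_tree_newick(int(rng.integers(4, 10)), rng))
        a1, b1, a2, b2 = rng.uniform(0.05, 2, size=4)
        pair = {
            lab: (int(rng.integers(2)), int(rng.integers(2))) for lab in tree.tip_labels
        }
        Q4 = build_independent_q(a1, b1, a2, b2)
        vecs = PairTrait(pair).observation_vectors()
        ll4 = ctmc.log_likelihood(tree, vecs, Q4, ctmc.uniform_prior(4))
        ll2 = 0.0
        for trait, (a, b) in [(0, (a1, b1)), (1, (a2, b2))]:
            Q2 = ctmc.build_q(2, {(0, 1): a, (1, 0): b})
            tips2 = {lab: ctmc.tip_vector(pair[lab][trait], 2) for lab in pair}
            ll2 += ctmc.log_likelihood(tree, tips2, Q2, ctmc.uniform_prior(2))
        assert ll4 == pytest.approx(ll2, abs=1e-6)


@pytest.mark.parametrize(
    "lnl_ind,lnl_dep,stat",
    [(-21.7, -16.3, 10.8), (-21.3, -17.5, 7.6)],
)
def test_lrt_statistic_arithmetic(lnl_ind, lnl_dep, stat):
    res = lrt(lnl_ind, lnl_dep)
    assert res.statistic == pytest.approx(stat, abs=1e-9)
    assert res.df == 4


def test_lrt_equal_likelihoods():
    res = lrt(-10.0, -10.0)
    assert res.statistic == 0
    assert res.p_value == 1


def test_lrt_flags_nesting_violation():
    with pytest.raises(ValueError, match="nested"):
        lrt(-10.0, -12.0)


def test_chi2_df4_closed_form(rng):
    for x in rng.uniform(0, 20, size=10):
        res = lrt(-50.0, -50.0 + x / 2)
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert res.p_value == pytest.approx(closed, abs=1e-10)


def test_invariant_pair_fits_to_zero_rates_and_zero_statistic():
    tree = simulate_tree(12, seed=4)
    pair = PairTrait({lab: (1, 0) for lab in tree.tip_labels})
    lnl_ind, rates_ind = fit_pair_model(tree, pair, "independent", n_restarts=1, seed=0)
    lnl_dep, _ = fit_pair_model(
        tree, pair, "dependent", n_restarts=1, seed=1, independent_mle=rates_ind
    )
    assert lnl_dep - lnl_ind == pytest.approx(0, abs=1e-4)
    # the only data-relevant rates (loss of trait 1, gain of trait 2) vanish
    assert rates_ind[1] < 1e-4 and rates_ind[2] < 1e-4


def test_nesting_holds_on_simulated_pairs():
    for seed in range(3):
        tree = simulate_tree(25, seed=seed)
        pair = simulate_pair(tree, "independent", [0.6, 0.6, 0.6, 0.6], seed=seed)
        res = pair_lrt(tree, pair, n_restarts=1, seed=seed)
        assert res.lnl_dependent >= res.lnl_independent - 1e-6
        assert res.statistic >= 0


def test_strong_dependence_detected():
    # trait 2 can only be gained while trait 1 is present
    tree = simulate_tree(120, seed=7)
    # rate order: gain1|2=0, gain1|2=1, loss1|2=0, loss1|2=1,
    #             gain2|1=0, gain2|1=1, loss2|1=0, loss2|1=1
    rates = [0.5, 0.5, 0.5, 0.5, 0.0, 2.0, 2.0, 0.1]
    pair = simulate_pair(tree, "dependent", rates, seed=7, root=0)
    res = pair_lrt(tree, pair, n_restarts=1, seed=7)
    assert res.p_value < 0.05


def test_missing_trait_values_allowed():
    tree = simulate_tree(10, seed=2)
    data = {lab: (1, 0) for lab in tree.tip_labels}
    first = tree.tip_labels[0]
    data[first] = ("?", "?")
    vec = PairTrait(data).observation_vectors()[first]
    assert np.array_equal(vec, np.ones(4))
    lnl, _ = fit_pair_model(tree, PairTrait(data), "independent", n_restarts=1, seed=0)
    assert np.isfinite(lnl)


def test_retained_segments_drop_empty_and_telomeric_only(study):
    kept = retained_segments(study.matrix)
    assert len(kept) == 28
    assert "10d" not in kept and "12d" not in kept


def test_run_all_segments_toy_invariant_matrix():
    import pandas as pd

    tree = simulate_tree(8, seed=1)
    taxa = tree.tip_labels
    matrix = pd.DataFrame({"s1": ["1"] * len(taxa), "s2": ["0"] * len(taxa)}, index=taxa)
    cen = pd.DataFrame({"s1": ["1"] * len(taxa), "s2": ["1"] * len(taxa)}, index=taxa)
    out = run_all_segments(tree, matrix, cen, n_restarts=1)
    assert list(out["segment"]) == ["s1"]  # s2 never carries a cluster
    assert out["p_value"].iloc[0] > 0.99
    assert not out["significant"].any()
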