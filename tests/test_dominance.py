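"""Dominance analysis tests against brute-force enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from _util import (
    brute_r2,
    complete_by_enumeration,
    conditional_by_enumeration,
    random_instance,
    shapley_by_permutation,
)
from plandom.dominance import (
    PredictorSet,
    additional_contribution,
    build_lattice,
    complete_dominance,
    conditional_dominance,
    dominance_analysis,
    general_dominance,
    rank_predictors,
)
from plandom import reference


@pytest.fixture(scope="module")
def small_instance():
    return random_instance(seed=100, p=3, n=400)


def test_lattice_has_all_subsets_and_zero_empty_r2(small_instance):
    df, sets = small_instance
    lat = build_lattice(df, "y", sets)
    assert lat.r2.size == 2 ** 3
    assert lat.r2_of([]) == 0.0
    df4, sets4 = random_instance(seed=101, p=4, n=300)
    assert build_lattice(df4, "y", sets4).r2.size == 16


def test_memoized_lattice_matches_fresh_refits(small_instance):
    df, sets = small_instance
    lat = build_lattice(df, "y", sets)
    from itertools import combinations

    names = [s.name for s in sets]
    for k in range(len(names) + 1):
        for S in combinations(names, k):
            assert lat.r2_of(S) == pytest.approx(
                brute_r2(df, "y", sets, S), abs=1e-8)


def test_additional_contribution_definition_and_errors(small_instance):
    df, sets = small_instance
    lat = build_lattice(df, "y", sets)
    a, b, c = [s.name for s in sets]
    # S = empty set gives the direct effect
    assert additional_contribution(lat, [], a) == pytest.approx(lat.r2_of([a]))
    # matches a direct refit difference
    want = brute_r2(df, "y", sets, [a, b]) - brute_r2(df, "y", sets, [b])
    assert additional_contribution(lat, [b], a) == pytest.approx(want, abs=1e-8)
    with pytest.raises(ValueError):
        additional_contribution(lat, [a], a)


def test_zero_variance_predictor_contributes_nothing():
    df, sets = random_instance(seed=102, p=2, n=300)
    df["s1_c0"] = 0.0  # degenerate column in set1
    sets = [sets[0], PredictorSet("set1", ("s1_c0",))]
    lat = build_lattice(df, "y", sets)
    assert additional_contribution(lat, [], "set1") == pytest.approx(0.0, abs=1e-8)


def test_conditional_dominance_boundary_levels_and_enumeration(small_instance):
    df, sets = small_instance
    lat = build_lattice(df, "y", sets)
    C = conditional_dominance(lat)
    names = [s.name for s in sets]
    full = lat.r2_of(names)
    for j in names:
        assert C.loc[j, "level_0"] == pytest.approx(lat.r2_of([j]), abs=1e-12)
        rest = [n for n in names if n != j]
        assert C.loc[j, "level_2"] == pytest.approx(full - lat.r2_of(rest), abs=1e-12)
    want = conditional_by_enumeration(df, "y", sets)
    assert np.allclose(C.to_numpy(), want.to_numpy(), atol=1e-8)


def test_general_dominance_single_predictor_gets_full_r2():
    df, sets = random_instance(seed=103, p=1, n=300)
    res = dominance_analysis(df, "y", sets)
    assert res.general.iloc[0] == pytest.approx(res.r2_full, abs=1e-12)


def test_duplicated_predictor_sets_split_the_r2_equally():
    rng = np.random.default_rng(104)
    x = rng.standard_normal(500)
    y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(float)
    df = pd.DataFrame({"x1": x, "x2": x.copy(), "y": y})
    sets = [PredictorSet("first", ("x1",)), PredictorSet("second", ("x2",))]
    res = dominance_analysis(df, "y", sets)
    assert res.general["first"] == pytest.approx(res.r2_full / 2, abs=1e-6)
    assert res.general["second"] == pytest.approx(res.r2_full / 2, abs=1e-6)


def test_general_matches_permutation_shapley():
    for seed in (105, 106, 107):
        df, sets = random_instance(seed=seed, p=4, n=300)
        res = dominance_analysis(df, "y", sets)
        want = shapley_by_permutation(df, "y", sets)
        assert np.allclose(res.general[want.index].to_numpy(),
                           want.to_numpy(), atol=1e-8)


def test_shapley_weights_sum_to_full_model_r2(small_instance):
    df, sets = small_instance
    res = dominance_analysis(df, "y", sets)
    assert res.general.sum() == pytest.approx(res.r2_full, abs=1e-6)
    assert (res.general >= -1e-9).all()


def test_complete_dominance_signal_beats_noise():
    rng = np.random.default_rng(108)
    strong = rng.standard_normal(800)
    noise = rng.standard_normal(800)
    other = rng.standard_normal(800)
    y = (rng.random(800) < 1 / (1 + np.exp(-1.5 * strong - 0.3 * other))).astype(float)
    df = pd.DataFrame({"strong": strong, "noise": noise, "other": other, "y": y})
    sets = [PredictorSet(n, (n,)) for n in ("strong", "noise", "other")]
    lat = build_lattice(df, "y", sets)
    D = complete_dominance(lat)
    want = complete_by_enumeration(df, "y", sets)
    assert (D.to_numpy() == want.to_numpy()).all()
    assert D.loc["strong", "noise"] == "dominates"
    # antisymmetry and an undetermined diagonal
    for i in D.index:
        assert D.loc[i, i] == "undetermined"
        for j in D.columns:
            if D.loc[i, j] == "dominates":
                assert D.loc[j, i] == "dominated"


class TestRanking:
    @pytest.mark.parametrize("outcome", reference.OUTCOMES)
    def test_published_weight_columns_reproduce_printed_ranks(self, outcome):
        got = rank_predictors(reference.general_dominance_weights(outcome))
        assert got.equals(reference.printed_ranks(outcome)), outcome

    def test_distinct_weights_rank_one_to_p(self):
        g = pd.Series([0.5, 0.3, 0.2, 0.1], index=list("abcd"))
        assert rank_predictors(g).tolist() == [1, 2, 3, 4]

    def test_dense_tie_rule(self):
        g = pd.Series([0.5, 0.5, 0.2])
        assert rank_predictors(g).tolist() == [1, 1, 2]

    def test_only_top_k_distinct_values_ranked(self):
        g = pd.Series(np.linspace(0.9, 0.1, 9))
        r = rank_predictors(g, top_k=6)
        assert r.notna().sum() == 6 and r.max() == 6


def test_order_invariance_of_outputs():
    df, sets = random_instance(seed=109, p=4, n=300)
    res = dominance_analysis(df, "y", sets)
    perm = [sets[2], sets[0], sets[3], sets[1]]
    res_p = dominance_analysis(df, "y", perm)
    names = [s.name for s in sets]
    assert np.allclose(res.general[names], res_p.general[names], atol=1e-12)
    assert np.allclose(res.conditional.loc[names].to_numpy(),
                       res_p.conditional.loc[names].to_numpy(), atol=1e-12)
    assert (res.complete.loc[names, names].to_numpy() ==
            res_p.complete.loc[names, names].to_numpy()).all()


def test_structural_validation():
    df, sets = random_instance(seed=110, p=2, n=200)
    with pytest.raises(ValueError, match="disjoint"):
        build_lattice(df, "y", [sets[0], PredictorSet("dup", sets[0].columns)])
    with pytest.raises(ValueError, match="unique"):
        build_lattice(df, "y", [sets[0], PredictorSet(sets[0].name, sets[1].columns)])
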