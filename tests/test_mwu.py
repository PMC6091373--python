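import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fpathseq.data import GeneSetCollection
from fpathseq.mwu import (
    estimate_q,
    rank_pathways_t,
    select_pathways,
    gene_set_test,
    weighted_mwu,
)
from fpathseq.synthetic import simulate_study

from conftest import make_study


def exact_mean_rank_p(ranks, idx, mid_p=False):
    """Exhaustive two-sided p of the set's mean rank over all subsets."""
    N, m = len(ranks), len(idx)
    mu = (N + 1) / 2
    t_obs = np.mean(ranks[list(idx)])
    devs = [abs(np.mean(ranks[list(c)]) - mu) for c in itertools.combinations(range(N), m)]
    d = abs(t_obs - mu)
    if mid_p:
        greater = np.mean([x > d + 1e-12 for x in devs])
        equal = np.mean([abs(x - d) <= 1e-12 for x in devs])
        return greater + 0.5 * equal
    return np.mean([x >= d - 1e-12 for x in devs])


def test_agrees_with_exact_enumeration_on_six_genes():
    """Equal weights, q=0: normal p tracks the exhaustive rank-sum law.

    At N=6 the exact two-sided p is a coarse step function; the normal
    approximation is compared against the mid-p exact value (documented
    budget 0.05) and the conservative exact value (budget 0.20).
    """
    scores = pd.Series([0.3, 1.2, 2.5, 3.1, 4.8, 7.9], index=list("abcdef"))
    ranks = scores.rank().to_numpy()
    for idx in itertools.combinations(range(6), 3):
        mask = pd.Series(False, index=scores.index)
        mask.iloc[list(idx)] = True
        row = weighted_mwu(scores, 1.0, mask, q_bar=0.0)
        assert abs(row["p_value"] - exact_mean_rank_p(ranks, idx, mid_p=True)) <= 0.05
        assert abs(row["p_value"] - exact_mean_rank_p(ranks, idx)) <= 0.20


def test_equal_weights_reproduce_classical_normal_mwu():
    """z^2 matches the classical normal-approximation U test (no ties)."""
    rng = np.random.default_rng(0)
    scores = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
    mask = pd.Series([True] * 10 + [False] * 20, index=scores.index)
    row = weighted_mwu(scores, 1.0, mask, q_bar=0.0)
    u = stats.mannwhitneyu(scores[mask], scores[~mask], alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    m, n = 10, 20
    z_classic = (u.statistic - m * n / 2) / np.sqrt(m * n * (m + n + 1) / 12)
    assert row["z"] ** 2 == pytest.approx(z_classic**2, rel=1e-9)
    assert row["p_value"] == pytest.approx(u.pvalue, rel=1e-9)


def test_centered_set_gives_zero_z():
    scores = pd.Series(np.arange(1.0, 8.0), index=list("abcdefg"))
    mask = pd.Series([False, False, False, True, False, False, False],
                     index=scores.index)   # rank exactly the middle
    row = weighted_mwu(scores, 1.0, mask, q_bar=0.0)
    assert row["z"] == pytest.approx(0.0)
    assert row["p_value"] == pytest.approx(1.0)


def test_vif_monotonically_deflates_z():
    rng = np.random.default_rng(1)
    scores = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
    mask = pd.Series(scores.to_numpy() > 0.3, index=scores.index)
    zs, ps = [], []
    for q in (0.0, 0.2, 0.5, 0.9):
        row = weighted_mwu(scores, 1.0, mask, q_bar=q)
        zs.append(abs(row["z"]))
        ps.append(row["p_value"])
    assert all(a > b for a, b in zip(zs, zs[1:]))
    assert all(a < b for a, b in zip(ps, ps[1:]))
    assert weighted_mwu(scores, 1.0, mask, q_bar=0.5)["vif"] == pytest.approx(
        1 + (mask.sum() - 1) * 0.5)


def test_weighting_moves_the_statistic():
    scores = pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(10)])
    mask = pd.Series([True, False, False, False, False, False, False, False, False, True],
                     index=scores.index)
    w = pd.Series(0.0, index=scores.index)
    w["g0"], w["g9"] = 1.0, 3.0           # tilt toward the top-ranked member
    row = weighted_mwu(scores, w, mask, q_bar=0.0)
    assert row["statistic"] == pytest.approx((1 * 1 + 3 * 10) / 4)
    eq = weighted_mwu(scores, 1.0, mask, q_bar=0.0)
    assert row["statistic"] > eq["statistic"]


def test_invalid_inputs_rejected():
    scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    mask = pd.Series([True, False, False], index=scores.index)
    with pytest.raises(ValueError, match="zero"):
        weighted_mwu(scores, 0.0, mask)
    with pytest.raises(ValueError, match="nonempty"):
        weighted_mwu(scores, 1.0, pd.Series([True, True, True], index=scores.index))
    with pytest.raises(ValueError, match="nonneg"):
        weighted_mwu(scores, pd.Series([-1.0, 1, 1], index=scores.index), mask)


def test_estimate_q_duplicated_gene_rows_near_one():
    rng = np.random.default_rng(2)
    row = rng.normal(size=12)
    study = make_study(np.vstack([row, row, row]),
                       times=[0, 0, 0, 8, 8, 8, 24, 24, 24, 72, 72, 72])
    q = estimate_q(study, ["g0", "g1", "g2"])
    assert 0.99 < q < 1.0


def test_estimate_q_independent_genes_near_zero():
    rng = np.random.default_rng(3)
    study = make_study(rng.normal(size=(40, 60)))
    assert estimate_q(study, [f"g{i}" for i in range(40)]) < 0.05


@pytest.mark.parametrize("q_true", [0.3])
def test_estimate_q_recovers_planted_correlation(small_config, q_true):
    """Residual-based q estimate matches the generator's target even with
    planted signal present."""
    cfg = dataclasses.replace(small_config, q=q_true, n_patients=20, n_controls=8,
                              overlap_fraction=0.0)
    study, coll, _ = simulate_study(cfg)
    qs = [estimate_q(study, sorted(members)) for members in coll.sets.values()]
    assert np.mean(qs) == pytest.approx(q_true, abs=0.06)


def test_rank_pathways_t_hand_welch():
    scores = pd.Series([5.0, 6.0, 1.0, 2.0], index=list("abcd"))
    coll = GeneSetCollection({"hi": frozenset({"a", "b"}), "lo": frozenset({"c", "d"})})
    ranking = rank_pathways_t(scores, coll)
    # Welch t for {5,6} vs {1,2}: diff 4, se = sqrt(0.5/2+0.5/2) -> t = 4/sqrt(0.5)
    expected = 4.0 / np.sqrt(0.5)
    assert ranking.loc[0, "pathway"] == "hi"
    assert ranking.loc[0, "t_statistic"] == pytest.approx(expected)
    assert ranking.loc[1, "t_statistic"] == pytest.approx(-expected)


def test_shifted_pathway_ranks_first():
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(60)]
    scores = pd.Series(rng.normal(size=60), index=genes)
    scores[genes[:10]] += 50.0
    coll = GeneSetCollection({"shifted": frozenset(genes[:10]),
                              "null": frozenset(genes[30:40])})
    ranking = rank_pathways_t(scores, coll)
    assert ranking.loc[0, "pathway"] == "shifted"


def test_select_pathways_strict_cut():
    table = pd.DataFrame({
        "pathway": ["a", "b", "c"], "m": [10, 10, 10], "statistic": [1, 2, 3],
        "q_bar": [0, 0, 0], "vif": [1, 1, 1], "z": [1, 2, 3],
        "p_value": [0.05, 0.01, 0.2], "skipped": [False, False, False],
        "skip_reason": ["", "", ""],
    })
    from fpathseq.mwu import GeneSetTestResult
    res = GeneSetTestResult(table=table)
    assert select_pathways(res, p_cut=0.05) == ["b"]       # 0.05 excluded
    table2 = table.assign(p_value=[0.5, 0.6, 0.7])
    assert select_pathways(GeneSetTestResult(table=table2)) == []


def test_small_sets_skipped_with_reason(small_simulation):
    study, coll, _ = small_simulation
    genes = [f"x{i}" for i in range(20)]
    scores = pd.Series(np.arange(20.0), index=genes)
    tiny = GeneSetCollection({"tiny": frozenset(genes[:3]),
                              "ok": frozenset(genes[5:15])})
    res = gene_set_test(scores, tiny, min_set_size=6)
    row = res.table.set_index("pathway").loc["tiny"]
    assert row["skipped"] and "size 3" in row["skip_reason"]
    assert not res.table.set_index("pathway").loc["ok", "skipped"]


def test_permuting_gene_labels_leaves_p_unchanged(small_simulation):
    study, coll, _ = small_simulation
    rng = np.random.default_rng(5)
    genes = study.genes
    scores = pd.Series(rng.normal(size=len(genes)) ** 2, index=genes)
    res1 = gene_set_test(scores, coll, study=study)
    perm = list(genes)
    rng.shuffle(perm)
    res2 = gene_set_test(scores.loc[perm], coll, study=study)
    t1 = res1.table.set_index("pathway")["p_value"]
    t2 = res2.table.set_index("pathway")["p_value"]
    pd.testing.assert_series_equal(t1, t2)
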