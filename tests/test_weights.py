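import dataclasses

import numpy as np
import pytest

from fpathseq.data import GeneSetCollection
from fpathseq.fpca import TemporalProfileSet, fit_fpca
from fpathseq.synthetic import SimulationConfig, simulate_study
from fpathseq.weights import (
    build_design,
    compute_weights,
    fit_elastic_net,
    fit_pathway_bases,
    pathway_sum_weights,
    pathway_weights,
)

from test_fpca import profiles_from_means


def proximal_oracle(x, D, lam1, lam2, n_iter=200_000):
    """Independent ISTA solve of ||x-Db||^2 + lam1|b|_1 + lam2|b|_2^2."""
    x = np.asarray(x, float)
    D = np.asarray(D, float)
    L = 2.0 * (np.linalg.norm(D, 2) ** 2 + lam2) + 1e-9
    beta = np.zeros(D.shape[1])
    for _ in range(n_iter):
        grad = -2.0 * D.T @ (x - D @ beta) + 2.0 * lam2 * beta
        z = beta - grad / L
        new = np.sign(z) * np.maximum(np.abs(z) - lam1 / L, 0.0)
        if np.abs(new - beta).max() < 1e-13:
            beta = new
            break
        beta = new
    return beta


@pytest.mark.parametrize("seed,lam1,lam2", [
    (0, 0.1, 0.1), (1, 0.5, 0.0), (2, 0.0, 0.3), (3, 1.0, 0.5), (4, 0.05, 2.0),
])
def test_elastic_net_matches_proximal_oracle(seed, lam1, lam2):
    rng = np.random.default_rng(seed)
    D = rng.normal(size=(6, 4))
    x = rng.normal(size=6)
    beta = fit_elastic_net(x, D, lam1, lam2)
    oracle = proximal_oracle(x, D, lam1, lam2)
    np.testing.assert_allclose(beta, oracle, atol=1e-6)


def test_ols_limit_on_orthonormal_design():
    """With no penalty and orthonormal columns the fit is the projection."""
    rng = np.random.default_rng(5)
    Q, _ = np.linalg.qr(rng.normal(size=(4, 3)))
    x = rng.normal(size=4)
    beta = fit_elastic_net(x, Q, 0.0, 0.0)
    np.testing.assert_allclose(beta, Q.T @ x, atol=1e-10)


def test_large_l1_shrinks_to_exact_zero():
    rng = np.random.default_rng(6)
    D = rng.normal(size=(4, 3))
    x = rng.normal(size=4)
    beta = fit_elastic_net(x, D, lam1=1e4, lam2=0.0)
    assert (beta == 0.0).all()


def test_l1_norm_monotone_in_lam1():
    rng = np.random.default_rng(7)
    D = rng.normal(size=(8, 5))
    x = rng.normal(size=8)
    norms = [np.abs(fit_elastic_net(x, D, lam1, 0.05)).sum()
             for lam1 in (0.0, 0.1, 0.5, 2.0, 10.0)]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


def test_matches_sklearn_parameterization():
    sklearn = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(8)
    D = rng.normal(size=(10, 4))
    x = rng.normal(size=10)
    lam1, lam2 = 0.3, 0.2
    beta = fit_elastic_net(x, D, lam1, lam2)
    # our objective / (2n) maps to sklearn's with
    #   alpha*l1_ratio = lam1/(2n)  and  alpha*(1-l1_ratio)/2 = lam2/(2n)
    n = len(x)
    alpha = (lam1 / 2 + lam2) / n
    l1_ratio = (lam1 / 2) / (lam1 / 2 + lam2)
    model = sklearn.ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False,
                               tol=1e-12, max_iter=100_000)
    model.fit(D, x)
    np.testing.assert_allclose(beta, model.coef_, atol=1e-6)


def test_pathway_weight_energy_split():
    """beta = (sqrt(3), 0, 1, 0) over two pathways -> weights (0.75, 0.25)."""
    beta = np.array([np.sqrt(3), 0.0, 1.0, 0.0])
    w = pathway_weights(beta, ["pa", "pa", "pb", "pb"])
    assert w["pa"] == pytest.approx(0.75)
    assert w["pb"] == pytest.approx(0.25)


def test_all_zero_beta_uniform_fallback():
    w = pathway_weights(np.zeros(4), ["pa", "pa", "pb", "pb"])
    assert w == {"pa": 0.5, "pb": 0.5}


def test_design_column_counts():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(8)]
    M = rng.normal(size=(8, 4))
    profiles = profiles_from_means(M)
    profiles.genes = genes
    coll = GeneSetCollection({"pa": frozenset(genes[:4]), "pb": frozenset(genes[3:])})
    bases = fit_pathway_bases(profiles, coll, ["pa", "pb"], n_components=2)
    D, groups = build_design("g3", ["pa", "pb"], bases)
    assert D.shape == (4, 4)                      # L * |K_i| columns
    assert groups == ["pa", "pa", "pb", "pb"]
    D1, groups1 = build_design("g0", ["pa"], bases)
    assert D1.shape == (4, 2) and set(groups1) == {"pa"}
    with pytest.raises(ValueError, match="no pathway"):
        build_design("g0", ["absent"], bases)


def test_weight_normalization_and_conservation(small_simulation):
    study, coll, _ = small_simulation
    profiles = TemporalProfileSet.from_study(study)
    pw = compute_weights(profiles, coll, coll.names, lam1=0.01, lam2=0.01)
    per_gene = pw.table.groupby("gene")["weight"].sum()
    np.testing.assert_allclose(per_gene.to_numpy(), 1.0, atol=1e-9)
    totals = pathway_sum_weights(pw.table)
    assert totals.sum() == pytest.approx(per_gene.size, abs=1e-9)
    assert (pw.table["weight"] >= 0).all()


def test_disjoint_pathways_totals_equal_member_counts():
    rng = np.random.default_rng(10)
    genes = [f"g{i}" for i in range(10)]
    profiles = profiles_from_means(rng.normal(size=(10, 4)))
    profiles.genes = genes
    coll = GeneSetCollection({"pa": frozenset(genes[:4]), "pb": frozenset(genes[4:])})
    pw = compute_weights(profiles, coll, ["pa", "pb"])
    totals = pw.sum_weights()
    assert totals["pa"] == pytest.approx(4.0)
    assert totals["pb"] == pytest.approx(6.0)


def test_overlap_gene_weighted_toward_its_own_pattern():
    """A gene following pathway A's temporal pattern but also listed in B
    should put most of its weight on A (checked across 10 seeds)."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        # centered patterns are orthogonal so the two bases are distinct
        t_pattern_a = np.array([0.0, 1.0, 2.0, 1.0])
        t_pattern_b = np.array([2.0, 0.0, 2.0, 0.0])
        genes = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)] + ["shared"]
        A = np.outer(rng.normal(1, 0.2, 8), t_pattern_a) + 0.1 * rng.normal(size=(8, 4))
        B = np.outer(rng.normal(1, 0.2, 8), t_pattern_b) + 0.1 * rng.normal(size=(8, 4))
        shared = t_pattern_a + 0.1 * rng.normal(size=4)
        M = np.vstack([A, B, shared])
        profiles = profiles_from_means(M)
        profiles.genes = genes
        coll = GeneSetCollection({"pa": frozenset(genes[:8] + ["shared"]),
                                  "pb": frozenset(genes[8:16] + ["shared"])})
        pw = compute_weights(profiles, coll, ["pa", "pb"], lam1=0.01, lam2=0.01)
        w = pw.gene_weights("shared")
        wins += w["pa"] > w["pb"]
    assert wins >= 9


def test_non_finite_profile_rejected():
    with pytest.raises(ValueError, match="non-finite"):
        fit_elastic_net(np.array([1.0, np.nan]), np.ones((2, 1)), 0.1, 0.1)
    with pytest.raises(ValueError, match="nonneg"):
        fit_elastic_net(np.ones(2), np.ones((2, 1)), -0.1, 0.0)
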