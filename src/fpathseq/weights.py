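"""Elastic-net decomposition of overlapping genes across pathways.

A gene belonging to several pathways would otherwise be counted at full
strength by every set-level test.  To apportion it, each pathway k gets
its own FPCA basis (fitted on that pathway's member genes), and the
gene's centered mean profile x_i(t) is regressed on the stacked
pathway bases with an elastic-net penalty:

    OBJ(beta) = ||x_i - D beta||^2 + lam1 ||beta||_1 + lam2 ||beta||_2^2

The weight of pathway k for gene i is the squared-coefficient energy of
that pathway's block, normalized over the pathways containing i:

    W_{i,k} = sum_l beta_{l,k}^2 / sum_{k' in K_i} sum_l beta_{l,k'}^2

Genes whose fit is entirely shrunk to zero fall back to the uniform
weight 1/|K_i|.  The L2 term is used in its squared form (standard
elastic net), which keeps the coordinate-descent update closed-form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneSetCollection
from .fpca import FpcaResult, TemporalProfileSet, fit_fpca

logger = logging.getLogger(__name__)


@dataclass
class PathwayWeights:
    """Per-(gene, pathway) weights plus fitted coefficients.

    ``table`` has columns gene, pathway, weight; ``betas``/``groups``
    record the raw coefficient vector and the pathway label of each
    design column per gene.
    """

    table: pd.DataFrame
    betas: dict[str, np.ndarray]
    groups: dict[str, list[str]]
    lam1: float
    lam2: float

    def gene_weights(self, gene: str) -> pd.Series:
        rows = self.table[self.table["gene"] == gene]
        return rows.set_index("pathway")["weight"]

    def weights_for_pathway(self, pathway: str) -> pd.Series:
        rows = self.table[self.table["pathway"] == pathway]
        return rows.set_index("gene")["weight"]

    def sum_weights(self) -> pd.Series:
        """Per-pathway totals of member-gene weights (conserves gene count)."""
        return pathway_sum_weights(self.table)


def fit_pathway_bases(profiles: TemporalProfileSet, collection: GeneSetCollection,
                      pathways: list[str], n_components: int | None = None,
                      variance_target: float = 0.9) -> dict[str, FpcaResult]:
    """Fit one FPCA basis per pathway on its member genes' profiles.

    Pathways with no member gene in the profile set are dropped with a
    log line; a single-member pathway still yields its (rank-1) basis.
    """
    gene_set = set(profiles.genes)
    gene_idx = {g: i for i, g in enumerate(profiles.genes)}
    fits: dict[str, FpcaResult] = {}
    for name in pathways:
        members = sorted(collection.sets[name] & gene_set)
        if not members:
            logger.info("fit_pathway_bases: pathway %s has no genes in profile set; dropped", name)
            continue
        rows = [gene_idx[g] for g in members]
        sub = TemporalProfileSet(
            genes=members,
            time_points=profiles.time_points,
            observations=[block[rows] for block in profiles.observations],
        )
        fits[name] = fit_fpca(sub, n_components=n_components, variance_target=variance_target)
    return fits


def build_design(gene: str, membership: list[str],
                 pathway_bases: dict[str, FpcaResult]) -> tuple[np.ndarray, list[str]]:
    """Stack the eigenfunction columns of every pathway containing `gene`.

    Returns (D, groups): D is (T, sum_k L_k) and groups labels each column
    with its pathway.  Pathways whose basis is degenerate (all-constant
    members) are dropped with a log line.
    """
    cols = []
    groups: list[str] = []
    usable = [k for k in membership if k in pathway_bases]
    if not usable:
        raise ValueError(f"gene {gene!r} belongs to no pathway with a fitted basis")
    for k in usable:
        fit = pathway_bases[k]
        if fit.degenerate:
            logger.info("build_design: pathway %s basis degenerate; dropped for gene %s", k, gene)
            continue
        for l in range(fit.n_components):
            cols.append(fit.eigenfunctions[l])
            groups.append(k)
    if not cols:
        raise ValueError(f"gene {gene!r}: every containing pathway has a degenerate basis")
    return np.column_stack(cols), groups


def fit_elastic_net(x: np.ndarray, design: np.ndarray, lam1: float, lam2: float,
                    tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Coordinate-descent minimizer of ||x - D b||^2 + lam1|b|_1 + lam2|b|_2^2.

    Deterministic; cycles coordinates until the largest update falls
    below `tol`.
    """
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be nonnegative")
    x = np.asarray(x, dtype=float)
    D = np.asarray(design, dtype=float)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(D)):
        raise ValueError("non-finite values in profile or design")
    n, p = D.shape
    beta = np.zeros(p)
    col_sq = (D**2).sum(axis=0)
    resid = x.copy()
    thresh = lam1 / 2.0
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if col_sq[j] == 0.0:
                continue
            rho = D[:, j] @ resid + col_sq[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - thresh, 0.0) / (col_sq[j] + lam2)
            delta = new - beta[j]
            if delta != 0.0:
                resid -= delta * D[:, j]
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return beta


def pathway_weights(beta: np.ndarray, groups: list[str]) -> dict[str, float]:
    """Squared-coefficient energy per pathway, normalized over the groups.

    All-zero coefficient vectors fall back to uniform 1/|K_i|.
    """
    names = list(dict.fromkeys(groups))
    energy = {k: 0.0 for k in names}
    for b, k in zip(beta, groups):
        energy[k] += float(b) ** 2
    total = sum(energy.values())
    if total <= 0.0:
        return {k: 1.0 / len(names) for k in names}
    return {k: e / total for k, e in energy.items()}


def compute_weights(profiles: TemporalProfileSet, collection: GeneSetCollection,
                    pathways: list[str], lam1: float = 0.01, lam2: float = 0.01,
                    n_components: int | None = None,
                    variance_target: float = 0.9) -> PathwayWeights:
    """Decompose every profiled gene over the pathways that contain it."""
    bases = fit_pathway_bases(profiles, collection, pathways,
                              n_components=n_components, variance_target=variance_target)
    M = profiles.mean_profiles()
    centered = M - M.mean(axis=1, keepdims=True)
    gene_idx = {g: i for i, g in enumerate(profiles.genes)}

    rows = []
    betas: dict[str, np.ndarray] = {}
    groups_by_gene: dict[str, list[str]] = {}
    for gene in profiles.genes:
        membership = [k for k in pathways if gene in collection.sets.get(k, frozenset())]
        membership = [k for k in membership if k in bases]
        if not membership:
            continue
        if len(membership) == 1:
            # single-pathway gene: the whole energy belongs to that pathway
            rows.append((gene, membership[0], 1.0))
            continue
        D, groups = build_design(gene, membership, bases)
        beta = fit_elastic_net(centered[gene_idx[gene]], D, lam1, lam2)
        w = pathway_weights(beta, groups)
        betas[gene] = beta
        groups_by_gene[gene] = groups
        for k in dict.fromkeys(groups):
            rows.append((gene, k, w[k]))
    table = pd.DataFrame(rows, columns=["gene", "pathway", "weight"])
    return PathwayWeights(table=table, betas=betas, groups=groups_by_gene,
                          lam1=lam1, lam2=lam2)


def pathway_sum_weights(table: pd.DataFrame) -> pd.Series:
    """Total weight per pathway; totals over all pathways sum to #genes."""
    return table.groupby("pathway")["weight"].sum().sort_index()
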