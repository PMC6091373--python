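"""Spearman coexpression networks, hub calling and cross-source overlap.

Edges connect gene pairs whose Spearman correlation magnitude exceeds a
threshold (0.6 by default).  A hub is a node whose degree strictly
exceeds the network's mean degree (isolated nodes count toward the
mean).  Hub sets from several sample sources are intersected into the
Venn regions whose full intersection defines the "common markers".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    """Thresholded Spearman adjacency over a gene panel."""

    graph: nx.Graph
    rho: pd.DataFrame
    tau: float
    signed: bool = False

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), name="degree").reindex(self.nodes)

    @property
    def mean_degree(self) -> float:
        d = self.degrees
        return float(d.mean()) if len(d) else 0.0

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, self.graph.edges[a, b]["rho"]) for a, b in sorted(self.graph.edges)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho"])


def build_network(study: ExpressionStudy, genes: list[str], tau: float = 0.6,
                  signed: bool = False) -> CoexpressionNetwork:
    """Threshold the pairwise Spearman matrix of `genes` into a graph.

    With ``signed=False`` (default) an edge requires |rho| > tau; with
    ``signed=True`` rho > tau.  Constant genes have undefined rho and are
    kept as isolated nodes with a logged warning.
    """
    present = [g for g in genes if g in set(study.genes)]
    if len(present) < 2:
        raise ValueError("need at least 2 genes present in the study")
    if study.n_samples < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    X = study.values.loc[present].to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    if constant.any():
        logger.warning("build_network: %d constant genes kept as isolated nodes",
                       int(constant.sum()))
    # Spearman = Pearson on midranks; constant rows yield undefined rho
    ranks = pd.DataFrame(X).rank(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_mat = np.corrcoef(ranks)
    rho_mat[constant, :] = np.nan
    rho_mat[:, constant] = np.nan
    rho = pd.DataFrame(rho_mat, index=present, columns=present)

    graph = nx.Graph()
    graph.add_nodes_from(present)
    for i, a in enumerate(present):
        for j in range(i + 1, len(present)):
            b = present[j]
            r = rho_mat[i, j]
            if not np.isfinite(r):
                continue
            strength = r if signed else abs(r)
            if strength > tau:
                graph.add_edge(a, b, rho=float(r))
    return CoexpressionNetwork(graph=graph, rho=rho, tau=tau, signed=signed)


def call_hubs(network: CoexpressionNetwork) -> set[str]:
    """Nodes whose degree strictly exceeds the mean degree."""
    d = network.degrees
    if len(d) == 0:
        return set()
    mean = network.mean_degree
    return {str(g) for g in d.index[d > mean]}


def intersect_sources(hub_sets: dict[str, set[str]]) -> dict[str, list[str]]:
    """Exclusive Venn regions of per-source hub sets.

    Keys are '&'-joined source-name combinations; the region of all
    sources is additionally exposed under ``common_markers``.
    """
    names = sorted(hub_sets)
    regions: dict[str, list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(hub_sets[n]) for n in combo))
            outside = set().union(*(set(hub_sets[n]) for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            regions["&".join(combo)] = sorted(inside - outside)
    full = set.intersection(*(set(hub_sets[n]) for n in names)) if names else set()
    regions["common_markers"] = sorted(full)
    return regions


def summarize_expression(study: ExpressionStudy, genes: list[str]) -> pd.DataFrame:
    """Five-number summaries per gene, group and time point.

    Columns: gene, group, time_h, min, q1, median, q3, max — the numbers
    behind a box-whisker plot.
    """
    present = [g for g in genes if g in set(study.genes)]
    rows = []
    meta = study.samples
    for (grp, t), idx in meta.groupby(["group", "time_h"], observed=True).indices.items():
        cols = meta.index[np.asarray(idx)]
        block = study.values.loc[present, cols].to_numpy(dtype=float)
        q = np.percentile(block, [0, 25, 50, 75, 100], axis=1)
        for i, g in enumerate(present):
            rows.append((g, grp, int(t), *q[:, i]))
    out = pd.DataFrame(rows, columns=["gene", "group", "time_h",
                                      "min", "q1", "median", "q3", "max"])
    return out.sort_values(["gene", "group", "time_h"]).reset_index(drop=True)
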