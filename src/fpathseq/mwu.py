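"""Correlation-adjusted, weighted Mann-Whitney U competitive gene-set test.

Member genes' scores (here: FPCA F-values) are compared against the rest
of the scored universe through their midranks.  The statistic is the
weighted mean rank of the set,

    T = sum_{i in set} w_i r_i / sum_{i in set} w_i ,

whose null mean is (N+1)/2.  The null variance under sampling without
replacement from the observed (tie-corrected) ranks is

    Var(T) = sigma_r^2 (N sum a_i^2 - 1) / (N - 1),   a_i = w_i / sum w,

which reduces to the classical mean-rank variance for equal weights.
Because member genes of a pathway are not independent — the model assumes
they share a common pairwise correlation q — the variance is inflated by

    VIF = 1 + (m - 1) * q_bar

(the standard correction for an equicorrelated mean), with q_bar the
estimated mean pairwise correlation of the member genes.  A two-sided
normal p-value is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionStudy, GeneSetCollection

logger = logging.getLogger(__name__)

_Q_MAX = 1.0 - 1e-9


@dataclass
class GeneSetTestResult:
    """Per-pathway weighted-MWU results plus the t-statistic ranking.

    ``table`` columns: pathway, m, statistic, q_bar, vif, z, p_value,
    skipped, skip_reason.  ``ranking`` is the pathway order by descending
    in-set vs out-set t-statistic (reporting only; selection uses p).
    """

    table: pd.DataFrame
    ranking: pd.DataFrame | None = None


def weighted_mwu(scores: pd.Series, weights: pd.Series | float, in_set: pd.Series,
                 q_bar: float = 0.0) -> dict:
    """One pathway's weighted, correlation-adjusted rank test.

    Parameters
    ----------
    scores
        Per-gene scores over the whole tested universe.
    weights
        Per-gene weights for the tested pathway (only in-set entries are
        used); a scalar means equal weights.
    in_set
        Boolean membership mask aligned with `scores`.
    q_bar
        Mean pairwise correlation of the member genes; clipped to [0, 1).
    """
    s = np.asarray(scores, dtype=float)
    mask = np.asarray(in_set, dtype=bool)
    N = len(s)
    m = int(mask.sum())
    if m == 0 or m == N:
        raise ValueError("both the in-set and out-set must be nonempty")
    if np.isscalar(weights):
        w = np.full(N, float(weights))
    else:
        w = np.asarray(weights, dtype=float)
    w_set = w[mask]
    if np.any(w_set < 0):
        raise ValueError("weights must be nonnegative")
    if w_set.sum() <= 0:
        raise ValueError("all in-set weights are zero")

    ranks = stats.rankdata(s)                      # midranks
    a = w_set / w_set.sum()
    statistic = float(a @ ranks[mask])
    mu = (N + 1) / 2.0
    sigma2 = float(np.var(ranks))                  # population variance, tie-corrected
    var = sigma2 * (N * float(a @ a) - 1.0) / (N - 1.0)
    q_bar = float(np.clip(q_bar, 0.0, _Q_MAX))
    vif = max(1.0, 1.0 + (m - 1) * q_bar)
    var_adj = var * vif
    if var_adj <= 0:
        z = 0.0
    else:
        z = (statistic - mu) / np.sqrt(var_adj)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"m": m, "statistic": statistic, "q_bar": q_bar, "vif": vif,
            "z": float(z), "p_value": min(p, 1.0)}


def estimate_q(study: ExpressionStudy, genes: list[str],
               center_by: tuple[str, ...] = ("group", "source", "time_h")) -> float:
    """Mean pairwise Pearson correlation of member genes, clipped to [0, 1).

    Expression rows are first centered within each (group, source, time)
    cell so that planted group/time structure does not masquerade as
    inter-gene correlation; what remains estimates the common noise
    correlation q of the equicorrelated model.
    """
    present = [g for g in genes if g in set(study.genes)]
    if len(present) < 2:
        return 0.0
    X = study.values.loc[present].to_numpy(dtype=float)
    if center_by:
        cells = study.samples.groupby(list(center_by), observed=True).indices
        R = X.copy()
        for idx in cells.values():
            idx = np.asarray(idx)
            R[:, idx] -= R[:, idx].mean(axis=1, keepdims=True)
    else:
        R = X - X.mean(axis=1, keepdims=True)
    sd = R.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return 0.0
    corr = np.corrcoef(R[ok])
    iu = np.triu_indices_from(corr, k=1)
    q_bar = float(np.nanmean(corr[iu]))
    return float(np.clip(q_bar, 0.0, _Q_MAX))


def rank_pathways_t(scores: pd.Series, collection: GeneSetCollection,
                    pathways: list[str] | None = None) -> pd.DataFrame:
    """Rank pathways by the Welch t-statistic of in-set vs out-set scores.

    Descending order; reporting only — selection is based on the MWU p.
    """
    pathways = pathways if pathways is not None else collection.names
    universe = set(scores.index)
    rows = []
    for name in pathways:
        members = collection.sets[name] & universe
        if not members or len(members) == len(universe):
            continue
        mask = scores.index.isin(members)
        t = stats.ttest_ind(scores[mask], scores[~mask], equal_var=False).statistic
        rows.append((name, len(members), float(t)))
    out = pd.DataFrame(rows, columns=["pathway", "m", "t_statistic"])
    return out.sort_values("t_statistic", ascending=False, kind="mergesort").reset_index(drop=True)


def gene_set_test(scores: pd.Series, collection: GeneSetCollection,
                   study: ExpressionStudy | None = None,
                   weights: "pd.DataFrame | None" = None,
                   pathways: list[str] | None = None,
                   min_set_size: int = 6,
                   adjust_correlation: bool = True) -> GeneSetTestResult:
    """Run the weighted MWU test for every pathway over the scored universe.

    `weights` is a (gene, pathway, weight) table as produced by the
    elastic-net decomposition; absent entries default to weight 1.  When
    `study` is given, q_bar is estimated per pathway from member-gene
    expression; otherwise (or with ``adjust_correlation=False``) no
    inflation is applied.
    """
    pathways = pathways if pathways is not None else collection.names
    universe = list(scores.index)
    universe_set = set(universe)
    rows = []
    for name in pathways:
        members = collection.sets[name] & universe_set
        m = len(members)
        if m < min_set_size:
            rows.append({"pathway": name, "m": m, "statistic": np.nan, "q_bar": np.nan,
                         "vif": np.nan, "z": np.nan, "p_value": np.nan, "skipped": True,
                         "skip_reason": f"set size {m} < {min_set_size}"})
            continue
        if m == len(universe):
            rows.append({"pathway": name, "m": m, "statistic": np.nan, "q_bar": np.nan,
                         "vif": np.nan, "z": np.nan, "p_value": np.nan, "skipped": True,
                         "skip_reason": "set covers the whole universe"})
            continue
        in_set = pd.Series(scores.index.isin(members), index=scores.index)
        w = pd.Series(1.0, index=scores.index)
        if weights is not None:
            wk = weights[weights["pathway"] == name].set_index("gene")["weight"]
            w.loc[w.index.intersection(wk.index)] = wk
        q_bar = 0.0
        if adjust_correlation and study is not None:
            q_bar = estimate_q(study, sorted(members))
        row = weighted_mwu(scores, w, in_set, q_bar=q_bar)
        row.update({"pathway": name, "skipped": False, "skip_reason": ""})
        rows.append(row)
    table = pd.DataFrame(rows, columns=["pathway", "m", "statistic", "q_bar", "vif",
                                        "z", "p_value", "skipped", "skip_reason"])
    ranking = rank_pathways_t(scores, collection, pathways)
    return GeneSetTestResult(table=table, ranking=ranking)


def select_pathways(result: GeneSetTestResult, p_cut: float = 0.05) -> list[str]:
    """Pathways with p strictly below `p_cut`, ascending by p; may be empty."""
    t = result.table
    ok = t[(~t["skipped"]) & (t["p_value"] < p_cut)]
    return ok.sort_values(["p_value", "pathway"], kind="mergesort")["pathway"].tolist()
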