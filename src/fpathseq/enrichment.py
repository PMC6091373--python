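"""Fisher's-exact pathway enrichment with BH false-discovery control.

For each pathway the 2x2 table (in-set & in-query, in-set & not-query,
not-set & in-query, not-set & not-query) over the background universe is
tested one-sided for over-representation; the p-value equals the
hypergeometric upper tail P(X >= overlap).  Selection follows the
convention p < 0.05 and overlap count > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-pathway enrichment table, sorted ascending by p-value.

    Columns: pathway, overlap_count, set_size, query_size, universe_size,
    p_value, fdr (Benjamini-Hochberg).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        bad = self.table[(self.table["p_value"] < 0) | (self.table["p_value"] > 1)]
        if len(bad):  # pragma: no cover - defensive
            raise ValueError("p-values outside [0, 1]")


def fisher_enrich(query_genes: Iterable[str], collection: GeneSetCollection,
                  universe: Iterable[str]) -> EnrichmentResult:
    """One-sided (over-representation) Fisher exact test per pathway.

    Every tested set is first intersected with `universe`; the query must
    be a subset of the universe.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty background universe")
    query = frozenset(query_genes)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders[:10]}"
                         + ("..." if len(offenders) > 10 else ""))
    N = len(universe)
    n_query = len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        k = len(in_universe & query)
        # upper-tail hypergeometric: P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n_query)) if K else 1.0
        rows.append((name, k, K, n_query, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["pathway", "overlap_count", "set_size",
                                        "query_size", "universe_size", "p_value"])
    if len(table):
        table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["fdr"] = pd.Series(dtype=float)
    table = table.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(table)


def select_significant(result: EnrichmentResult, p_cut: float = 0.05,
                       min_overlap: int = 2) -> list[str]:
    """Pathways with p strictly below `p_cut` and overlap >= `min_overlap`.

    Returned in ascending p-value order.
    """
    t = result.table
    keep = t[(t["p_value"] < p_cut) & (t["overlap_count"] >= min_overlap)]
    selected = keep.sort_values(["p_value", "pathway"], kind="mergesort")["pathway"].tolist()
    logger.info("select_significant: %d of %d pathways at p<%g, overlap>=%d",
                len(selected), len(t), p_cut, min_overlap)
    return selected
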