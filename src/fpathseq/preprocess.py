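"""Gene filtering and normalization stand-ins.

The working gene universe is defined by a quartile-based variability
filter: the per-gene statistic (IQR across samples by default) is ranked
over genes and everything at or below a chosen empirical quantile is
dropped.  A quantile-normalization op is provided for inputs that are not
already on a common scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ExpressionStudy

logger = logging.getLogger(__name__)

FILTER_STATS = ("iqr", "mean")


def gene_statistics(study: ExpressionStudy, stat: str = "iqr") -> pd.Series:
    """Per-gene filter statistic across all samples (``iqr`` or ``mean``)."""
    if stat == "iqr":
        q75, q25 = np.percentile(study.values.to_numpy(), [75, 25], axis=1)
        vals = q75 - q25
    elif stat == "mean":
        vals = study.values.to_numpy().mean(axis=1)
    else:
        raise ValueError(f"unknown filter statistic {stat!r}; choose from {FILTER_STATS}")
    return pd.Series(vals, index=study.values.index, name=stat)


def quartile_filter(study: ExpressionStudy, stat: str = "iqr",
                    quartile_cut: float = 0.25) -> ExpressionStudy:
    """Drop genes whose filter statistic is at or below the cut quantile.

    The quantile is computed once on the input study's statistics, so the
    operation is deterministic and idempotent only in the sense that
    re-running it re-derives the threshold from the already-filtered
    statistics.  ``quartile_cut = 0`` disables filtering.
    """
    if not 0.0 <= quartile_cut < 1.0:
        raise ValueError("quartile_cut must be in [0, 1)")
    stats = gene_statistics(study, stat)
    if stat == "iqr" and np.allclose(stats.to_numpy(), 0.0):
        raise ValueError("all per-gene IQRs are zero (constant matrix); "
                         "quantile threshold is degenerate")
    if quartile_cut == 0.0:
        logger.info("quartile_filter: cut=0, keeping all %d genes", study.n_genes)
        return study
    threshold = float(np.quantile(stats.to_numpy(), quartile_cut))
    keep = stats > threshold
    if not keep.any():
        raise ValueError(f"quartile_filter would remove every gene (threshold {threshold:.4g})")
    out = study.restrict_genes(stats.index[keep])
    logger.info("quartile_filter(stat=%s, cut=%.3g): %d -> %d genes",
                stat, quartile_cut, study.n_genes, out.n_genes)
    return out


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample column onto the mean sorted reference distribution.

    Each column's values are replaced by the row-wise mean of the sorted
    columns at the same rank; ties receive the average of the reference
    values they span.  Preserves within-column rank order.
    """
    X = study.values.to_numpy(dtype=float)
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    ranks = study.values.rank(axis=0, method="average").to_numpy()
    normalized = np.interp(ranks, np.arange(1, n + 1), reference)
    values = pd.DataFrame(normalized, index=study.values.index, columns=study.values.columns)
    return ExpressionStudy(values, study.samples.copy())


def subset_by_source(study: ExpressionStudy, source: str) -> ExpressionStudy:
    """Restrict samples to one tissue source; gene list unchanged."""
    available = set(study.samples["source"])
    if source not in available:
        raise ValueError(f"source {source!r} not present; available: {sorted(available)}")
    ids = study.samples.index[study.samples["source"] == source]
    return study.restrict_samples(ids)
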