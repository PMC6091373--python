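"""Functional PCA of temporal expression profiles and the F-statistic.

Each gene's replicate observations at the shared time grid are averaged
into a mean profile; the profiles are centered by their time-average and
the eigenfunctions of the gene-wise covariance across time points are
extracted.  With a four-point grid this is exactly PCA of the
4-dimensional mean-profile vectors — no basis smoothing is attempted,
since a spline basis would be unidentifiable at so few points.

The per-gene F-statistic

    F_i = (RSS_i^0 - RSS_i^1) / RSS_i^1

compares the constant-profile null fit (RSS^0, deviations of every
replicate observation from the gene's grand mean) against the truncated
FPCA reconstruction (RSS^1), so it acts as a signal-to-noise ratio for a
nonconstant temporal trend.  Both residual sums are taken over
replicate-level observations, which puts replicate noise in numerator and
denominator alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionStudy

logger = logging.getLogger(__name__)

F_CAP = 1e9
_EPS = 1e-12


@dataclass
class TemporalProfileSet:
    """Replicate-level temporal observations on a common time grid.

    ``observations[j]`` holds a (n_genes, n_replicates_j) array of values
    at time ``time_points[j]``; ``genes`` orders the rows.
    """

    genes: list[str]
    time_points: np.ndarray
    observations: list[np.ndarray]

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        if len(np.unique(self.time_points)) < 2:
            raise ValueError("need at least 2 distinct time points")
        if len(self.observations) != len(self.time_points):
            raise ValueError("one observation block per time point required")
        for j, block in enumerate(self.observations):
            if block.ndim != 2 or block.shape[0] != len(self.genes):
                raise ValueError(f"observation block {j} has shape {block.shape}; "
                                 f"expected ({len(self.genes)}, n_reps)")
            if block.shape[1] < 1:
                raise ValueError(f"time point {self.time_points[j]} has no observations")

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def mean_profiles(self) -> np.ndarray:
        """(n_genes, n_times) matrix of per-time replicate means."""
        return np.column_stack([block.mean(axis=1) for block in self.observations])

    @classmethod
    def from_study(cls, study: ExpressionStudy, genes: list[str] | None = None,
                   group: str | None = "patient") -> "TemporalProfileSet":
        """Build profiles from a study, default restricted to patient samples."""
        sub = study if genes is None else study.restrict_genes(genes)
        meta = sub.samples
        mask = np.ones(len(meta), dtype=bool)
        if group is not None:
            mask = (meta["group"] == group).to_numpy()
        times = sorted(meta.loc[mask, "time_h"].unique())
        blocks = []
        for t in times:
            cols = meta.index[mask & (meta["time_h"] == t).to_numpy()]
            blocks.append(sub.values[cols].to_numpy(dtype=float))
        return cls(list(sub.values.index), np.asarray(times, dtype=float), blocks)


@dataclass
class FpcaResult:
    """Eigenfunctions, scores and residual sums of a fitted FPCA model."""

    genes: list[str]
    time_points: np.ndarray
    eigenfunctions: np.ndarray      # (L, T), orthonormal rows
    eigenvalues: np.ndarray         # all T eigenvalues, descending
    scores: np.ndarray              # (n_genes, L)
    mean_levels: np.ndarray         # per-gene time-average of the mean profile
    rss0: np.ndarray
    rss1: np.ndarray
    degenerate: bool = False
    f_values: pd.Series | None = None

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]

    def fitted_profiles(self) -> np.ndarray:
        """(n_genes, T) reconstruction: mean level + truncated expansion."""
        recon = self.scores @ self.eigenfunctions
        return self.mean_levels[:, None] + recon


def fit_fpca(profiles: TemporalProfileSet, n_components: int | None = None,
             variance_target: float = 0.9) -> FpcaResult:
    """Fit discrete FPCA to a profile set.

    The number of components is either given explicitly or chosen as the
    smallest L whose eigenvalues capture `variance_target` of the total
    centered variance, capped at (#time points - 1).
    """
    T = profiles.n_times
    if n_components is not None:
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if n_components >= 2 and T < 3:
            raise ValueError("need at least 3 time points for n_components >= 2")
        if n_components > T - 1:
            raise ValueError(f"n_components must be <= {T - 1} for {T} time points")

    M = profiles.mean_profiles()                      # (G, T)
    mean_levels = M.mean(axis=1)
    C = M - mean_levels[:, None]                      # centered profiles
    n_genes = M.shape[0]

    cov = (C.T @ C) / n_genes                         # (T, T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    total_var = float(eigvals.sum())
    degenerate = total_var < 1e-10
    if degenerate:
        logger.warning("fit_fpca: near-zero total centered variance (%.3g); "
                       "all profiles effectively constant", total_var)

    if n_components is None:
        cap = T - 1
        if degenerate:
            L = 1
        else:
            frac = np.cumsum(eigvals) / total_var
            L = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
            L = max(1, min(L, cap))
    else:
        L = n_components

    phi = eigvecs[:, :L].T                            # (L, T)
    # deterministic sign: first component of largest magnitude positive
    for l in range(L):
        j = int(np.argmax(np.abs(phi[l])))
        if phi[l, j] < 0:
            phi[l] *= -1.0
    scores = C @ phi.T                                # (G, L)

    fitted = mean_levels[:, None] + scores @ phi
    rss0 = np.zeros(n_genes)
    rss1 = np.zeros(n_genes)
    n_obs = sum(block.shape[1] for block in profiles.observations)
    grand = sum(block.sum(axis=1) for block in profiles.observations) / n_obs
    for j, block in enumerate(profiles.observations):
        rss0 += ((block - grand[:, None]) ** 2).sum(axis=1)
        rss1 += ((block - fitted[:, j][:, None]) ** 2).sum(axis=1)

    result = FpcaResult(
        genes=list(profiles.genes),
        time_points=profiles.time_points.copy(),
        eigenfunctions=phi,
        eigenvalues=eigvals,
        scores=scores,
        mean_levels=mean_levels,
        rss0=rss0,
        rss1=rss1,
        degenerate=degenerate,
    )
    f_statistic(result)
    return result


def f_statistic(result: FpcaResult) -> pd.Series:
    """Per-gene signal-to-noise ratio F_i = (RSS0 - RSS1)/(RSS1 + eps).

    Values are floored at 0 and capped at 1e9 (exact fits).  The series is
    cached on the result.
    """
    num = result.rss0 - result.rss1
    f = num / (result.rss1 + _EPS)
    f = np.clip(f, 0.0, F_CAP)
    result.f_values = pd.Series(f, index=pd.Index(result.genes, name="gene"), name="F")
    return result.f_values


def select_top(result: FpcaResult, n: int = 1000) -> list[str]:
    """The `n` genes with largest F; ties broken by symbol order."""
    if result.f_values is None:
        f_statistic(result)
    f = result.f_values
    order = sorted(f.index, key=lambda g: (-f[g], g))
    return order[: min(n, len(order))]
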