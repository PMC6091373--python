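"""Synthetic expression studies with planted temporal pathway signal.

The generator emulates a small longitudinal sepsis-style microarray design:
a handful of control and patient subjects per tissue source, each sampled
at four time points, log2 RMA-scale baselines, and a set of "active"
pathways whose member genes follow a nonconstant temporal trend in
patients only.  Noise within a pathway is exchangeable with pairwise
correlation ``q``, constructed from a shared per-pathway latent factor:

    eps = noise_sd * (sqrt(q) * z_pathway + sqrt(1 - q) * z_gene)

so that any two member genes share correlation exactly q in expectation.
Genes belonging to several pathways receive the factor of their
first-assigned pathway, which keeps the joint covariance positive
semi-definite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    ExpressionStudy,
    GeneSetCollection,
    read_gmt,
    read_study,
    read_truth,
    write_gmt,
    write_study,
    write_truth,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_study",
    "trend_shape_values",
    "write_study",
    "read_study",
    "write_gmt",
    "read_gmt",
    "write_truth",
    "read_truth",
]

logger = logging.getLogger(__name__)

TREND_SHAPES = ("linear", "peak", "decay")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted-signal expression study.

    Defaults mirror a small four-time-point neonatal sepsis design:
    three tissue sources, 3 control and 8 patient subjects per source,
    samples at 0/8/24/72 h, a moderate planted amplitude of 2 log2 units
    against 0.5 log2 units of Gaussian noise.
    """

    n_genes: int = 1200
    n_pathways: int = 12
    pathway_size_range: tuple[int, int] = (15, 40)
    overlap_fraction: float = 0.10
    n_controls: int = 3
    n_patients: int = 8
    sources: tuple[str, ...] = ("blood", "lymphocyte", "monocyte")
    time_points: tuple[int, ...] = (0, 8, 24, 72)
    n_active_pathways: int = 2
    effect_size: float = 2.0
    trend_shape: str = "peak"
    q: float = 0.10
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_pathways < 1:
            raise ValueError("n_genes and n_pathways must be positive")
        lo, hi = self.pathway_size_range
        if lo < 2 or hi < lo:
            raise ValueError("pathway_size_range must satisfy 2 <= min <= max")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0.0 <= self.q < 1.0:
            raise ValueError("q must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ValueError("time_points must be strictly increasing")
        if len(self.time_points) < 2:
            raise ValueError("need at least two time points")
        if self.n_active_pathways > self.n_pathways:
            raise ValueError("n_active_pathways cannot exceed n_pathways")
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("need at least one control and one patient subject per source")
        if self.trend_shape not in TREND_SHAPES:
            raise ValueError(f"trend_shape must be one of {TREND_SHAPES}")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated study, for recovery benchmarks."""

    active_pathways: frozenset[str]
    active_genes: frozenset[str]
    amplitude: dict[str, float]


def trend_shape_values(shape: str, time_points: Sequence[float]) -> np.ndarray:
    """Temporal trend evaluated at `time_points`, normalized to max |shape| = 1.

    ``linear`` rises proportionally to time, ``peak`` is a Gaussian bump
    centered mid-course, ``decay`` is an exponential fall-off from t = 0.
    """
    t = np.asarray(time_points, dtype=float)
    t_max = t.max()
    if t_max <= 0:
        raise ValueError("time points must span a positive range")
    if shape == "linear":
        vals = t / t_max
    elif shape == "peak":
        mid = t_max / 2.0
        width = t_max / 4.0
        vals = np.exp(-((t - mid) ** 2) / (2.0 * width**2))
    elif shape == "decay":
        vals = np.exp(-3.0 * t / t_max)
    else:
        raise ValueError(f"unknown trend shape {shape!r}")
    return vals / np.max(np.abs(vals))


def _assign_pathways(cfg: SimulationConfig, rng: np.random.Generator,
                     gene_names: list[str]):
    """Draw pathway sizes and assign member genes with controlled overlap.

    Returns (sets, first_pathway_index) where first_pathway_index maps a
    gene to the index of its first-assigned pathway (the latent factor it
    shares).
    """
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    slots = int(sizes.sum())
    # overlap genes occupy 2 slots each:  distinct = slots - n_overlap and
    # n_overlap = overlap_fraction * distinct  =>  distinct = slots / (1 + f)
    n_distinct = int(round(slots / (1.0 + cfg.overlap_fraction)))
    n_overlap = slots - n_distinct
    if n_distinct > cfg.n_genes:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small for pathway demand of {n_distinct} distinct genes")
    member_genes = list(rng.choice(gene_names, size=n_distinct, replace=False))
    overlap_genes = member_genes[:n_overlap]
    single_genes = member_genes[n_overlap:]

    capacity = sizes.astype(int).copy()
    membership: dict[int, list[str]] = {k: [] for k in range(cfg.n_pathways)}
    first_pathway: dict[str, int] = {}

    for g in overlap_genes:
        open_k = np.flatnonzero(capacity > 0)
        if len(open_k) < 2:
            raise ValueError(
                "overlap_fraction too high: cannot place an overlap gene in two pathways")
        probs = capacity[open_k] / capacity[open_k].sum()
        chosen = rng.choice(open_k, size=2, replace=False, p=probs)
        chosen = sorted(int(k) for k in chosen)
        for k in chosen:
            membership[k].append(g)
            capacity[k] -= 1
        first_pathway[g] = chosen[0]

    remaining = [k for k in range(cfg.n_pathways) for _ in range(int(capacity[k]))]
    if len(remaining) != len(single_genes):  # pragma: no cover - arithmetic guard
        raise RuntimeError("slot bookkeeping error in pathway assignment")
    for g, k in zip(single_genes, remaining):
        membership[k].append(g)
        first_pathway[g] = k

    names = [f"PW{k:03d}" for k in range(cfg.n_pathways)]
    sets = {names[k]: frozenset(membership[k]) for k in range(cfg.n_pathways)}
    return sets, first_pathway


def simulate_study(config: SimulationConfig):
    """Generate a study, its gene-set collection and the planted truth.

    Expression of gene i in sample (subject s, time t) is

        baseline_i + 1{s patient, i active} * effect_size * shape(t) + eps

    with equicorrelated within-pathway noise as described in the module
    docstring.  Controls and inactive genes have constant expectation over
    time.  Deterministic for a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    sets, first_pathway = _assign_pathways(config, rng, genes)
    collection = GeneSetCollection(dict(sets))

    names = list(sets)
    active_idx = rng.choice(len(names), size=config.n_active_pathways, replace=False)
    active_pathways = frozenset(names[int(i)] for i in sorted(active_idx))
    active_genes = frozenset().union(*(sets[p] for p in active_pathways)) if active_pathways else frozenset()

    # sample grid: per source, subjects x time points
    records = []
    for source in config.sources:
        for grp, n_subj in (("control", config.n_controls), ("patient", config.n_patients)):
            for j in range(n_subj):
                for t in config.time_points:
                    sid = f"{source}_{grp}{j + 1}_t{t}"
                    records.append((sid, grp, source, int(t)))
    samples = pd.DataFrame(records, columns=["sample_id", "group", "source", "time_h"])
    samples = samples.set_index("sample_id")
    n_samples = len(samples)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    shape_by_time = dict(zip(config.time_points,
                             trend_shape_values(config.trend_shape, config.time_points)))

    z_pathway = rng.standard_normal((config.n_pathways, n_samples))
    z_gene = rng.standard_normal((config.n_genes, n_samples))
    sq, sq1 = np.sqrt(config.q), np.sqrt(1.0 - config.q)
    noise = np.empty_like(z_gene)
    factor_idx = np.full(config.n_genes, -1, dtype=int)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, k in first_pathway.items():
        factor_idx[gene_pos[g]] = k
    in_pathway = factor_idx >= 0
    noise[in_pathway] = sq * z_pathway[factor_idx[in_pathway]] + sq1 * z_gene[in_pathway]
    noise[~in_pathway] = z_gene[~in_pathway]
    noise *= config.noise_sd

    signal = np.zeros((config.n_genes, n_samples))
    patient = (samples["group"] == "patient").to_numpy()
    shape_per_sample = samples["time_h"].map(shape_by_time).to_numpy(dtype=float)
    active_rows = np.fromiter((g in active_genes for g in genes), dtype=bool, count=config.n_genes)
    signal[np.ix_(active_rows, patient)] = config.effect_size * shape_per_sample[patient]

    values = baseline[:, None] + signal + noise
    study = ExpressionStudy(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples.index),
        samples,
    )
    truth = SimulationTruth(
        active_pathways=active_pathways,
        active_genes=active_genes,
        amplitude={g: (config.effect_size if g in active_genes else 0.0) for g in genes
                   if factor_idx[gene_pos[g]] >= 0},
    )
    logger.info("simulated study: %d genes, %d samples, %d pathways (%d active)",
                config.n_genes, n_samples, config.n_pathways, config.n_active_pathways)
    return study, collection, truth
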