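"""Core data containers: expression studies and gene-set collections.

An :class:`ExpressionStudy` couples a log2-scale gene × sample expression
matrix with per-sample metadata (group, tissue source, sampling time in
hours).  A :class:`GeneSetCollection` maps pathway names to gene-symbol
sets (GMT-backed) and provides the inverse gene → pathways lookup used by
the overlap-decomposition stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = ("group", "source", "time_h")
VALID_GROUPS = ("control", "patient")

MATRIX_FILENAME = "expression.tsv"
METADATA_FILENAME = "samples.tsv"
GENESETS_FILENAME = "pathways.gmt"
TRUTH_FILENAME = "truth.json"


@dataclass
class ExpressionStudy:
    """Gene × sample expression matrix plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, one column per sample id,
        log2-scale normalized intensities.
    samples
        DataFrame indexed by sample id with columns ``group``
        (control/patient), ``source`` (tissue of origin) and ``time_h``
        (sampling time in hours).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols in expression matrix: {dups[:5]}")
        missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample metadata missing required columns: {missing_cols}")
        matrix_samples = list(self.values.columns)
        meta_samples = set(self.samples.index)
        absent = [s for s in matrix_samples if s not in meta_samples]
        if absent:
            raise ValueError(f"samples present in matrix but missing from metadata: {absent}")
        extra = [s for s in self.samples.index if s not in set(matrix_samples)]
        if extra:
            raise ValueError(f"samples present in metadata but missing from matrix: {extra}")
        # align metadata row order with matrix column order
        self.samples = self.samples.loc[matrix_samples]
        bad_groups = set(self.samples["group"]) - set(VALID_GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels {sorted(bad_groups)}; expected {VALID_GROUPS}")
        if self.samples["time_h"].isna().any():
            na = self.samples.index[self.samples["time_h"].isna()].tolist()
            raise ValueError(f"samples with missing time_h: {na[:5]}")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sources(self) -> list[str]:
        return sorted(self.samples["source"].unique())

    @property
    def time_points(self) -> list[int]:
        return sorted(self.samples["time_h"].unique())

    def sample_mask(self, group: str | None = None, source: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if group is not None:
            mask &= (self.samples["group"] == group).to_numpy()
        if source is not None:
            mask &= (self.samples["source"] == source).to_numpy()
        return mask

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionStudy":
        """Return a study restricted to `genes`, preserving matrix order."""
        keep = set(genes)
        idx = [g for g in self.genes if g in keep]
        return ExpressionStudy(self.values.loc[idx], self.samples.copy())

    def restrict_samples(self, sample_ids: Iterable[str]) -> "ExpressionStudy":
        ids = [s for s in self.sample_ids if s in set(sample_ids)]
        return ExpressionStudy(self.values[ids], self.samples.loc[ids])


@dataclass
class GeneSetCollection:
    """Named pathways mapped to gene-symbol sets.

    Gene symbols are matched case-sensitively.  ``universe`` optionally
    records an explicit background symbol set; when absent the union of
    all member genes serves as the implicit universe.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty[:5]}")
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def pathways_containing(self, gene: str) -> list[str]:
        """The pathways K_i containing `gene`, in collection order."""
        return [name for name, genes in self.sets.items() if gene in genes]

    def restrict_to(self, genes: Iterable[str], min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with `genes`, dropping sets below `min_size`."""
        keep = set(genes)
        sets = {}
        dropped = 0
        for name, members in self.sets.items():
            inter = members & keep
            if len(inter) >= min_size:
                sets[name] = frozenset(inter)
            else:
                dropped += 1
        if dropped:
            logger.info("restrict_to: dropped %d sets below size %d", dropped, min_size)
        return GeneSetCollection(sets, universe=frozenset(keep))


# -- file formats --------------------------------------------------------------


def write_gmt(collection: GeneSetCollection, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in collection.sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated symbols).

    Duplicate symbols within a set are collapsed (set semantics).
    """
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description and >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets)


def write_study(study: ExpressionStudy, dir_path: str | Path) -> None:
    """Write the matrix and metadata TSVs of `study` under `dir_path`."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    study.values.to_csv(dir_path / MATRIX_FILENAME, sep="\t", index_label="gene")
    meta = study.samples.copy()
    meta.to_csv(dir_path / METADATA_FILENAME, sep="\t", index_label="sample_id")


def read_study(dir_path: str | Path) -> ExpressionStudy:
    """Read a study written by :func:`write_study`; validates consistency."""
    dir_path = Path(dir_path)
    matrix_path = dir_path / MATRIX_FILENAME
    meta_path = dir_path / METADATA_FILENAME
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.name != "gene":
        raise ValueError(f"{matrix_path}: first column must be named 'gene', got "
                         f"{values.index.name!r}")
    samples = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return ExpressionStudy(values, samples)


def write_truth(truth: "object", path: str | Path) -> None:
    # local import avoids a module cycle with synthetic
    payload = {
        "active_pathways": sorted(truth.active_pathways),
        "active_genes": sorted(truth.active_genes),
        "amplitude": {g: float(a) for g, a in sorted(truth.amplitude.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path):
    from .synthetic import SimulationTruth

    payload = json.loads(Path(path).read_text())
    return SimulationTruth(
        active_pathways=frozenset(payload["active_pathways"]),
        active_genes=frozenset(payload["active_genes"]),
        amplitude=dict(payload["amplitude"]),
    )
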