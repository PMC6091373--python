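"""End-to-end orchestration of the seven analysis stages.

Per sample-source grouping (plus an "all" grouping over every sample):
quartile filter -> Fisher enrichment -> differential-pathway selection ->
FPCA on their genes -> top-N F-ranked genes -> elastic-net pathway
weights -> correlation-adjusted weighted MWU -> significant pathways ->
Spearman network and hubs; finally the hub sets of all analyzed
groupings are intersected.  Every stage writes its table under the
output directory and a manifest records parameters and row counts.

Statistically empty outcomes (no enriched pathway, no significant MWU
pathway) are valid results: downstream stages for that grouping are
skipped with a log line rather than aborting the run.  Structurally
empty inputs (no samples, no genes, no gene-set coverage) raise a
stage-named error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data import ExpressionStudy, GeneSetCollection, read_gmt, read_study
from .enrichment import fisher_enrich, select_significant
from .fpca import TemporalProfileSet, fit_fpca, select_top
from .mwu import select_pathways, gene_set_test
from .network import build_network, call_hubs, intersect_sources
from .preprocess import quartile_filter, subset_by_source
from .weights import compute_weights

logger = logging.getLogger(__name__)

ALL_SOURCES = "all"


@dataclass
class RunConfig:
    """Paths and per-stage parameters of a pipeline run."""

    matrix: Path | str | None = None
    metadata: Path | str | None = None
    gene_sets: Path | str | None = None
    out_dir: Path | str = "fpathseq_out"
    sources: list[str] | None = None          # None: every source + "all"
    filter_stat: str = "iqr"
    quartile_cut: float = 0.25
    enrich_p_cut: float = 0.05
    min_overlap: int = 2
    top_n: int = 1000
    n_components: int | None = None
    variance_target: float = 0.9
    lam1: float = 0.01
    lam2: float = 0.01
    alpha: float = 0.05
    min_set_size: int = 6
    tau: float = 0.6
    include_controls_in_profiles: bool = False
    seed: int = 0


@dataclass
class SourceResult:
    """Intermediate and final tables of one source grouping."""

    source: str
    n_samples: int
    n_genes_input: int
    n_genes_filtered: int
    enrichment: pd.DataFrame
    differential_pathways: list[str]
    f_values: pd.Series | None = None
    top_genes: list[str] = field(default_factory=list)
    weight_table: pd.DataFrame | None = None
    sum_weights: pd.Series | None = None
    mwu_table: pd.DataFrame | None = None
    t_ranking: pd.DataFrame | None = None
    significant_pathways: list[str] = field(default_factory=list)
    edge_table: pd.DataFrame | None = None
    hubs: set[str] = field(default_factory=set)
    network_built: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    results: dict[str, SourceResult]
    venn: dict[str, list[str]]
    common_markers: list[str]
    manifest: dict


def validate_inputs(study: ExpressionStudy, collection: GeneSetCollection) -> list[str]:
    """Consistency checks; returns a list of issues (empty on a happy path)."""
    issues: list[str] = []
    covered = collection.all_genes() & set(study.genes)
    if not covered:
        raise ValueError("validate_inputs: no gene-set symbol matches the expression matrix")
    frac = len(covered) / study.n_genes
    if frac < 0.10:
        issues.append(f"gene-set coverage of the matrix is low ({frac:.1%})")
    for source in study.sources:
        meta = study.samples[study.samples["source"] == source]
        for grp in ("control", "patient"):
            times = set(meta.loc[meta["group"] == grp, "time_h"])
            missing = set(study.time_points) - times
            if missing:
                issues.append(f"{source}/{grp}: no samples at time(s) {sorted(missing)}")
    return issues


def analyze_source(study: ExpressionStudy, collection: GeneSetCollection,
                   config: RunConfig, source: str) -> SourceResult:
    """Run all stages for one source grouping (``"all"`` = every sample)."""
    sub = study if source == ALL_SOURCES else subset_by_source(study, source)
    if sub.n_samples == 0:
        raise ValueError(f"[{source}] subset: no samples")

    filtered = quartile_filter(sub, stat=config.filter_stat, quartile_cut=config.quartile_cut)

    # background = measured genes appearing in >=1 pathway; query = the
    # filtered (variable) genes within that background
    universe = set(sub.genes) & collection.all_genes()
    if not universe:
        raise ValueError(f"[{source}] enrichment: no pathway gene measured in the study")
    query = set(filtered.genes) & universe
    enr = fisher_enrich(query, collection, universe)
    diff_pathways = select_significant(enr, p_cut=config.enrich_p_cut,
                                       min_overlap=config.min_overlap)

    res = SourceResult(source=source, n_samples=sub.n_samples,
                       n_genes_input=sub.n_genes, n_genes_filtered=filtered.n_genes,
                       enrichment=enr.table, differential_pathways=diff_pathways)
    if not diff_pathways:
        res.notes.append("no differential pathways at the enrichment stage; "
                         "downstream stages skipped")
        logger.info("[%s] %s", source, res.notes[-1])
        return res

    # FPCA scores every filtered pathway gene; the competitive MWU then
    # compares each differential pathway's members against that full
    # scored universe, while the top-N "dysregulated" genes (ranked within
    # the differential pathways) feed the weight and network stages.
    scored_genes = sorted(query)
    diff_genes = sorted(set().union(*(collection.sets[p] for p in diff_pathways))
                        & set(filtered.genes))
    if not diff_genes:
        raise ValueError(f"[{source}] fpca: differential pathways cover no filtered gene")
    group = None if config.include_controls_in_profiles else "patient"
    profiles = TemporalProfileSet.from_study(filtered, genes=scored_genes, group=group)
    fit = fit_fpca(profiles, n_components=config.n_components,
                   variance_target=config.variance_target)
    res.f_values = fit.f_values
    f_diff = res.f_values.loc[diff_genes]
    order = sorted(f_diff.index, key=lambda g: (-f_diff[g], g))
    res.top_genes = order[: min(config.top_n, len(order))]
    logger.info("[%s] %d differential pathways covering %d genes; top %d carried forward",
                source, len(diff_pathways), len(diff_genes), len(res.top_genes))

    gene_row = {g: i for i, g in enumerate(profiles.genes)}
    top_rows = [gene_row[g] for g in res.top_genes]
    top_profiles = TemporalProfileSet(
        genes=res.top_genes, time_points=profiles.time_points,
        observations=[block[top_rows] for block in profiles.observations])
    pw = compute_weights(top_profiles, collection, diff_pathways,
                         lam1=config.lam1, lam2=config.lam2,
                         n_components=config.n_components,
                         variance_target=config.variance_target)
    res.weight_table = pw.table
    res.sum_weights = pw.sum_weights()

    scores = res.f_values
    test_collection = GeneSetCollection(
        {p: collection.sets[p] for p in diff_pathways})
    mwu_res = gene_set_test(scores, test_collection, study=sub, weights=pw.table,
                             min_set_size=config.min_set_size)
    res.mwu_table = mwu_res.table
    res.t_ranking = mwu_res.ranking
    res.significant_pathways = select_pathways(mwu_res, p_cut=config.alpha)

    if not res.significant_pathways:
        res.notes.append("no pathway met the MWU significance threshold; network skipped")
        logger.info("[%s] %s", source, res.notes[-1])
        return res

    net_genes = sorted(set().union(*(collection.sets[p] for p in res.significant_pathways))
                       & set(res.top_genes))
    patients = sub.restrict_samples(sub.samples.index[sub.samples["group"] == "patient"])
    if len(net_genes) < 2:
        res.notes.append("fewer than 2 genes available for the coexpression network; skipped")
        logger.info("[%s] %s", source, res.notes[-1])
        return res
    network = build_network(patients, net_genes, tau=config.tau)
    res.edge_table = network.edge_table()
    res.hubs = call_hubs(network)
    res.network_built = True
    logger.info("[%s] %d significant pathways; network on %d genes, %d hubs",
                source, len(res.significant_pathways), len(net_genes), len(res.hubs))
    return res


def run_study(study: ExpressionStudy, collection: GeneSetCollection,
              config: RunConfig) -> RunReport:
    """In-memory pipeline over every configured source grouping."""
    issues = validate_inputs(study, collection)
    for msg in issues:
        logger.warning("validate_inputs: %s", msg)
    groupings = [ALL_SOURCES] + (config.sources if config.sources is not None
                                 else study.sources)
    results = {src: analyze_source(study, collection, config, src) for src in groupings}

    hub_sets = {src: r.hubs for src, r in results.items() if r.network_built}
    venn = intersect_sources(hub_sets) if hub_sets else {"common_markers": []}
    common = venn.get("common_markers", [])

    manifest = {
        "package_version": __version__,
        "parameters": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in dataclasses.asdict(config).items()},
        "validation_issues": issues,
        "stages": {src: {
            "n_samples": r.n_samples,
            "n_genes_input": r.n_genes_input,
            "n_genes_filtered": r.n_genes_filtered,
            "n_differential_pathways": len(r.differential_pathways),
            "n_top_genes": len(r.top_genes),
            "n_significant_pathways": len(r.significant_pathways),
            "n_hubs": len(r.hubs),
            "notes": r.notes,
        } for src, r in results.items()},
    }
    return RunReport(results=results, venn=venn, common_markers=common, manifest=manifest)


def write_report(report: RunReport, out_dir: Path | str) -> None:
    out_dir = Path(out_dir)
    for src, r in report.results.items():
        d = out_dir / src
        d.mkdir(parents=True, exist_ok=True)
        r.enrichment.to_csv(d / "enrichment.tsv", sep="\t", index=False)
        pd.Series(r.differential_pathways, name="pathway").to_csv(
            d / "differential_pathways.tsv", sep="\t", index=False)
        if r.f_values is not None:
            fv = r.f_values.sort_values(ascending=False).rename("F").to_frame()
            fv["selected"] = fv.index.isin(r.top_genes)
            fv.to_csv(d / "fpca_f_values.tsv", sep="\t", index_label="gene")
        if r.weight_table is not None:
            r.weight_table.to_csv(d / "pathway_weights.tsv", sep="\t", index=False)
            r.sum_weights.rename("sum_weight").to_csv(
                d / "pathway_sum_weights.tsv", sep="\t", index_label="pathway")
        if r.mwu_table is not None:
            r.mwu_table.to_csv(d / "mwu_results.tsv", sep="\t", index=False)
            r.t_ranking.to_csv(d / "pathway_t_ranking.tsv", sep="\t", index=False)
        if r.edge_table is not None:
            r.edge_table.to_csv(d / "network_edges.tsv", sep="\t", index=False)
            pd.Series(sorted(r.hubs), name="gene").to_csv(
                d / "hub_genes.tsv", sep="\t", index=False)
    (out_dir / "venn_regions.json").write_text(
        json.dumps(report.venn, indent=1, sort_keys=True))
    (out_dir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=1, sort_keys=True))


def run_all(config: RunConfig) -> RunReport:
    """Load inputs from `config` paths, run every grouping, write outputs."""
    for name in ("matrix", "metadata", "gene_sets"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"run_all: {name} path missing or not found: {p}")
    values = pd.read_csv(config.matrix, sep="\t", index_col=0)
    samples = pd.read_csv(config.metadata, sep="\t", index_col="sample_id")
    study = ExpressionStudy(values, samples)
    collection = read_gmt(config.gene_sets)
    report = run_study(study, collection, config)
    write_report(report, config.out_dir)
    return report
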