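"""End-to-end orchestration of the analysis stages.

``run_pipeline`` takes the four study inputs (counts, metadata, weather,
annotation) and carries them through normalization, variance-partition gene
selection, SOM clustering with rootstock tests, the environmental and
expression PCAs with G x E interaction screening, and functional enrichment
of the implicated gene sets. ``run_synthetic_pipeline`` first generates a
synthetic study so the whole analysis runs with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import enrich as enrich_mod
from . import env as env_mod
from . import normalize as norm_mod
from . import som as som_mod
from . import varpart as vp_mod
from .io import AnnotationMap, CountMatrix, HourlyWeather, SampleTable
from .simulate import SimulationConfig, simulate_study

__all__ = ["AnalysisParams", "PipelineResult", "run_pipeline", "run_synthetic_pipeline"]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable analysis settings with the study's published defaults."""

    min_count: float = 4
    min_samples: int = 4
    select_term: str = "rootstock"
    select_quantile: float = 0.75

    som_rows: int = 9
    som_cols: int = 9
    som_epochs: int = 500
    som_alpha: tuple = (0.05, 0.01)
    retain_quantile: float = 0.5
    cluster_alpha: float = 0.05
    cluster_min_size: int = 16

    window_hours: int = 24
    epc_cum_var: float = 0.80
    gpc_cum_var: float = 0.80
    effect_threshold: float = 0.05
    posthoc_alpha: float = 0.05
    loader_z: float = 1.96

    max_evalue: float = 1e-10
    enrich_alpha: float = 1e-5
    enrich_scheme: str = "gene-bonferroni"

    seed: int = 0

    def with_(self, **kwargs) -> "AnalysisParams":
        return replace(self, **kwargs)


@dataclass
class PipelineResult:
    """Everything the pipeline computes, stage by stage."""

    size_factors: norm_mod.SizeFactors
    trend: norm_mod.DispersionTrend
    filtered: CountMatrix
    expression: norm_mod.ExpressionMatrix
    scaled: norm_mod.ExpressionMatrix
    partition: vp_mod.VariancePartition
    selected_genes: list
    selection_threshold: float
    codebook: som_mod.Codebook
    clusters: som_mod.ClusterTable
    cluster_summary: pd.DataFrame
    env_table: env_mod.CompositeEnvTable
    epca: env_mod.PCAResult
    epc_components: list
    sample_epcs: pd.DataFrame
    gpca: env_mod.PCAResult
    gpc_components: list
    gxe_results: list
    flagged: list
    posthoc: dict
    loader_sets: dict
    enrichment: dict
    truth: object = None


def run_pipeline(
    counts: CountMatrix,
    meta: SampleTable,
    weather: HourlyWeather,
    annotation: AnnotationMap,
    params: AnalysisParams = AnalysisParams(),
) -> PipelineResult:
    # --- normalize ---------------------------------------------------------
    try:
        sf = norm_mod.size_factors(counts)
    except ValueError:
        sf = norm_mod.size_factors(counts, pseudo_reference=True)
    filtered = norm_mod.filter_genes(
        counts, params.min_count, params.min_samples, sf=sf
    )
    trend = norm_mod.fit_dispersion_trend(filtered, sf)
    expr = norm_mod.vst(filtered, sf, trend)
    scaled = norm_mod.scale_genes(expr)
    if scaled.constant_genes:
        keep = [g for g in scaled.genes if g not in set(scaled.constant_genes)]
        scaled = scaled.subset_genes(keep)
        expr = expr.subset_genes(keep)

    # --- variance partition & selection ------------------------------------
    design = vp_mod.build_design(meta)
    partition = vp_mod.variance_explained(scaled, design)
    selected, threshold = vp_mod.select_top_percentile(
        partition, params.select_term, params.select_quantile
    )

    # --- SOM ---------------------------------------------------------------
    grid = som_mod.HexGrid(params.som_rows, params.som_cols)
    som_input = scaled.subset_genes(selected)
    schedule = som_mod.TrainingSchedule(
        epochs=params.som_epochs,
        alpha_start=params.som_alpha[0],
        alpha_end=params.som_alpha[1],
        seed=params.seed,
    )
    cb0 = som_mod.init_codebook(som_input.values, grid, seed=params.seed)
    cb = som_mod.train_som(som_input.values, cb0, schedule)
    table = som_mod.assign_bmu(som_input.values, cb, gene_ids=som_input.genes)
    table = som_mod.retain_core_genes(table, params.retain_quantile)
    table = som_mod.cluster_rootstock_test(
        som_input, table, meta, params.cluster_alpha, params.cluster_min_size
    )
    summary = som_mod.cluster_summary(som_input, table, meta)

    # --- environment & G x E -----------------------------------------------
    env_table = env_mod.build_env_table(
        weather, all_days=True, window_h=params.window_hours
    )
    epca = env_mod.pca(env_table, standardize=True)
    epcs = env_mod.select_components(epca, params.epc_cum_var)
    sample_epcs = env_mod.attach_env(meta, env_table, epca, components=epcs)

    gpca = env_mod.pca(
        pd.DataFrame(expr.values.T, index=expr.samples, columns=expr.genes),
        standardize=False,
    )
    gpcs = env_mod.select_components(gpca, params.gpc_cum_var)

    results = []
    for gi in gpcs:
        g_scores = gpca.scores[:, gi]
        for ei in epcs:
            e_scores = sample_epcs[f"ePC{ei + 1}"].to_numpy()
            results.append(
                env_mod.fit_gpc_model(g_scores, e_scores, meta, gpc=gi, epc=ei)
            )
    flagged = env_mod.screen_effects(results, params.effect_threshold)

    posthoc = {}
    focal = {"env:rootstock", "env:tissue:rootstock"}
    by_key = {(r.gpc, r.epc): r for r in results}
    for gpc, epc, term in flagged:
        if term in focal and (gpc, epc) not in posthoc:
            posthoc[(gpc, epc)] = env_mod.posthoc_slopes(
                by_key[(gpc, epc)], params.posthoc_alpha
            )

    loader_sets = {}
    for gpc in sorted({g for g, _, t in flagged if t in focal}):
        loader_sets[gpc] = env_mod.heavy_loaders(gpca, gpc, params.loader_z)

    # --- enrichment --------------------------------------------------------
    ann = enrich_mod.filter_annotation(annotation, params.max_evalue)
    annotated = set(ann.data["gene"])
    universe = [g for g in expr.genes if g in annotated]
    enrichment = {}
    if universe:
        uset = set(universe)
        queries = {}
        for gpc, ls in loader_sets.items():
            if ls.positive:
                queries[f"gPC{gpc + 1}_pos"] = [g for g in ls.positive if g in uset]
            if ls.negative:
                queries[f"gPC{gpc + 1}_neg"] = [g for g in ls.negative if g in uset]
        sig_nodes = (
            table.nodes[table.nodes["significant"]]["node"].tolist()
            if len(table.nodes)
            else []
        )
        assigned = table.assignments
        for node in sig_nodes:
            genes = assigned[(assigned["node"] == node) & assigned["retained"]]["gene"]
            queries[f"cluster{node}"] = [g for g in genes if g in uset]
        for name, q in queries.items():
            if not q:
                continue
            res = enrich_mod.hypergeom_enrich(q, ann, universe)
            enrichment[name] = enrich_mod.correct_and_flag(
                res, params.enrich_alpha, params.enrich_scheme
            )

    return PipelineResult(
        size_factors=sf,
        trend=trend,
        filtered=filtered,
        expression=expr,
        scaled=scaled,
        partition=partition,
        selected_genes=selected,
        selection_threshold=threshold,
        codebook=cb,
        clusters=table,
        cluster_summary=summary,
        env_table=env_table,
        epca=epca,
        epc_components=epcs,
        sample_epcs=sample_epcs,
        gpca=gpca,
        gpc_components=gpcs,
        gxe_results=results,
        flagged=flagged,
        posthoc=posthoc,
        loader_sets=loader_sets,
        enrichment=enrichment,
    )


def run_synthetic_pipeline(
    config: SimulationConfig = SimulationConfig(),
    params: AnalysisParams = AnalysisParams(),
) -> PipelineResult:
    """Generate a synthetic study and analyze it end to end."""
    study = simulate_study(config)
    result = run_pipeline(
        study["counts"], study["design"], study["weather"], study["annotation"], params
    )
    result.truth = study["truth"]
    return result
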