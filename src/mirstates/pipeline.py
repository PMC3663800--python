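"""End-to-end wiring: expression matrices -> regulated interaction states ->
differential selection -> partition-Jaccard ranking (-> correlation filter).

Each stage is importable on its own; this module only chains them in the
canonical order so that batch runs, the bootstrap evaluation and the CLI all
execute exactly the same flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import classify, correlation, interactions, ranking
from .io_tables import AnalysisConfig, ExpressionMatrix, GroupAssignment, apply_present_call_filter


@dataclass
class PipelineResult:
    mirna_states: pd.DataFrame  # surviving miRNA rows, {L,M,H}
    gene_states: pd.DataFrame  # surviving gene rows, {L,M,H}
    mirna_info: pd.DataFrame
    mrna_info: pd.DataFrame
    table: pd.DataFrame  # regulated interaction states, 9-state alphabet
    differential: list[interactions.DifferentialInteraction] = field(default_factory=list)
    ranked: list[ranking.RankedInteraction] = field(default_factory=list)


def derive_interaction_states(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    probe_gene_map: pd.Series,
    catalog: Sequence[tuple[str, str]],
    config: AnalysisConfig,
    mirna_calls: pd.DataFrame | None = None,
    mrna_calls: pd.DataFrame | None = None,
    apply_present_calls: bool = False,
) -> PipelineResult:
    """Compute the regulated interaction-state table without group knowledge.

    Stages: optional present-call filter; per-probe discretization; probe
    score filter; aggregation of mRNA probes to genes; medium-ratio filter on
    both miRNA and gene rows; interaction-state construction; undefined-
    frequency filter.
    """
    if list(mirna.sample_ids) != list(mrna.sample_ids):
        raise ValueError("miRNA and mRNA matrices must share the same samples in order")
    if apply_present_calls:
        mirna = apply_present_call_filter(mirna, mirna_calls, config.present_call_min_fraction)
        mrna = apply_present_call_filter(mrna, mrna_calls, config.present_call_min_fraction)

    mirna_states, mirna_info = classify.classify_matrix(mirna, config)
    mrna_states, mrna_info = classify.classify_matrix(mrna, config)
    mirna_states, mirna_info = classify.filter_probes_by_score(
        mirna_states, mirna_info, config.probe_score_factor
    )
    mrna_states, mrna_info = classify.filter_probes_by_score(
        mrna_states, mrna_info, config.probe_score_factor
    )

    gene_states = interactions.aggregate_gene_states(
        mrna_states, probe_gene_map
    ) if len(mrna_states) else mrna_states

    mirna_states = interactions.filter_by_medium_ratio(mirna_states, config.medium_ratio_max)
    gene_states = interactions.filter_by_medium_ratio(gene_states, config.medium_ratio_max)

    table = interactions.build_interaction_states(mirna_states, gene_states, list(catalog))
    table = interactions.filter_by_undefined_frequency(table, config.undefined_freq_max)
    return PipelineResult(
        mirna_states=mirna_states,
        gene_states=gene_states,
        mirna_info=mirna_info,
        mrna_info=mrna_info,
        table=table,
    )


def rank_differential(result: PipelineResult, groups: GroupAssignment) -> PipelineResult:
    """Select differential interactions for two groups and rank them by JI."""
    result.differential = interactions.select_differential(result.table, groups)
    result.ranked = ranking.rank_interactions(result.differential, result.table, groups)
    return result


def run_pipeline(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    probe_gene_map: pd.Series,
    catalog: Sequence[tuple[str, str]],
    groups: GroupAssignment,
    config: AnalysisConfig,
    correlation_groups: GroupAssignment | None = None,
    apply_correlation_filter: bool = False,
    **kwargs,
) -> PipelineResult:
    """Full flow; optionally annotate per-group rho and filter by it.

    ``correlation_groups`` may carry a finer grouping (e.g. three clinical
    groups) than the two-group contrast used for differential selection.
    """
    result = derive_interaction_states(mirna, mrna, probe_gene_map, catalog, config, **kwargs)
    result = rank_differential(result, groups)
    if apply_correlation_filter and result.ranked:
        gene_expr = correlation.gene_level_expression(mrna, probe_gene_map)
        corr_groups = correlation_groups if correlation_groups is not None else groups
        correlation.annotate_spearman(result.ranked, mirna, gene_expr, corr_groups)
        result.ranked = correlation.filter_negative_correlation(
            result.ranked, config.correlation_cutoff
        )
    return result
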