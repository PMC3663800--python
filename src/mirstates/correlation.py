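"""Per-group Spearman correlation between miRNA and target expression.

A genuine repressive interaction should leave a trace of negative rank
correlation between the miRNA and its target mRNA within at least one
experimental group. Correlations are computed per group (not pooled) because
de-regulation patterns may differ between, say, healthy and tumor samples.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ExpressionMatrix, GroupAssignment
from .ranking import RankedInteraction


def spearman_by_group(
    mirna_values: np.ndarray,
    gene_values: np.ndarray,
    groups: GroupAssignment,
    sample_ids: Sequence[str],
) -> dict[str, float]:
    """Spearman rho of one miRNA/gene value pair within each group.

    Uses the midrank convention for ties (the standard definition). A group
    with a constant vector has no defined rank correlation; NaN is recorded.
    """
    mirna_values = np.asarray(mirna_values, dtype=float)
    gene_values = np.asarray(gene_values, dtype=float)
    out: dict[str, float] = {}
    for g in groups.groups:
        idx = [i for i, s in enumerate(sample_ids) if groups.labels[s] == g]
        if len(idx) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples; rho undefined")
        x, y = mirna_values[idx], gene_values[idx]
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[g] = math.nan
            continue
        rho = stats.spearmanr(x, y).statistic
        out[g] = float(rho)
    return out


def annotate_spearman(
    ranked: Sequence[RankedInteraction],
    mirna: ExpressionMatrix,
    mrna_gene_level: pd.DataFrame,
    groups: GroupAssignment,
) -> list[RankedInteraction]:
    """Fill per-group rho for each ranked interaction, in place.

    ``mrna_gene_level`` holds one expression row per gene id (e.g. the
    median over that gene's probes), aligned to the miRNA matrix samples.
    """
    samples = mirna.sample_ids
    if list(mrna_gene_level.columns) != samples:
        raise ValueError("gene-level expression must share the miRNA matrix samples")
    for r in ranked:
        r.spearman_by_group = spearman_by_group(
            mirna.data.loc[r.mirna_id].to_numpy(),
            mrna_gene_level.loc[r.gene_id].to_numpy(),
            groups,
            samples,
        )
    return list(ranked)


def gene_level_expression(mrna: ExpressionMatrix, probe_gene_map: pd.Series) -> pd.DataFrame:
    """Median log expression per gene over its probes (for correlations)."""
    genes = probe_gene_map.reindex(mrna.probe_ids)
    if genes.isna().any():
        missing = list(genes.index[genes.isna()][:5])
        raise ValueError(f"probes without gene mapping: {missing}")
    return mrna.data.groupby(genes.to_numpy(), sort=False).median()


def filter_negative_correlation(
    ranked: Sequence[RankedInteraction], cutoff: float = -0.4
) -> list[RankedInteraction]:
    """Keep interactions with rho <= cutoff in at least one group.

    The cutoff is inclusive; a missing (NaN) rho never satisfies it.
    """
    kept = []
    for r in ranked:
        rhos = list(r.spearman_by_group.values())
        if not rhos:
            raise ValueError(
                f"interaction {r.interaction} has no correlations; run annotate_spearman first"
            )
        if any((not math.isnan(rho)) and rho <= cutoff for rho in rhos):
            kept.append(r)
    return kept
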