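"""Partition-agreement ranking of differential interactions.

For a single interaction, the per-sample interaction states induce an
*expected* partition of the samples into three blocks — repression active
(G_HL), repression released (G_LH) and undefined (G_undef). How well this
expected partition agrees with the predefined experimental two-group
partition is measured with the pair-counting Jaccard index from the
cluster-validity literature:

    J = N11 / (N11 + N10 + N01)

over all unordered sample pairs, where N11 counts pairs co-clustered in both
partitions, N10 pairs co-clustered only in the first and N01 only in the
second. J lies in [0, 1]; J = 1 means the interaction alone reproduces the
experimental grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import DifferentialInteraction, S_COMP_HL, S_COMP_LH
from .io_tables import GroupAssignment


def expected_partition(states: Sequence[str]) -> dict[str, list[int]]:
    """Group sample positions into G_HL / G_LH / G_undef by interaction state."""
    blocks: dict[str, list[int]] = {"G_HL": [], "G_LH": [], "G_undef": []}
    for i, s in enumerate(states):
        if s in S_COMP_HL:
            blocks["G_HL"].append(i)
        elif s in S_COMP_LH:
            blocks["G_LH"].append(i)
        else:
            blocks["G_undef"].append(i)
    return blocks


def _labels_from_partition(partition: Sequence[Sequence[int]], n: int) -> np.ndarray:
    labels = np.full(n, -1, dtype=int)
    for k, block in enumerate(partition):
        for i in block:
            if labels[i] != -1:
                raise ValueError(f"sample {i} appears in two blocks")
            labels[i] = k
    if (labels == -1).any():
        raise ValueError("partition does not cover all samples")
    return labels


def jaccard_partition_similarity(
    partition_p: Sequence[Sequence[int]], partition_q: Sequence[Sequence[int]]
) -> float:
    """Pair-counting Jaccard agreement between two partitions of one sample set.

    Computed from the contingency table: with n_ij the block-overlap counts,
    N11 = sum C(n_ij, 2), and the co-clustered pair totals of each partition
    give N10 and N01. Defined as 0 when no pair is co-clustered anywhere.
    """
    n = sum(len(b) for b in partition_p)
    if n < 2:
        raise ValueError("jaccard_partition_similarity needs at least 2 samples")
    if n != sum(len(b) for b in partition_q):
        raise ValueError("partitions cover different sample sets")
    lp = _labels_from_partition(partition_p, n)
    lq = _labels_from_partition(partition_q, n)

    def pairs(x: np.ndarray) -> int:
        _, c = np.unique(x, return_counts=True)
        return int((c * (c - 1) // 2).sum())

    joint = lp.astype(np.int64) * (lq.max() + 1) + lq
    n11 = pairs(joint)
    pairs_p = pairs(lp)
    pairs_q = pairs(lq)
    denom = pairs_p + pairs_q - n11  # = N11 + N10 + N01
    if denom == 0:
        return 0.0
    return n11 / denom


@dataclass
class RankedInteraction:
    """A differential interaction with its partition-agreement score."""

    mirna_id: str
    gene_id: str
    jaccard_index: float
    direction: str
    modal_states: dict[str, str]
    spearman_by_group: dict[str, float] = field(default_factory=dict)

    @property
    def interaction(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


def rank_interactions(
    differential: Sequence[DifferentialInteraction],
    table: pd.DataFrame,
    groups: GroupAssignment,
) -> list[RankedInteraction]:
    """Score each differential interaction by the agreement between its
    expected partition and the experimental two-group partition; sort by
    descending Jaccard index, ties by (mirna_id, gene_id)."""
    labels = groups.groups
    if len(labels) != 2:
        raise ValueError("ranking needs exactly two experimental groups")
    samples = list(table.columns)
    experimental = [
        [i for i, s in enumerate(samples) if groups.labels[s] == g] for g in labels
    ]
    ranked = []
    for di in differential:
        states = table.loc[(di.mirna_id, di.gene_id)]
        blocks = expected_partition(list(states))
        ji = jaccard_partition_similarity(list(blocks.values()), experimental)
        ranked.append(
            RankedInteraction(
                mirna_id=di.mirna_id,
                gene_id=di.gene_id,
                jaccard_index=ji,
                direction=di.direction,
                modal_states=dict(di.modal_states),
            )
        )
    ranked.sort(key=lambda r: (-r.jaccard_index, r.mirna_id, r.gene_id))
    return ranked


def frame_to_ranked(df: pd.DataFrame) -> list[RankedInteraction]:
    """Inverse of :func:`ranked_to_frame` (modal_/rho_ columns by group)."""
    modal_cols = [c for c in df.columns if c.startswith("modal_")]
    rho_cols = [c for c in df.columns if c.startswith("rho_")]
    out = []
    for _, row in df.iterrows():
        out.append(
            RankedInteraction(
                mirna_id=str(row["mirna_id"]),
                gene_id=str(row["gene_id"]),
                jaccard_index=float(row["jaccard_index"]),
                direction=str(row["direction"]),
                modal_states={c[len("modal_"):]: str(row[c]) for c in modal_cols},
                spearman_by_group={c[len("rho_"):]: float(row[c]) for c in rho_cols},
            )
        )
    return out


def ranked_to_frame(ranked: Sequence[RankedInteraction]) -> pd.DataFrame:
    """Flatten a ranked list to a DataFrame for TSV export."""
    rows = []
    for r in ranked:
        row: dict[str, object] = {
            "mirna_id": r.mirna_id,
            "gene_id": r.gene_id,
            "jaccard_index": r.jaccard_index,
            "direction": r.direction,
        }
        for g, s in r.modal_states.items():
            row[f"modal_{g}"] = s
        for g, rho in r.spearman_by_group.items():
            row[f"rho_{g}"] = rho
        rows.append(row)
    return pd.DataFrame(rows)
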