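"""From probe states to per-sample interaction states and differential calls.

An interaction state is the two-letter concatenation of the miRNA state and
the gene state of one sample, giving the nine-state alphabet S. The states
split by biological meaning: S_compHL (miRNA up, target down — active
repression), S_compLH (miRNA down, target up — released repression) and
S_undef (combinations without a repression reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine-state interaction alphabet S.
INTERACTION_STATES = frozenset(
    m + g for m in "LMH" for g in "LMH"
)

S_COMP_HL = frozenset({"HL", "ML", "HM"})  # miRNA up / mRNA down
S_COMP_LH = frozenset({"LH", "MH", "LM"})  # miRNA down / mRNA up
S_UNDEF = frozenset({"HH", "LL", "MM"})

#: Tie preference when aggregating probe states to a gene state.
_STATE_PREFERENCE = ("L", "H", "M")


def aggregate_gene_states(probe_states: pd.DataFrame, probe_gene_map: pd.Series) -> pd.DataFrame:
    """Collapse mRNA probe states to gene states by the modal state per sample.

    Ties are broken by the fixed preference order low, high, then medium.
    Every probe must be mapped; genes are emitted in first-probe order.
    """
    unmapped = [p for p in probe_states.index if p not in probe_gene_map.index]
    if unmapped:
        raise ValueError(f"probes without gene mapping: {unmapped[:5]}")
    genes = probe_gene_map.loc[probe_states.index]
    order: dict[str, None] = {}
    for g in genes:
        order.setdefault(g, None)
    rows = []
    for gene in order:
        block = probe_states.loc[genes[genes == gene].index].to_numpy()
        row = [_modal_probe_state(block[:, c]) for c in range(block.shape[1])]
        rows.append(row)
    return pd.DataFrame(rows, index=list(order), columns=probe_states.columns)


def _modal_probe_state(states: np.ndarray) -> str:
    counts = {s: 0 for s in _STATE_PREFERENCE}
    for s in states:
        counts[s] += 1
    best = max(counts.values())
    for s in _STATE_PREFERENCE:
        if counts[s] == best:
            return s
    raise AssertionError("unreachable")


def filter_by_medium_ratio(state_matrix: pd.DataFrame, medium_ratio_max: float) -> pd.DataFrame:
    """Drop rows whose fraction of M states strictly exceeds the threshold."""
    frac_m = (state_matrix.to_numpy() == "M").mean(axis=1)
    keep = frac_m <= medium_ratio_max
    return state_matrix.loc[keep]


def build_interaction_states(
    mirna_states: pd.DataFrame,
    gene_states: pd.DataFrame,
    catalog: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Combine miRNA and gene states into per-sample interaction states.

    The cell for (miRNA, gene) in a sample is the concatenation of the two
    states in that order. Catalog pairs whose miRNA or gene did not survive
    the upstream filters are dropped (counted in the log, not fatal). The
    result is indexed by a (mirna_id, gene_id) MultiIndex.
    """
    if list(mirna_states.columns) != list(gene_states.columns):
        raise ValueError("miRNA and gene state matrices must share the same samples")
    mir_ok = set(mirna_states.index)
    gene_ok = set(gene_states.index)
    kept = [(m, g) for m, g in catalog if m in mir_ok and g in gene_ok]
    dropped = len(catalog) - len(kept)
    if dropped:
        logger.info("dropped %d/%d catalog pairs without surviving probes", dropped, len(catalog))
    if not kept:
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["mirna_id", "gene_id"]),
            columns=mirna_states.columns,
        )
    mir_block = mirna_states.loc[[m for m, _ in kept]].to_numpy()
    gene_block = gene_states.loc[[g for _, g in kept]].to_numpy()
    cells = np.char.add(mir_block.astype("<U1"), gene_block.astype("<U1"))
    index = pd.MultiIndex.from_tuples(kept, names=["mirna_id", "gene_id"])
    return pd.DataFrame(cells, index=index, columns=mirna_states.columns)


def filter_by_undefined_frequency(table: pd.DataFrame, undefined_freq_max: float) -> pd.DataFrame:
    """Drop interactions whose fraction of undefined states strictly exceeds u.

    Survivors form the set of regulated interactions.
    """
    undef = np.isin(table.to_numpy(), sorted(S_UNDEF))
    keep = undef.mean(axis=1) <= undefined_freq_max
    return table.loc[keep]


@dataclass
class DifferentialInteraction:
    """An interaction whose modal states sit in opposite comp sets."""

    mirna_id: str
    gene_id: str
    modal_states: dict[str, str]  # group label -> modal interaction state
    direction: str  # 'down_in_A': mRNA down (miRNA up) in the first group

    @property
    def interaction(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


def modal_state(states: Sequence[str]) -> str | None:
    """The most frequent state, or None if tied states straddle comp sets.

    A tie is harmless when every top state lies in the same comp set (any of
    them yields the same comp-set assignment); the first in a fixed order is
    returned then. Otherwise the modal state is ambiguous.
    """
    counts: dict[str, int] = {}
    for s in states:
        counts[s] = counts.get(s, 0) + 1
    best = max(counts.values())
    top = sorted(s for s, c in counts.items() if c == best)
    side = {_comp_side(s) for s in top}
    if len(side) != 1:
        return None
    return top[0]


def _comp_side(state: str) -> str:
    if state in S_COMP_HL:
        return "HL"
    if state in S_COMP_LH:
        return "LH"
    return "undef"


def select_differential(
    table: pd.DataFrame, groups: "GroupAssignment"
) -> list[DifferentialInteraction]:
    """Interactions differentially regulated between the two given groups.

    Selected iff the modal state of group A lies in S_compHL and that of
    group B in S_compLH, or the reciprocal.
    """
    from .io_tables import GroupAssignment  # noqa: F401  (typing only)

    labels = groups.groups
    if len(labels) != 2:
        raise ValueError(f"differential selection needs exactly 2 groups, got {labels}")
    group_a, group_b = labels
    cols_a = [s for s in table.columns if groups.labels[s] == group_a]
    cols_b = [s for s in table.columns if groups.labels[s] == group_b]
    out: list[DifferentialInteraction] = []
    arr_a = table[cols_a].to_numpy()
    arr_b = table[cols_b].to_numpy()
    for r, (mirna, gene) in enumerate(table.index):
        ma = modal_state(arr_a[r])
        mb = modal_state(arr_b[r])
        if ma is None or mb is None:
            continue
        sa, sb = _comp_side(ma), _comp_side(mb)
        if {sa, sb} == {"HL", "LH"}:
            direction = "down_in_A" if sa == "HL" else "up_in_A"
            out.append(
                DifferentialInteraction(
                    mirna_id=mirna,
                    gene_id=gene,
                    modal_states={group_a: ma, group_b: mb},
                    direction=direction,
                )
            )
    return out
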