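"""Vote-counting classifier over interaction states, and its bootstrap
evaluation.

A model is built from top-ranked interactions: for each one it stores the
comp set (S_compHL or S_compLH) containing the modal state of the reference
("first") group. Classifying a sample counts, over the model's interactions,
how many of the sample's states fall in the stored comp set (votes for the
reference group) versus the opposite comp set (votes against); undefined
states cast no vote. The bootstrap protocol repeatedly halves every group
into train/test without replacement, re-runs the whole state pipeline on
each half independently, builds models from the training ranking at several
Jaccard-index thresholds and scores the test samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import pipeline
from .interactions import S_COMP_HL, S_COMP_LH
from .io_tables import AnalysisConfig, ExpressionMatrix, GroupAssignment
from .ranking import RankedInteraction

logger = logging.getLogger(__name__)


@dataclass
class ClassificationModel:
    """Selected interactions with their reference-group comp sets."""

    reference_group: str
    other_group: str
    # interaction -> comp set of states that vote for the reference group
    state_sets: dict[tuple[str, str], frozenset[str]]

    def __len__(self) -> int:
        return len(self.state_sets)


def _comp_set_of(state: str) -> frozenset[str] | None:
    if state in S_COMP_HL:
        return S_COMP_HL
    if state in S_COMP_LH:
        return S_COMP_LH
    return None


def build_model(
    ranked: Sequence[RankedInteraction],
    ji_threshold: float,
    reference_group: str,
    other_group: str,
) -> ClassificationModel:
    """Model from all interactions with JI >= threshold whose reference-group
    modal state lies in a comp set."""
    state_sets: dict[tuple[str, str], frozenset[str]] = {}
    for r in ranked:
        if r.jaccard_index < ji_threshold:
            continue
        modal = r.modal_states.get(reference_group)
        comp = _comp_set_of(modal) if modal is not None else None
        if comp is None:
            continue
        state_sets[r.interaction] = comp
    if not state_sets:
        raise ValueError(
            f"no interaction reaches Jaccard index {ji_threshold}; lower the threshold"
        )
    return ClassificationModel(reference_group, other_group, state_sets)


def build_random_model(
    ranked: Sequence[RankedInteraction],
    n_interactions: int,
    ji_range: tuple[float, float],
    seed: int,
    reference_group: str,
    other_group: str,
) -> ClassificationModel:
    """Model from a uniform sample (without replacement) of interactions whose
    JI lies inside the inclusive range."""
    lo, hi = ji_range
    eligible = [
        r
        for r in ranked
        if lo <= r.jaccard_index <= hi
        and r.modal_states.get(reference_group) is not None
        and _comp_set_of(r.modal_states[reference_group]) is not None
    ]
    if len(eligible) < n_interactions:
        raise ValueError(
            f"only {len(eligible)} interactions inside Jaccard range {ji_range}, "
            f"need {n_interactions}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_interactions, replace=False)
    state_sets = {
        eligible[i].interaction: _comp_set_of(eligible[i].modal_states[reference_group])
        for i in sorted(chosen)
    }
    return ClassificationModel(reference_group, other_group, state_sets)  # type: ignore[arg-type]


def classify_sample(model: ClassificationModel, sample_states: dict[tuple[str, str], str]) -> str:
    """Vote a sample into the reference or the other group.

    ``sample_states`` maps interaction -> this sample's interaction state.
    Model interactions missing from it are skipped. Ties (including the
    all-undefined case) go to the non-reference group.
    """
    c_first = 0
    c_second = 0
    for interaction, comp in model.state_sets.items():
        state = sample_states.get(interaction)
        if state is None:
            continue
        if state in comp:
            c_first += 1
        elif state in (S_COMP_LH if comp is S_COMP_HL else S_COMP_HL):
            c_second += 1
        # undefined states increment neither count
    return model.reference_group if c_first > c_second else model.other_group


def bootstrap_split(groups: GroupAssignment, seed: int) -> tuple[GroupAssignment, GroupAssignment]:
    """Halve every group into train/test without replacement.

    Odd group sizes put the extra sample into training. Sample order inside
    the returned assignments follows the original order.
    """
    rng = np.random.default_rng(seed)
    train_ids: set[str] = set()
    for g in groups.groups:
        members = groups.members(g)
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples; cannot split")
        n_train = (len(members) + 1) // 2
        picked = rng.choice(len(members), size=n_train, replace=False)
        train_ids.update(members[i] for i in picked)
    all_ids = groups.sample_ids
    train = [s for s in all_ids if s in train_ids]
    test = [s for s in all_ids if s not in train_ids]
    return groups.subset(train), groups.subset(test)


@dataclass
class BootstrapSummary:
    """Mean performance over bootstrap replicates, per JI threshold."""

    ji_thresholds: list[float]
    mean_sensitivity: dict[float, float]
    mean_specificity: dict[float, float]
    mean_fpr: dict[float, float]
    mean_model_size: dict[float, float]
    n_replicates: int
    n_skipped: dict[float, int]
    base_seed: int
    reference_group: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ji_threshold": self.ji_thresholds,
                "mean_sensitivity": [self.mean_sensitivity[t] for t in self.ji_thresholds],
                "mean_specificity": [self.mean_specificity[t] for t in self.ji_thresholds],
                "mean_fpr": [self.mean_fpr[t] for t in self.ji_thresholds],
                "mean_model_size": [self.mean_model_size[t] for t in self.ji_thresholds],
                "n_replicates": self.n_replicates,
                "n_skipped": [self.n_skipped[t] for t in self.ji_thresholds],
            }
        )


def _rates(
    predictions: dict[str, str], truth: GroupAssignment, positive: str
) -> tuple[float, float]:
    tp = fn = tn = fp = 0
    for sample, predicted in predictions.items():
        actual = truth.labels[sample]
        if actual == positive:
            if predicted == positive:
                tp += 1
            else:
                fn += 1
        else:
            if predicted == positive:
                fp += 1
            else:
                tn += 1
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return sensitivity, specificity


def run_bootstrap(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    probe_gene_map: pd.Series,
    catalog: Sequence[tuple[str, str]],
    groups: GroupAssignment,
    config: AnalysisConfig,
    n_replicates: int,
    ji_thresholds: Sequence[float],
    seed: int,
    reference_group: str | None = None,
) -> BootstrapSummary:
    """Bootstrap evaluation of the ranking via the vote classifier.

    Per replicate: split every group in half (without replacement, extra
    sample to training), run the state pipeline independently on the training
    and the test samples, build a model from the training ranking per JI
    threshold and classify the test samples using the test-side interaction
    states of the training-selected interactions. The reference group is the
    "positive" class for sensitivity/specificity. Replicate r uses seed
    ``seed + r``, so replicates are individually reproducible.
    """
    labels = groups.groups
    if len(labels) != 2:
        raise ValueError("bootstrap evaluation needs exactly two groups")
    if reference_group is None:
        reference_group = labels[0]
    other_group = next(g for g in labels if g != reference_group)

    sens: dict[float, list[float]] = {t: [] for t in ji_thresholds}
    spec: dict[float, list[float]] = {t: [] for t in ji_thresholds}
    sizes: dict[float, list[int]] = {t: [] for t in ji_thresholds}
    skipped: dict[float, int] = {t: 0 for t in ji_thresholds}

    for r in range(n_replicates):
        train_groups, test_groups = bootstrap_split(groups, seed + r)
        sides = {}
        for name, side_groups in (("train", train_groups), ("test", test_groups)):
            side_mirna = mirna.subset_samples(side_groups.sample_ids)
            side_mrna = mrna.subset_samples(side_groups.sample_ids)
            result = pipeline.derive_interaction_states(
                side_mirna, side_mrna, probe_gene_map, catalog, config
            )
            sides[name] = result
        train_result = pipeline.rank_differential(sides["train"], train_groups)
        test_table = sides["test"].table

        test_states_by_sample = {
            sample: dict(zip(test_table.index, test_table[sample]))
            for sample in test_table.columns
        }
        for t in ji_thresholds:
            try:
                model = build_model(train_result.ranked, t, reference_group, other_group)
            except ValueError:
                skipped[t] += 1
                continue
            predictions = {
                sample: classify_sample(model, states)
                for sample, states in test_states_by_sample.items()
            }
            s_sens, s_spec = _rates(predictions, test_groups, reference_group)
            sens[t].append(s_sens)
            spec[t].append(s_spec)
            sizes[t].append(len(model))

    def mean(xs: list[float]) -> float:
        return float(np.mean(xs)) if xs else float("nan")

    mean_spec = {t: mean(spec[t]) for t in ji_thresholds}
    return BootstrapSummary(
        ji_thresholds=list(ji_thresholds),
        mean_sensitivity={t: mean(sens[t]) for t in ji_thresholds},
        mean_specificity=mean_spec,
        mean_fpr={t: 1.0 - mean_spec[t] for t in ji_thresholds},
        mean_model_size={t: mean(sizes[t]) for t in ji_thresholds},
        n_replicates=n_replicates,
        n_skipped=skipped,
        base_seed=seed,
        reference_group=reference_group,
    )
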