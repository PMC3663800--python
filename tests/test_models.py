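import numpy as np
import pandas as pd
import pytest

import mirstates as ms
from mirstates.interactions import S_COMP_HL, S_COMP_LH
from mirstates.models import (
    bootstrap_split,
    build_model,
    build_random_model,
    classify_sample,
    run_bootstrap,
)
from mirstates.ranking import RankedInteraction


def _ranked_fixture():
    """Five perfect interactions plus some weaker ones for group A vs B."""
    out = []
    for i in range(5):
        out.append(RankedInteraction(
            mirna_id=f"mir-{i}", gene_id=f"g{i}", jaccard_index=1.0,
            direction="down_in_A", modal_states={"A": "HL", "B": "LH"},
        ))
    for i, ji in enumerate([0.8, 0.5, 0.3]):
        out.append(RankedInteraction(
            mirna_id=f"mir-w{i}", gene_id=f"gw{i}", jaccard_index=ji,
            direction="up_in_A", modal_states={"A": "LH", "B": "HL"},
        ))
    return out


class TestBuildModel:
    def test_threshold_one_selects_perfect_five(self):
        model = build_model(_ranked_fixture(), 1.0, "A", "B")
        assert len(model) == 5
        assert all(comp is S_COMP_HL for comp in model.state_sets.values())

    def test_threshold_zero_includes_all(self):
        assert len(build_model(_ranked_fixture(), 0.0, "A", "B")) == 8

    def test_lowering_threshold_never_shrinks(self):
        ranked = _ranked_fixture()
        sizes = [len(build_model(ranked, t, "A", "B")) for t in (1.0, 0.8, 0.5, 0.0)]
        assert sizes == sorted(sizes)

    def test_empty_model_is_an_error(self):
        weak = [r for r in _ranked_fixture() if r.jaccard_index < 1.0]
        with pytest.raises(ValueError, match="lower"):
            build_model(weak, 0.99, "A", "B")

    def test_reference_comp_set_follows_modal_state(self):
        model = build_model(_ranked_fixture(), 0.0, "A", "B")
        assert model.state_sets[("mir-w0", "gw0")] is S_COMP_LH


class TestBuildRandomModel:
    def test_reproducible_under_seed(self):
        ranked = _ranked_fixture()
        a = build_random_model(ranked, 3, (0.0, 1.0), 7, "A", "B")
        b = build_random_model(ranked, 3, (0.0, 1.0), 7, "A", "B")
        assert a.state_sets.keys() == b.state_sets.keys()

    def test_full_range_population_is_deterministic(self):
        ranked = _ranked_fixture()
        model = build_random_model(ranked, 8, (0.0, 1.0), 1, "A", "B")
        assert len(model) == 8

    def test_underpopulated_range_reports_count(self):
        with pytest.raises(ValueError, match="3"):
            build_random_model(_ranked_fixture(), 5, (0.0, 0.9), 0, "A", "B")

    def test_different_seeds_usually_differ(self):
        ranked = _ranked_fixture()
        picks = {
            tuple(sorted(build_random_model(ranked, 3, (0.0, 1.0), s, "A", "B").state_sets))
            for s in range(10)
        }
        assert len(picks) > 1


class TestClassifySample:
    def test_majority_vote(self):
        model = build_model(_ranked_fixture()[:5], 1.0, "A", "B")
        states = {("mir-0", "g0"): "HL", ("mir-1", "g1"): "ML", ("mir-2", "g2"): "LH"}
        assert classify_sample(model, states) == "A"

    def test_all_undefined_ties_to_non_reference(self):
        model = build_model(_ranked_fixture()[:5], 1.0, "A", "B")
        states = {k: "MM" for k in model.state_sets}
        assert classify_sample(model, states) == "B"

    def test_missing_interactions_skipped(self):
        model = build_model(_ranked_fixture()[:5], 1.0, "A", "B")
        assert classify_sample(model, {("mir-0", "g0"): "LH"}) == "B"

    def test_invariant_to_interaction_order(self):
        ranked = _ranked_fixture()
        model_fwd = build_model(ranked, 0.0, "A", "B")
        model_rev = build_model(list(reversed(ranked)), 0.0, "A", "B")
        states = {k: ("HL" if i % 2 else "LH") for i, k in enumerate(model_fwd.state_sets)}
        assert classify_sample(model_fwd, states) == classify_sample(model_rev, states)


class TestBootstrapSplit:
    @staticmethod
    def _groups(sizes):
        labels, ids = [], []
        for g, n in sizes.items():
            for i in range(n):
                ids.append(f"{g}{i}")
                labels.append(g)
        return ms.GroupAssignment(pd.Series(labels, index=ids))

    def test_even_group_halved(self):
        train, test = bootstrap_split(self._groups({"g": 8}), 0)
        assert len(train.sample_ids) == 4 and len(test.sample_ids) == 4

    def test_odd_group_extra_sample_to_training(self):
        train, test = bootstrap_split(self._groups({"g": 7}), 0)
        assert len(train.sample_ids) == 4 and len(test.sample_ids) == 3

    def test_colon_collective_shape(self):
        # groups of 4 healthy and 7 tumor -> train 2+4, test 2+3
        groups = self._groups({"healthy": 4, "tumor": 7})
        train, test = bootstrap_split(groups, 3)
        assert len(train.members("healthy")) == 2 and len(train.members("tumor")) == 4
        assert len(test.members("healthy")) == 2 and len(test.members("tumor")) == 3

    def test_disjoint_and_exhaustive(self):
        groups = self._groups({"a": 5, "b": 6})
        train, test = bootstrap_split(groups, 11)
        assert set(train.sample_ids).isdisjoint(test.sample_ids)
        assert set(train.sample_ids) | set(test.sample_ids) == set(groups.sample_ids)

    def test_deterministic_per_seed(self):
        groups = self._groups({"a": 6, "b": 6})
        assert bootstrap_split(groups, 5)[0].sample_ids == bootstrap_split(groups, 5)[0].sample_ids
        assert bootstrap_split(groups, 5)[0].sample_ids != bootstrap_split(groups, 6)[0].sample_ids


class TestPerfectJiConsistency:
    def test_model_from_perfect_interactions_classifies_training_exactly(self, planted_result):
        """Interactions with JI = 1.0 force all votes one way per group."""
        result, _truth, groups = planted_result
        ref, other = groups.groups
        model = build_model(result.ranked, 1.0, ref, other)
        table = result.table
        for sample in table.columns:
            states = dict(zip(table.index, table[sample]))
            assert classify_sample(model, states) == groups.labels[sample]


@pytest.fixture(scope="module")
def small_dataset():
    params = ms.SimulationParams(
        group_sizes={"n": 4, "t": 4}, contrast={"n": "n", "t": "t"},
        n_planted=12, n_decoys=12,
    )
    return ms.generate_dataset(params)


class TestRunBootstrap:
    def test_reproducible_under_seed(self, small_dataset, config):
        mirna, mrna, pg_map, catalog, groups, _ = small_dataset
        kwargs = dict(n_replicates=3, ji_thresholds=[0.5], seed=9, reference_group="t")
        a = run_bootstrap(mirna, mrna, pg_map, catalog, groups, config, **kwargs)
        b = run_bootstrap(mirna, mrna, pg_map, catalog, groups, config, **kwargs)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_rates_within_unit_interval(self, small_dataset, config):
        mirna, mrna, pg_map, catalog, groups, _ = small_dataset
        s = run_bootstrap(
            mirna, mrna, pg_map, catalog, groups, config,
            n_replicates=5, ji_thresholds=[0.0, 1.0], seed=2, reference_group="t",
        )
        for t in s.ji_thresholds:
            if s.n_skipped[t] < s.n_replicates:
                assert 0.0 <= s.mean_sensitivity[t] <= 1.0
                assert 0.0 <= s.mean_specificity[t] <= 1.0
                assert s.mean_fpr[t] == pytest.approx(1.0 - s.mean_specificity[t])
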