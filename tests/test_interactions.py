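import numpy as np
import pandas as pd
import pytest

import mirstates as ms
from mirstates.interactions import (
    INTERACTION_STATES,
    S_COMP_HL,
    S_COMP_LH,
    S_UNDEF,
    aggregate_gene_states,
    build_interaction_states,
    filter_by_medium_ratio,
    filter_by_undefined_frequency,
    modal_state,
    select_differential,
)


def _states(rows, index, samples=None):
    samples = samples or [f"s{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, index=index, columns=samples)


class TestStateAlphabet:
    def test_nine_states_partitioned_three_ways(self):
        assert len(INTERACTION_STATES) == 9
        assert S_COMP_HL | S_COMP_LH | S_UNDEF == INTERACTION_STATES
        assert len(S_COMP_HL) == len(S_COMP_LH) == len(S_UNDEF) == 3
        assert S_COMP_HL.isdisjoint(S_COMP_LH)
        assert S_UNDEF.isdisjoint(S_COMP_HL | S_COMP_LH)


class TestGeneAggregation:
    @pytest.mark.parametrize(
        "probe_states,expected",
        [
            (["L", "L", "H"], "L"),  # strict majority
            (["L", "H"], "L"),  # tie: preference low
            (["M", "H"], "H"),  # tie: high before medium
            (["M", "M", "H"], "M"),  # strict majority of M
        ],
    )
    def test_modal_with_preference_order(self, probe_states, expected):
        probes = [f"p{i}" for i in range(len(probe_states))]
        states = _states([[s] * 2 for s in probe_states], probes)
        mapping = pd.Series("g1", index=probes)
        out = aggregate_gene_states(states, mapping)
        assert out.loc["g1"].tolist() == [expected, expected]

    def test_unmapped_probe_is_fatal(self):
        states = _states([["L", "H"]], ["p1"])
        with pytest.raises(ValueError, match="p1"):
            aggregate_gene_states(states, pd.Series(dtype=object))

    def test_single_probe_genes_pass_through(self):
        states = _states([["L", "M"], ["H", "H"]], ["p1", "p2"])
        mapping = pd.Series(["g1", "g2"], index=["p1", "p2"])
        out = aggregate_gene_states(states, mapping)
        assert out.loc["g1"].tolist() == ["L", "M"]
        assert out.loc["g2"].tolist() == ["H", "H"]


class TestMediumRatioFilter:
    def test_strict_inequality(self):
        rows = [["M"] * 8, ["L", "H"] * 4, ["M", "M", "M", "L", "H", "L", "H", "L"]]
        states = _states(rows, ["allM", "noM", "threeM"])
        kept = filter_by_medium_ratio(states, 0.5)
        assert list(kept.index) == ["noM", "threeM"]
        # 3/8 = 0.375 is not strictly greater than 0.375 -> kept
        kept = filter_by_medium_ratio(states, 0.375)
        assert "threeM" in kept.index
        kept = filter_by_medium_ratio(states, 0.374)
        assert "threeM" not in kept.index


class TestInteractionStates:
    def test_concatenation_order_mirna_then_gene(self):
        mir = _states([["L", "H", "M"]], ["mir-1"])
        gene = _states([["H", "L", "M"]], ["g1"])
        table = build_interaction_states(mir, gene, [("mir-1", "g1")])
        assert table.loc[("mir-1", "g1")].tolist() == ["LH", "HL", "MM"]

    def test_unresolvable_pairs_dropped_not_fatal(self):
        mir = _states([["L", "H"]], ["mir-1"])
        gene = _states([["H", "L"]], ["g1"])
        table = build_interaction_states(
            mir, gene, [("mir-1", "g1"), ("mir-2", "g1"), ("mir-1", "gX")]
        )
        assert len(table) == 1

    def test_undefined_frequency_filter_strict(self):
        idx = pd.MultiIndex.from_tuples([("m", "a"), ("m", "b"), ("m", "c")])
        table = pd.DataFrame(
            [["MM"] * 8, ["HL"] * 8, ["MM", "HH", "LL", "LL", "HL", "LH", "HL", "LH"]],
            index=idx,
            columns=[f"s{i}" for i in range(8)],
        )
        kept = filter_by_undefined_frequency(table, 0.5)
        # all-MM removed; 4/8 undefined == 0.5 is kept (not strictly greater)
        assert [g for _, g in kept.index] == ["b", "c"]


class TestDifferentialSelection:
    @staticmethod
    def _table(states_a, states_b):
        idx = pd.MultiIndex.from_tuples([("mir", "g")], names=["mirna_id", "gene_id"])
        samples = [f"a{i}" for i in range(len(states_a))] + [f"b{i}" for i in range(len(states_b))]
        table = pd.DataFrame([states_a + states_b], index=idx, columns=samples)
        groups = ms.GroupAssignment(
            pd.Series(["A"] * len(states_a) + ["B"] * len(states_b), index=samples)
        )
        return table, groups

    def test_opposite_modal_states_selected_with_direction(self):
        table, groups = self._table(["HL", "HL", "ML"], ["LH", "LH", "MH"])
        (di,) = select_differential(table, groups)
        assert di.direction == "down_in_A"
        assert di.modal_states == {"A": "HL", "B": "LH"}

    def test_reciprocal_direction(self):
        table, groups = self._table(["LH", "LH"], ["HL", "HL"])
        (di,) = select_differential(table, groups)
        assert di.direction == "up_in_A"

    def test_same_side_not_selected(self):
        table, groups = self._table(["HL", "HL"], ["HL", "ML"])
        assert select_differential(table, groups) == []

    def test_undefined_modal_not_selected(self):
        table, groups = self._table(["MM", "MM", "HL"], ["LH", "LH", "LH"])
        assert select_differential(table, groups) == []

    def test_ambiguous_tie_not_selected(self):
        # A: HL and MM tied -> comp assignment ambiguous -> skipped
        table, groups = self._table(["HL", "MM"], ["LH", "LH"])
        assert select_differential(table, groups) == []

    def test_tie_within_one_comp_set_is_unambiguous(self):
        table, groups = self._table(["HL", "ML"], ["LH", "MH"])
        (di,) = select_differential(table, groups)
        assert di.direction == "down_in_A"

    def test_emitted_modal_states_in_opposite_comp_sets(self, planted_result):
        result, _truth, _groups = planted_result
        assert result.differential
        for di in result.differential:
            sides = {s in S_COMP_HL for s in di.modal_states.values()}
            assert sides == {True, False}


class TestModalState:
    def test_plain_majority(self):
        assert modal_state(["HL", "HL", "LH"]) == "HL"

    def test_straddling_tie_is_none(self):
        assert modal_state(["HL", "LH"]) is None
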