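"""Revised counts, threshold calibration, classification and the
resistance index."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mutdiff import (
    CodingGenome,
    ContextClass,
    DataError,
    MutationEvent,
    MutationRecord,
    annotate_gene,
    build_difficulty,
    calibrate_thresholds,
    cancer_type_difficulty,
    classify,
    estimate_tendencies,
    resistance_index,
    revised_count,
)
from mutdiff.revise import INDETERMINATE, LOF, UNSCORED, WT_LIKE
from helpers import make_estimate, uniform_table


class TestRevisedCount:
    def test_cancer_type_weighted_sum(self, toy_genome):
        # 10 samples in a type with difficulty 1 plus 5 in a type with
        # difficulty 3 -> revised count 25
        recs_colo = [
            MutationRecord("g1", f"c{i}", "colorectal", 11, "T", "G") for i in range(3)
        ]
        recs_lung = [MutationRecord("g1", f"l{i}", "lung", 11, "T", "G") for i in range(1)]
        pan = build_difficulty(
            estimate_tendencies(
                [MutationRecord("g1", f"p{i}", "x", 3, "C", "T") for i in range(3)],
                toy_genome,
                n_genomes=1,
            )
        )
        tables = cancer_type_difficulty(
            {"colorectal": recs_colo, "lung": recs_lung},
            toy_genome,
            samples_per_type={"colorectal": 1, "lung": 1},
            pan_reference_rate=pan.reference_rate,
            min_samples=1,
        )
        assert tables["colorectal"].difficulty("GATGT", "G") == pytest.approx(1.0)
        assert tables["lung"].difficulty("GATGT", "G") == pytest.approx(3.0)
        event = MutationEvent("g1", 11, "T", "G", {"colorectal": 10, "lung": 5})
        a = revised_count(event, toy_genome, per_type_tables=tables)
        assert a.revised_count == pytest.approx(25.0)
        assert a.contributions["colorectal"] == (10, pytest.approx(1.0), pytest.approx(10.0))
        assert a.contributions["lung"] == (5, pytest.approx(3.0), pytest.approx(15.0))

    def test_single_difficulty_233(self, toy_genome):
        est = make_estimate(
            {ContextClass("TTCGT", "T"): 233, ContextClass("GATGT", "G"): 1},
            {"TTCGT": 1, "GATGT": 1},
        )
        table = build_difficulty(est)
        event = MutationEvent("g1", 11, "T", "G", {"pan": 11})
        a = revised_count(event, toy_genome, fallback_table=table)
        assert a.revised_count == pytest.approx(2563.0)
        assert a.label == LOF

    def test_empty_event_gives_zero(self, toy_genome):
        table = uniform_table(toy_genome)
        event = MutationEvent("g1", 11, "T", "G", {})
        a = revised_count(event, toy_genome, fallback_table=table)
        assert a.revised_count == 0.0

    def test_all_difficulties_one_reduces_to_original_count(self, toy_genome):
        table = uniform_table(toy_genome, difficulty_value=1.0)
        event = MutationEvent("g1", 3, "C", "T", {"a": 4, "b": 3})
        a = revised_count(event, toy_genome, fallback_table=table)
        assert a.revised_count == pytest.approx(event.original_count)

    def test_additive_and_linear_in_counts(self, toy_genome):
        est = make_estimate(
            {ContextClass("TTCGT", "T"): 6, ContextClass("GATGT", "G"): 2},
            {"TTCGT": 1, "GATGT": 1},
        )
        table = build_difficulty(est)
        r1 = revised_count(
            MutationEvent("g1", 11, "T", "G", {"a": 2}), toy_genome, fallback_table=table
        ).revised_count
        r2 = revised_count(
            MutationEvent("g1", 11, "T", "G", {"b": 5}), toy_genome, fallback_table=table
        ).revised_count
        both = revised_count(
            MutationEvent("g1", 11, "T", "G", {"a": 2, "b": 5}),
            toy_genome,
            fallback_table=table,
        ).revised_count
        assert both == pytest.approx(r1 + r2)
        tripled = revised_count(
            MutationEvent("g1", 11, "T", "G", {"a": 6}), toy_genome, fallback_table=table
        ).revised_count
        assert tripled == pytest.approx(3 * r1)

    def test_context_unavailable_event_raises(self, toy_genome):
        table = uniform_table(toy_genome)
        event = MutationEvent("g1", 1, "T", "G", {"a": 1})
        with pytest.raises(DataError, match="context unavailable"):
            revised_count(event, toy_genome, fallback_table=table)

    def test_missing_table_raises(self, toy_genome):
        event = MutationEvent("g1", 3, "C", "T", {"a": 1})
        with pytest.raises(DataError, match="no difficulty table"):
            revised_count(event, toy_genome)


class TestClassify:
    @pytest.mark.parametrize(
        "r, mnv, expected",
        [
            (186, False, WT_LIKE),
            (2887, False, LOF),
            (800, False, INDETERMINATE),
            (700, False, INDETERMINATE),  # boundary: strict inequalities
            (900, False, INDETERMINATE),
            (699.9, False, WT_LIKE),
            (900.1, False, LOF),
            (400, True, UNSCORED),
            (800, True, UNSCORED),
            (2887, True, LOF),  # SNV-derived count already exceeds the bound
        ],
    )
    def test_contract(self, r, mnv, expected):
        assert classify(r, mnv_support=mnv) == expected

    def test_threshold_order_validated(self):
        with pytest.raises(DataError):
            classify(100, wt_max=1000, lof_min=900)

    @given(st.floats(min_value=0, max_value=5000), st.floats(min_value=0, max_value=5000))
    def test_monotone_in_revised_count(self, r1, r2):
        order = {WT_LIKE: 0, INDETERMINATE: 1, LOF: 2}
        lo, hi = sorted([r1, r2])
        assert order[classify(lo)] <= order[classify(hi)]


class TestCalibrateThresholds:
    def test_percentile_matches_sorted_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(10, 690, size=40).tolist()
        cal = calibrate_thresholds(values, percentile=95)
        assert cal.wt_max <= 700
        # brute-force oracle: sort and interpolate at rank 0.95*(n-1)
        s = sorted(values)
        rank = 0.95 * (len(s) - 1)
        lo, frac = int(rank), rank - int(rank)
        expected = s[lo] + frac * (s[lo + 1] - s[lo])
        assert cal.wt_max == pytest.approx(expected)

    def test_degenerate_all_equal(self):
        cal = calibrate_thresholds([400.0] * 25)
        assert cal.wt_max == pytest.approx(400.0)
        assert cal.outliers == []

    def test_outlier_listed_and_percentile_robust(self):
        values = [100.0 + i for i in range(30)] + [5000.0]
        cal = calibrate_thresholds(values, percentile=90)
        assert any(v == 5000.0 for _, v in cal.outliers)
        assert cal.wt_max < 200  # the single outlier barely moves the 90th pct

    def test_too_few_events_suggests_defaults(self):
        with pytest.raises(DataError, match="700"):
            calibrate_thresholds([100.0] * 5)


class TestAnnotateGene:
    def _setup(self):
        # gene of 5 codons with varied contexts; uniform difficulty 10
        genome = CodingGenome({"g1": "ATGTTCGTACCAGGA"}, {"g1": ("CC", "GG")})
        table = uniform_table(genome, difficulty_value=10.0)
        return genome, table

    def test_rows_match_manual_computation(self):
        genome, table = self._setup()
        events = [
            MutationEvent("g1", 6, "C", "T", {"a": 2}),
            MutationEvent("g1", 7, "G", "A", {"a": 1, "b": 3}),
            MutationEvent("g1", 9, "A", "C", {"b": 5}),
            MutationEvent("g1", 10, "C", "G", {"a": 1}),
            MutationEvent("g1", 12, "A", "T", {"a": 90, "b": 5}),
        ]
        df = annotate_gene(events, genome, fallback_table=table)
        assert len(df) == 5
        # uniform difficulty 10: every revised count is 10x the original
        assert df["revised_count"].tolist() == pytest.approx(
            [20.0, 40.0, 50.0, 10.0, 950.0]
        )
        assert df["label"].tolist() == [WT_LIKE] * 4 + [LOF]
        assert df.loc[0, "cds_change"] == "c.6C>T"

    def test_ranking_by_revised_equals_ranking_by_original_under_unit_difficulty(self):
        genome, _ = self._setup()
        table = uniform_table(genome, difficulty_value=1.0)
        events = [
            MutationEvent("g1", 6, "C", "T", {"a": 7}),
            MutationEvent("g1", 9, "A", "C", {"a": 2}),
            MutationEvent("g1", 12, "A", "T", {"a": 30}),
        ]
        df = annotate_gene(events, genome, fallback_table=table)
        assert df["revised_count"].tolist() == pytest.approx(
            [float(o) for o in df["original_count"]]
        )

    def test_per_residue_aggregation_sums_events(self):
        genome, table = self._setup()
        # two different substitutions on the same codon (positions 7 and 8
        # are both codon 3)
        events = [
            MutationEvent("g1", 7, "G", "A", {"a": 2}),
            MutationEvent("g1", 8, "T", "C", {"a": 3}),
        ]
        df = annotate_gene(events, genome, fallback_table=table)
        agg = annotate_gene(events, genome, fallback_table=table, per_residue=True)
        assert len(df) == 2 and len(agg) == 1
        assert agg.loc[0, "original_count"] == 5
        assert agg.loc[0, "revised_count"] == pytest.approx(
            df["revised_count"].sum()
        )

    def test_empty_event_list(self):
        genome, table = self._setup()
        assert annotate_gene([], genome, fallback_table=table).empty

    def test_unscored_label_for_mnv_supported_event(self):
        genome, table = self._setup()
        ev = MutationEvent("g1", 6, "C", "T", {"a": 2}, mnv_support=True)
        df = annotate_gene([ev], genome, fallback_table=table)
        assert df.loc[0, "label"] == UNSCORED
        assert df.loc[0, "flags"] == "mnv_support"


class TestResistanceIndex:
    @pytest.mark.parametrize(
        "g1, g2, expected",
        [(0.4, 0.4, 1.0), (0.3, 0.6, 3.5), (0.5, 0.25, 1 / 3)],
    )
    def test_values(self, g1, g2, expected):
        assert resistance_index(g1, g2) == pytest.approx(expected)

    @pytest.mark.parametrize("g1", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_g1(self, g1):
        with pytest.raises(DataError):
            resistance_index(g1, 0.5)

    def test_g2_one_is_undefined(self):
        with pytest.raises(DataError):
            resistance_index(0.5, 1.0)

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_no_enrichment_gives_unity(self, g):
        assert resistance_index(g, g) == pytest.approx(1.0)

    @given(
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.0, max_value=0.98),
        st.floats(min_value=0.001, max_value=0.019),
    )
    def test_strictly_increasing_in_g2(self, g1, g2, delta):
        assert resistance_index(g1, g2 + delta) > resistance_index(g1, g2)
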