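"""Filtering, rarefaction, normalization and aggregation on the OTU table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sipnet.exceptions import EmptyInputError, GroupingError
from sipnet.otu import (
    SampleGroup,
    aggregate_replicates,
    aggregate_taxonomy,
    filter_by_relative_abundance,
    prevalence_filter,
    rarefaction_curve,
    rarefy,
    to_proportions,
)

from conftest import make_table


class TestAbundanceFilter:
    def test_strict_0005_percent_threshold(self):
        # grand total 100,000: 6 reads = 0.006% kept, 4 = 0.004% dropped,
        # 5 reads sits exactly at the threshold and is dropped (strict >)
        counts = pd.DataFrame(
            {"keep": [6], "drop": [4], "exact": [5], "bulk_otu": [99985]},
            index=["s1"],
        )
        table = make_table(counts)
        out = filter_by_relative_abundance(table, min_fraction=5e-5)
        assert set(out.otu_ids) == {"keep", "bulk_otu"}

    def test_zero_threshold_drops_only_allzero_otus(self):
        counts = pd.DataFrame({"a": [1, 0], "z": [0, 0]}, index=["s1", "s2"])
        out = filter_by_relative_abundance(make_table(counts), min_fraction=0.0)
        assert out.otu_ids == ["a"]

    def test_empty_table_raises(self):
        counts = pd.DataFrame({"a": [0]}, index=["s1"])
        with pytest.raises(EmptyInputError):
            filter_by_relative_abundance(make_table(counts))

    @settings(derandomize=True, max_examples=25)
    @given(
        arrays(
            np.int64,
            (3, 6),
            elements=st.integers(min_value=0, max_value=200),
        ).filter(lambda a: a.sum() > 0)
    )
    def test_idempotence(self, raw):
        counts = pd.DataFrame(raw, index=["s1", "s2", "s3"], columns=list("abcdef"))
        once = filter_by_relative_abundance(make_table(counts), 5e-3)
        twice = filter_by_relative_abundance(once, 5e-3)
        assert once.otu_ids == twice.otu_ids


class TestPrevalenceFilter:
    def test_strictly_more_than_25_percent(self):
        # 12 samples: present in 4 (33%) kept, in 3 (exactly 25%) dropped
        data = np.zeros((12, 2), dtype=int)
        data[:4, 0] = 1
        data[:3, 1] = 1
        counts = pd.DataFrame(data, index=[f"s{i}" for i in range(12)], columns=["in4", "in3"])
        out = prevalence_filter(make_table(counts), min_prevalence=0.25)
        assert out.otu_ids == ["in4"]

    def test_zero_prevalence_keeps_any_occurrence(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 0]}, index=["s1", "s2"])
        out = prevalence_filter(make_table(counts), min_prevalence=0.0)
        assert out.otu_ids == ["a"]

    def test_ubiquitous_otu_survives_any_threshold_below_one(self):
        counts = pd.DataFrame({"a": [2, 3, 1]}, index=["s1", "s2", "s3"])
        for prev in (0.0, 0.25, 0.5, 0.99):
            assert prevalence_filter(make_table(counts), prev).otu_ids == ["a"]


class TestRarefy:
    def test_totals_exactly_depth(self):
        counts = pd.DataFrame(
            {"a": [100, 50], "b": [200, 70], "c": [300, 9000]},
            index=["s1", "s2"],
        )
        out = rarefy(make_table(counts), depth=100, seed=3)
        assert (out.counts.sum(axis=1) == 100).all()

    def test_depth_equal_to_total_returns_sample_unchanged(self):
        counts = pd.DataFrame({"a": [7], "b": [3]}, index=["s1"])
        out = rarefy(make_table(counts), depth=10, seed=0)
        assert out.counts.loc["s1"].tolist() == [7, 3]

    def test_shallow_sample_dropped_with_warning(self, caplog):
        counts = pd.DataFrame({"a": [1000, 5000]}, index=["shallow", "deep"])
        with caplog.at_level("WARNING"):
            out = rarefy(make_table(counts), depth=2744, seed=0)
        assert out.sample_ids == ["deep"]
        assert "shallow" in caplog.text

    def test_depth_one_gives_single_read(self):
        counts = pd.DataFrame({"a": [5], "b": [5]}, index=["s1"])
        out = rarefy(make_table(counts), depth=1, seed=1)
        assert out.counts.loc["s1"].sum() == 1

    def test_seed_reproducibility(self):
        counts = pd.DataFrame(
            np.arange(1, 13).reshape(2, 6) * 10,
            index=["s1", "s2"],
            columns=list("abcdef"),
        )
        a = rarefy(make_table(counts), depth=50, seed=42)
        b = rarefy(make_table(counts), depth=50, seed=42)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_invalid_depth(self):
        counts = pd.DataFrame({"a": [5]}, index=["s1"])
        with pytest.raises(ValueError):
            rarefy(make_table(counts), depth=0, seed=0)


class TestRarefactionCurve:
    def test_full_depth_equals_observed_richness(self):
        counts = pd.DataFrame({"a": [5], "b": [5], "c": [0]}, index=["s1"])
        curve = rarefaction_curve(make_table(counts), "s1", [10], reps=5, seed=0)
        assert curve == [(10, 2.0)]

    def test_depth_one_gives_richness_one(self):
        counts = pd.DataFrame({"a": [4], "b": [6]}, index=["s1"])
        curve = rarefaction_curve(make_table(counts), "s1", [1], reps=50, seed=0)
        assert curve == [(1, 1.0)]

    def test_hypergeometric_expectation_two_otus(self):
        # sample (5, 5), depth 2: P(both reads same OTU) = 2*(5/10)*(4/9) = 4/9,
        # so E[richness] = 1 + 5/9; Monte-Carlo mean within 3 SE at 10,000 reps
        counts = pd.DataFrame({"a": [5], "b": [5]}, index=["s1"])
        reps = 10_000
        [(_, mean)] = rarefaction_curve(make_table(counts), "s1", [2], reps=reps, seed=7)
        expected = 1 + 5 / 9
        se = np.sqrt((5 / 9) * (4 / 9) / reps)
        assert abs(mean - expected) < 3 * se

    def test_depth_exceeding_total_raises(self):
        counts = pd.DataFrame({"a": [5]}, index=["s1"])
        with pytest.raises(ValueError):
            rarefaction_curve(make_table(counts), "s1", [6], reps=2, seed=0)


class TestToProportions:
    def test_per_sample(self):
        counts = pd.DataFrame({"a": [10], "b": [30], "c": [60]}, index=["s1"])
        out = to_proportions(make_table(counts), "per_sample")
        assert out.loc["s1"].tolist() == [0.1, 0.3, 0.6]

    def test_per_otu(self):
        counts = pd.DataFrame({"a": [2, 2]}, index=["s1", "s2"])
        out = to_proportions(make_table(counts), "per_otu")
        assert out["a"].tolist() == [0.5, 0.5]

    def test_per_otu_scale_invariance(self):
        counts = pd.DataFrame({"a": [1, 3], "b": [4, 2]}, index=["s1", "s2"])
        doubled = counts.copy()
        doubled["a"] *= 2
        p1 = to_proportions(make_table(counts), "per_otu")
        p2 = to_proportions(make_table(doubled), "per_otu")
        pd.testing.assert_frame_equal(p1, p2)

    def test_rows_sum_to_one(self):
        counts = pd.DataFrame({"a": [3, 1], "b": [2, 9]}, index=["s1", "s2"])
        out = to_proportions(make_table(counts), "per_sample")
        assert np.allclose(out.sum(axis=1), 1.0)


class TestAggregation:
    def test_sum_and_mean_of_replicates(self):
        counts = pd.DataFrame({"a": [1, 2, 3]}, index=["r1", "r2", "r3"])
        table = make_table(counts)
        group = [SampleGroup("g", frozenset(["r1", "r2", "r3"]))]
        assert aggregate_replicates(table, group, "sum").counts.loc["g", "a"] == 6
        assert aggregate_replicates(table, group, "mean").counts.loc["g", "a"] == 2

    def test_single_sample_group_identity(self):
        counts = pd.DataFrame({"a": [4], "b": [5]}, index=["s1"])
        table = make_table(counts)
        out = aggregate_replicates(table, [SampleGroup("only", frozenset(["s1"]))])
        assert out.counts.loc["only"].tolist() == [4, 5]

    def test_overlapping_groups_rejected(self):
        counts = pd.DataFrame({"a": [1, 2]}, index=["s1", "s2"])
        table = make_table(counts)
        groups = [
            SampleGroup("g1", frozenset(["s1", "s2"])),
            SampleGroup("g2", frozenset(["s2"])),
        ]
        with pytest.raises(GroupingError):
            aggregate_replicates(table, groups)

    def test_taxonomy_aggregation_sums_and_pools_unclassified(self, small_table):
        out = aggregate_taxonomy(small_table, "phylum")
        # otu1 + otu3 are Proteobacteria: 10+60, 0+5, 3+7
        assert out["Proteobacteria"].tolist() == [70, 5, 10]
        assert out["unclassified"].tolist() == [0, 0, 0]  # otu4 has empty lineage
        assert out.to_numpy().sum() == small_table.counts.to_numpy().sum()

    def test_unknown_rank_rejected(self, small_table):
        with pytest.raises(ValueError):
            aggregate_taxonomy(small_table, "kingdom")
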