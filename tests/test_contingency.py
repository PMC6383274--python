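import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from addinter.contingency import (
    ExposureTable2x4,
    GroupSummary,
    build_exposure_table,
    chisq_rxc,
    crude_or,
    summarize_by_group,
    two_sample_t,
    woolf_ci,
)
from addinter.errors import ValidationError, ZeroCellError
from addinter.records import StudyDataset

from .conftest import TABLE5_COUNTS, dataset_from_cell_counts

counts = st.integers(min_value=1, max_value=500)


class TestBuildExposureTable:
    def test_empty_dataset_gives_zero_table(self):
        table = build_exposure_table(StudyDataset(records=[]))
        assert all(v == (0, 0) for v in table.counts.values())

    def test_one_case_per_combo(self):
        ds = dataset_from_cell_counts({c: (1, 0) for c in TABLE5_COUNTS})
        table = build_exposure_table(ds)
        assert all(v == (1, 0) for v in table.counts.values())
        assert table.case_total == 4
        assert table.control_total == 0

    def test_reproduces_study_cell_counts(self, table5_dataset):
        table = build_exposure_table(table5_dataset)
        assert table.counts == TABLE5_COUNTS

    def test_counts_partition_dataset(self, table5_dataset):
        table = build_exposure_table(table5_dataset)
        assert table.case_total + table.control_total == len(table5_dataset.records)


class TestCrudeOr:
    def test_study_odds_ratios(self, table5):
        """Crude ORs and Woolf CIs reproduce the printed rows exactly."""
        bmi_only = crude_or(table5, (0, 1))
        assert bmi_only.or_point == pytest.approx(3.333, abs=5e-4)
        assert bmi_only.ci_low == pytest.approx(1.679, abs=5e-4)
        assert bmi_only.ci_high == pytest.approx(6.617, abs=5e-4)
        fh_only = crude_or(table5, (1, 0))
        assert fh_only.or_point == pytest.approx(4.986, abs=5e-4)
        assert fh_only.ci_low == pytest.approx(2.832, abs=5e-4)
        assert fh_only.ci_high == pytest.approx(8.777, abs=5e-4)

    def test_identical_odds_give_unity(self):
        table = ExposureTable2x4(
            counts={(0, 0): (10, 10), (0, 1): (10, 10), (1, 0): (1, 1), (1, 1): (1, 1)}
        )
        est = crude_or(table, (0, 1))
        assert est.or_point == pytest.approx(1.0)
        assert est.ci_low < 1 < est.ci_high

    def test_reference_against_itself_is_one(self, table5):
        assert crude_or(table5, (0, 0)).or_point == 1.0

    def test_zero_cell_raises_without_continuity(self):
        table = ExposureTable2x4(
            counts={(0, 0): (10, 10), (0, 1): (0, 10), (1, 0): (1, 1), (1, 1): (1, 1)}
        )
        with pytest.raises(ZeroCellError):
            crude_or(table, (0, 1))
        est = crude_or(table, (0, 1), continuity=True)
        assert est.continuity is True
        assert est.or_point == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    @given(a=counts, b=counts, c=counts, d=counts, k=st.integers(2, 9))
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, a, b, c, d, k):
        """OR(ka, kb, kc, kd) = OR(a, b, c, d)."""
        t1 = ExposureTable2x4(
            counts={(0, 0): (c, d), (0, 1): (a, b), (1, 0): (1, 1), (1, 1): (1, 1)}
        )
        t2 = ExposureTable2x4(
            counts={(0, 0): (k * c, k * d), (0, 1): (k * a, k * b),
                    (1, 0): (1, 1), (1, 1): (1, 1)}
        )
        assert crude_or(t2, (0, 1)).or_point == pytest.approx(
            crude_or(t1, (0, 1)).or_point, rel=1e-12
        )

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(max_examples=100, derandomize=True)
    def test_case_control_exchange_inverts(self, a, b, c, d):
        """Swapping case and control columns maps OR -> 1/OR and flips CIs."""
        t = ExposureTable2x4(
            counts={(0, 0): (c, d), (0, 1): (a, b), (1, 0): (1, 1), (1, 1): (1, 1)}
        )
        t_swapped = ExposureTable2x4(
            counts={(0, 0): (d, c), (0, 1): (b, a), (1, 0): (1, 1), (1, 1): (1, 1)}
        )
        est = crude_or(t, (0, 1))
        swapped = crude_or(t_swapped, (0, 1))
        assert swapped.or_point == pytest.approx(1 / est.or_point, rel=1e-12)
        assert swapped.ci_low == pytest.approx(1 / est.ci_high, rel=1e-9)
        assert swapped.ci_high == pytest.approx(1 / est.ci_low, rel=1e-9)


class TestWoolfCi:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((32, 36, 20, 75), (1.679, 6.617)),
            ((117, 88, 20, 75), (2.832, 8.777)),
        ],
    )
    def test_printed_intervals(self, cells, expected):
        low, high = woolf_ci(*cells)
        assert low == pytest.approx(expected[0], abs=5e-4)
        assert high == pytest.approx(expected[1], abs=5e-4)

    def test_symmetric_table_brackets_one(self):
        low, high = woolf_ci(10, 10, 10, 10)
        assert low == pytest.approx(1 / high, rel=1e-12)
        assert low < 1 < high

    @given(a=counts, b=counts, c=counts, d=counts, bump=st.integers(1, 50))
    @settings(max_examples=100, derandomize=True)
    def test_width_shrinks_as_counts_grow(self, a, b, c, d, bump):
        low1, high1 = woolf_ci(a, b, c, d)
        low2, high2 = woolf_ci(a + bump, b, c, d)
        assert math.log(high2) - math.log(low2) <= math.log(high1) - math.log(low1) + 1e-12

    def test_zero_count_raises(self):
        with pytest.raises(ZeroCellError):
            woolf_ci(0, 10, 10, 10)


class TestTwoSampleT:
    @pytest.mark.parametrize(
        "control, case, expected_t",
        [
            ((62.62, 10.04), (67.75, 11.35), 6.26),  # weight
            ((83.73, 9.96), (88.69, 9.09), 6.80),  # waist circumference
            ((92.79, 9.26), (96.07, 8.22), 4.90),  # hip circumference
        ],
    )
    def test_study_summary_statistics(self, control, case, expected_t):
        s1 = GroupSummary("v", "control", 342, *control)
        s2 = GroupSummary("v", "case", 342, *case)
        result = two_sample_t(s1, s2)
        assert result.t == pytest.approx(expected_t, abs=0.01)
        assert result.p < 0.001

    def test_identical_summaries(self):
        s = GroupSummary("v", "g", 10, 5.0, 2.0)
        assert two_sample_t(s, s).t == 0.0

    def test_zero_variance_equal_means(self):
        s = GroupSummary("v", "g", 10, 5.0, 0.0)
        result = two_sample_t(s, s)
        assert result.t == 0.0 and result.p == 1.0

    def test_zero_variance_unequal_means_is_infinite(self):
        s1 = GroupSummary("v", "a", 10, 5.0, 0.0)
        s2 = GroupSummary("v", "b", 10, 6.0, 0.0)
        result = two_sample_t(s1, s2)
        assert math.isinf(result.t) and result.p == 0.0

    @given(
        mean1=st.floats(-50, 50), mean2=st.floats(-50, 50),
        sd=st.floats(0.5, 20), n=st.integers(2, 500),
    )
    @settings(max_examples=100, derandomize=True)
    def test_equal_n_matches_pooled_form(self, mean1, mean2, sd, n):
        """With n1 = n2 the Welch statistic equals the pooled-variance t."""
        s1 = GroupSummary("v", "a", n, mean1, sd)
        s2 = GroupSummary("v", "b", n, mean2, sd * 1.5)
        welch = two_sample_t(s1, s2).t
        sp2 = (sd**2 + (1.5 * sd) ** 2) / 2
        pooled = abs(mean2 - mean1) / math.sqrt(sp2 * 2 / n)
        assert welch == pytest.approx(pooled, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t(GroupSummary("v", "a", 1, 5.0, 1.0),
                         GroupSummary("v", "b", 10, 5.0, 1.0))


def _chisq_bruteforce(observed: np.ndarray) -> float:
    """Independent oracle: explicit expected-count double loop."""
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    stat = 0.0
    for i in range(observed.shape[0]):
        for j in range(observed.shape[1]):
            expected = observed[i].sum() * observed[:, j].sum() / total
            stat += (observed[i, j] - expected) ** 2 / expected
    return stat


class TestChisq:
    def test_homogeneous_table_is_zero(self):
        assert chisq_rxc([[10, 10], [10, 10]]).statistic == pytest.approx(0.0)

    def test_hand_computed_2x2(self):
        result = chisq_rxc([[20, 10], [10, 20]])
        assert result.statistic == pytest.approx(20 / 3, rel=1e-9)
        assert result.df == 1

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            r, c = rng.integers(2, 5, size=2)
            table = rng.integers(1, 60, size=(r, c))
            result = chisq_rxc(table)
            assert result.statistic == pytest.approx(
                _chisq_bruteforce(table), abs=1e-9
            )
            assert result.df == (r - 1) * (c - 1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chisq_rxc([[0, 0], [10, 20]])


class TestSummarizeByGroup:
    def test_small_example(self, table5_dataset):
        ds = table5_dataset
        summaries = summarize_by_group(ds, ["bmi", "age"])
        by_key = {(s.variable, s.group): s for s in summaries}
        assert by_key[("age", "case")].n == 415
        assert by_key[("bmi", "control")].sd is not None

    def test_two_value_groups(self):
        from .conftest import _record

        records = [
            _record("a", "p1", "case", 0, False),
            _record("b", "p1", "control", 0, False),
        ]
        records[0].extras = {}
        ds = StudyDataset(records=records)
        summaries = summarize_by_group(ds, ["weight"])
        by_group = {s.group: s for s in summaries}
        assert by_group["case"].mean == pytest.approx(55.0)
        assert by_group["case"].sd is None  # single observation: flagged

    def test_serialization_roundtrip(self, table5):
        restored = ExposureTable2x4.from_json(table5.to_json())
        assert restored.counts == table5.counts
        text = table5.to_tsv()
        assert "3.333" in text and "1.679~6.617" in text
        assert json.loads(table5.to_json())["cells"]["00"] == [20, 75]
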