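import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from addinter.contingency import ExposureTable2x4, build_exposure_table
from addinter.errors import UndefinedMeasureError, ValidationError
from addinter.interaction import (
    InteractionClass,
    attributable_proportion,
    bootstrap_all,
    bootstrap_ci,
    classify_interaction,
    compute_measures,
    delta_ci,
    measures_from_table,
    pure_attributable_proportion,
    reri,
    synergy_index,
)

from .conftest import REPORTED_OR_TRIPLE, TABLE5_COUNTS, dataset_from_cell_counts

# random OR triples with positive interaction structure (or11 > 1, others > 1)
or_triples = st.tuples(
    st.floats(1.01, 40), st.floats(1.01, 15), st.floats(1.01, 15)
)


class TestPointMeasures:
    def test_reported_triple(self):
        """The study's OR triple yields its headline interaction measures."""
        or11, or10, or01 = REPORTED_OR_TRIPLE
        assert reri(or11, or10, or01) == pytest.approx(5.674, abs=5e-4)
        assert synergy_index(or11, or10, or01) == pytest.approx(1.898, abs=5e-4)
        assert attributable_proportion(or11, or10, or01) == pytest.approx(
            0.4367, abs=5e-5
        )
        assert pure_attributable_proportion(or11, or10, or01) == pytest.approx(
            0.4731, abs=5e-5
        )

    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((1, 1, 1), 0.0),  # no effects, no interaction
            ((6, 4, 3), 0.0),  # exact additivity of excess risks
            ((2, 2, 2), -1.0),  # sub-additive
        ],
    )
    def test_reri_special_cases(self, triple, expected):
        assert reri(*triple) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "triple, expected",
        [((6, 4, 3), 1.0), ((7, 3, 3), 1.5)],
    )
    def test_synergy_special_cases(self, triple, expected):
        assert synergy_index(*triple) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fn, triple, expected",
        [
            (attributable_proportion, (6, 4, 3), 0.0),
            (attributable_proportion, (2, 1, 1), 0.5),
            (pure_attributable_proportion, (6, 4, 3), 0.0),
            (pure_attributable_proportion, (3, 2, 1.5), 0.25),
        ],
    )
    def test_proportion_examples(self, fn, triple, expected):
        assert fn(*triple) == pytest.approx(expected)

    def test_undefined_regions_signalled(self):
        with pytest.raises(UndefinedMeasureError):
            synergy_index(2.0, 0.9, 0.9)  # denominator <= 0
        with pytest.raises(UndefinedMeasureError):
            pure_attributable_proportion(0.8, 2.0, 2.0)  # or11 <= 1
        with pytest.raises(ValidationError):
            reri(-1.0, 2.0, 2.0)

    @given(triple=or_triples)
    @settings(max_examples=300, derandomize=True)
    def test_algebraic_identities(self, triple):
        """RERI = AP*OR11; PAP = RERI/(OR11-1); SI = (OR11-1)/((OR11-1)-RERI);
        PAP = 1 - 1/SI."""
        or11, or10, or01 = triple
        m = compute_measures(or11, or10, or01)
        r = m.reri.estimate
        assert r == pytest.approx(m.ap.estimate * or11, abs=1e-9)
        if or11 > 1:
            assert m.pap.estimate == pytest.approx(r / (or11 - 1), abs=1e-9)
        if (or10 - 1) + (or01 - 1) > 0 and (or11 - 1) - r != 0:
            assert m.si.estimate == pytest.approx(
                (or11 - 1) / ((or11 - 1) - r), rel=1e-9
            )
            assert m.pap.estimate == pytest.approx(
                1 - 1 / m.si.estimate, abs=1e-9
            )

    @given(triple=or_triples)
    @settings(max_examples=100, derandomize=True)
    def test_reri_symmetric_in_single_exposures(self, triple):
        or11, or10, or01 = triple
        assert reri(or11, or10, or01) == pytest.approx(reri(or11, or01, or10))

    @given(or10=st.floats(1.01, 10), or01=st.floats(1.01, 10))
    @settings(max_examples=100, derandomize=True)
    def test_exact_additivity_zeroes_everything(self, or10, or01):
        or11 = or10 + or01 - 1
        m = compute_measures(or11, or10, or01)
        assert m.reri.estimate == pytest.approx(0.0, abs=1e-9)
        assert m.ap.estimate == pytest.approx(0.0, abs=1e-9)
        assert m.pap.estimate == pytest.approx(0.0, abs=1e-9)
        assert m.si.estimate == pytest.approx(1.0, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "triple, expected",
        [
            (REPORTED_OR_TRIPLE, InteractionClass.POSITIVE),
            ((6, 4, 3), InteractionClass.NONE),
            ((2, 2, 2), InteractionClass.NEGATIVE),
        ],
    )
    def test_sign_of_reri_drives_class(self, triple, expected):
        assert compute_measures(*triple).classification() is expected

    def test_scalar_input(self):
        assert classify_interaction(5.674) is InteractionClass.POSITIVE


class TestDeltaCi:
    def test_zero_covariance_collapses_to_point(self):
        b = np.log(REPORTED_OR_TRIPLE)
        low, high = delta_ci("reri", b, np.zeros((3, 3)))
        point = reri(*REPORTED_OR_TRIPLE)
        assert low == pytest.approx(point) and high == pytest.approx(point)
        low, high = delta_ci("si", b, np.zeros((3, 3)))
        assert low == pytest.approx(synergy_index(*REPORTED_OR_TRIPLE))

    def test_covariance_inflation_doubles_half_width(self, table5):
        b = np.log(table5.or_triple())
        cov = table5.log_or_covariance()
        low1, high1 = delta_ci("reri", b, cov)
        low4, high4 = delta_ci("reri", b, 4 * cov)
        assert (high4 - low4) == pytest.approx(2 * (high1 - low1), rel=1e-12)

    def test_si_interval_positive_and_brackets_estimate(self, table5):
        b = np.log(table5.or_triple())
        cov = table5.log_or_covariance()
        low, high = delta_ci("si", b, cov)
        assert 0 < low < synergy_index(*table5.or_triple()) < high

    def test_pap_interval_is_si_transform(self, table5):
        b = np.log(table5.or_triple())
        cov = table5.log_or_covariance()
        si_low, si_high = delta_ci("si", b, cov)
        pap_low, pap_high = delta_ci("pap", b, cov)
        assert pap_low == pytest.approx(1 - 1 / si_low)
        assert pap_high == pytest.approx(1 - 1 / si_high)

    def test_undefined_point_estimate_raises(self):
        b = np.log([1.5, 0.9, 0.9])
        with pytest.raises(UndefinedMeasureError):
            delta_ci("si", b, np.eye(3) * 0.01)

    def test_asymmetric_covariance_rejected(self):
        cov = np.eye(3)
        cov[0, 1] = 0.5
        with pytest.raises(ValidationError):
            delta_ci("reri", np.log(REPORTED_OR_TRIPLE), cov)

    def test_matches_parametric_bootstrap_oracle(self, table5, rng):
        """Delta interval agrees with a 2000-replicate parametric bootstrap
        that draws log ORs from their asymptotic normal law."""
        b = np.log(table5.or_triple())
        cov = table5.log_or_covariance()
        draws = rng.multivariate_normal(b, cov, size=2000)
        ors = np.exp(draws)
        reri_draws = ors[:, 0] - ors[:, 1] - ors[:, 2] + 1
        boot = np.quantile(reri_draws, [0.025, 0.975])
        low, high = delta_ci("reri", b, cov)
        width = high - low
        # Monte-Carlo agreement: endpoints within ~10% of the width
        assert abs(low - boot[0]) < 0.15 * width
        assert abs(high - boot[1]) < 0.15 * width


class TestBootstrapCi:
    def test_fixed_seed_reproducible(self, table5_dataset):
        a = bootstrap_ci(table5_dataset, "reri", n_replicates=200, seed=42)
        b = bootstrap_ci(table5_dataset, "reri", n_replicates=200, seed=42)
        assert a == b

    def test_single_pair_pattern_degenerates_to_point(self):
        """Every pair identical -> every resampled table identical."""
        from addinter.records import StudyDataset

        from .conftest import _record

        records = []
        for i in range(30):
            records.append(_record(f"c{i}", f"p{i}", "case", 1, True))
            records.append(_record(f"k{i}", f"p{i}", "control", 0, False))
        ds = StudyDataset(records=records)
        low, high = bootstrap_ci(
            ds, "reri", n_replicates=200, seed=1, continuity=True
        )
        assert low == high  # degenerate interval at the point estimate

    def test_requires_seed_and_enough_replicates(self, table5_dataset):
        with pytest.raises(ValidationError):
            bootstrap_ci(table5_dataset, "reri", n_replicates=200, seed=None)
        with pytest.raises(ValidationError):
            bootstrap_ci(table5_dataset, "reri", n_replicates=50, seed=1)

    def test_brackets_point_estimate(self, table5_dataset):
        # the bootstrap resamples complete pairs, so compare against the
        # paired-only table's point estimate
        table = build_exposure_table(table5_dataset, paired_only=True)
        point = reri(*table.or_triple())
        low, high = bootstrap_ci(table5_dataset, "reri", n_replicates=500, seed=3)
        assert low < point < high

    def test_all_measures_from_one_resampling(self, table5_dataset):
        cis = bootstrap_all(table5_dataset, n_replicates=300, seed=9)
        assert set(cis) == {"reri", "ap", "pap", "si"}
        for low, high in cis.values():
            assert low < high


class TestMeasuresFromTable:
    def test_full_pipeline_on_study_counts(self, table5):
        m = measures_from_table(table5)
        # the printed counts give OR11 = 13.179, hence RERI 5.86 here
        assert m.reri.estimate == pytest.approx(
            13.179 - 4.986 - 3.333 + 1, abs=5e-3
        )
        assert m.reri.ci_low < m.reri.estimate < m.reri.ci_high
        assert m.reri.method == "delta"
        assert m.classification() is InteractionClass.POSITIVE

    def test_json_round_shape(self, table5):
        doc = measures_from_table(table5).as_dict()
        assert {"or11", "or10", "or01", "reri", "ap", "si", "pap",
                "classification"} <= set(doc)
        assert doc["reri"]["method"] == "delta"
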