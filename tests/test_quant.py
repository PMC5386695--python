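import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from supersilac import (
    QuantMatrix,
    aggregate_technical,
    build_matrix,
    format_fold,
    group_difference,
    median_center,
    min_valid_filter,
    to_log2_sample_ratio,
)
from supersilac.io import ProteinRecord, SampleDesign
from supersilac.quant import bio_design


def _matrix(data, samples, proteins=None):
    proteins = proteins or [f"P{i}" for i in range(len(data))]
    return QuantMatrix(pd.DataFrame(data, index=proteins, columns=samples))


def _design(samples, groups, bios, techs):
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": groups,
                "biological_replicate": bios,
                "technical_replicate": techs,
            }
        )
    )


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "ratio,standard,expected",
        [(1.0, "heavy", 0.0), (2.0, "heavy", -1.0), (0.25, "heavy", 2.0), (2.0, "light", 1.0)],
    )
    def test_sign_convention(self, ratio, standard, expected):
        assert to_log2_sample_ratio(ratio, standard) == pytest.approx(expected)

    def test_nonpositive_ratio_errors(self):
        with pytest.raises(ValueError):
            to_log2_sample_ratio(0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(1e-6, 1e6))
    def test_inverse_round_trip(self, ratio):
        v = to_log2_sample_ratio(ratio, "heavy")
        assert 2.0 ** (-v) == pytest.approx(ratio, rel=1e-9)


class TestAggregateTechnical:
    def test_median_damps_outlier_and_handles_missing(self):
        samples = ["A_b1_t1", "A_b1_t2", "A_b1_t3", "A_b2_t1", "B_b1_t1", "B_b2_t1"]
        design = _design(samples, ["A"] * 4 + ["B"] * 2, [1, 1, 1, 2, 1, 2], [1, 2, 3, 1, 1, 1])
        m = _matrix(
            [
                [1.0, 1.2, 5.0, 0.0, 0.0, 0.0],   # outlier tech rep
                [1.0, np.nan, np.nan, 0.0, 0.0, 0.0],  # observed-only median
                [np.nan, np.nan, np.nan, 0.0, 0.0, 0.0],  # all-missing cell
            ],
            samples,
        )
        agg = aggregate_technical(m, design)
        assert agg.data.loc["P0", "A_b1"] == pytest.approx(1.2)
        assert agg.data.loc["P1", "A_b1"] == pytest.approx(1.0)
        assert np.isnan(agg.data.loc["P2", "A_b1"])

    def test_permutation_invariant_over_tech_reps(self):
        samples = ["A_b1_t1", "A_b1_t2", "A_b1_t3", "A_b2_t1", "B_b1_t1", "B_b2_t1"]
        design = _design(samples, ["A"] * 4 + ["B"] * 2, [1, 1, 1, 2, 1, 2], [1, 2, 3, 1, 1, 1])
        rng = np.random.default_rng(0)
        data = rng.normal(size=(5, 6))
        base = aggregate_technical(_matrix(data, samples), design)
        shuffled = data.copy()
        shuffled[:, [0, 1, 2]] = shuffled[:, [2, 0, 1]]
        design2 = _design(samples, ["A"] * 4 + ["B"] * 2, [1, 1, 1, 2, 1, 2], [3, 1, 2, 1, 1, 1])
        again = aggregate_technical(_matrix(shuffled, samples), design2)
        pd.testing.assert_frame_equal(base.data, again.data)

    def test_unknown_column_errors(self, six_sample_design):
        m = _matrix([[0.0]], ["nope"])
        with pytest.raises(ValueError, match="not present in design"):
            aggregate_technical(m, six_sample_design)


class TestMedianCenter:
    def test_centering_and_idempotence(self):
        m = _matrix([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]], ["s1", "s2"])
        c = median_center(m)
        assert list(c.data["s1"]) == [-1.0, 0.0, 1.0]
        pd.testing.assert_frame_equal(median_center(c).data, c.data)

    def test_mask_respected(self):
        m = _matrix([[1.0, 0.0], [np.nan, 0.0], [3.0, 0.0], [5.0, 0.0]], ["s1", "s2"])
        c = median_center(m)
        assert c.data["s1"].median(skipna=True) == 0.0
        assert np.isnan(c.data.loc["P1", "s1"])

    def test_empty_column_errors(self):
        m = _matrix([[np.nan, 1.0]], ["s1", "s2"])
        with pytest.raises(ValueError, match="no observed"):
            median_center(m)


class TestMinValidFilter:
    samples = ["MM_b1", "MM_b2", "MM_b3", "sPCL_b1", "sPCL_b2", "sPCL_b3"]

    def _bio_design(self):
        return _design(self.samples, ["MM"] * 3 + ["sPCL"] * 3, [1, 2, 3] * 2, [1] * 6)

    def test_scope_semantics(self):
        x = np.nan
        m = _matrix(
            [
                [1, 1, x, 1, 1, 1],  # 2/3 and 3/3 -> kept either scope
                [1, x, x, 1, x, x],  # 1/3 and 1/3 -> dropped
                [1, 1, 1, x, x, x],  # 3/3 and 0/3 -> scope-dependent
            ],
            self.samples,
        )
        d = self._bio_design()
        each = min_valid_filter(m, d, 2, scope="each")
        assert list(each.data.index) == ["P0"]
        any_ = min_valid_filter(m, d, 2, scope="any")
        assert list(any_.data.index) == ["P0", "P2"]

    def test_min_valid_too_large_errors(self):
        m = _matrix([[1.0] * 6], self.samples)
        with pytest.raises(ValueError, match="exceeds"):
            min_valid_filter(m, self._bio_design(), 4)


class TestGroupDifference:
    samples = ["MM_b1", "MM_b2", "MM_b3", "sPCL_b1", "sPCL_b2", "sPCL_b3"]

    def _bio_design(self):
        return _design(self.samples, ["MM"] * 3 + ["sPCL"] * 3, [1, 2, 3] * 2, [1] * 6)

    def test_sign_convention(self):
        m = _matrix([[0, 0, 0, 1, 1, 1], [1, 1, 1, 0, 0, 0]], self.samples)
        diff = group_difference(m, self._bio_design())
        assert diff.loc["P0", "delta"] == pytest.approx(1.0)
        assert diff.loc["P0", "fold_change"] == pytest.approx(2.0)
        # higher in MM -> negative delta
        assert diff.loc["P1", "delta"] == pytest.approx(-1.0)

    def test_fold_change_scale(self):
        # 2**4.406 evaluated independently = 21.2001
        m = _matrix([[0, 0, 0, 4.406, 4.406, 4.406]], self.samples)
        diff = group_difference(m, self._bio_design())
        assert diff.loc["P0", "fold_change"] == pytest.approx(21.2001, rel=1e-4)
        assert format_fold(diff.loc["P0", "delta"]) == "21.2-fold up"
        assert format_fold(-4.406) == "21.2-fold down"

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(10, 6)), self.samples)
        d1 = self._bio_design()
        # same sample->group assignment, groups discovered in opposite order
        from supersilac.io import SampleDesign

        d2 = SampleDesign(d1.frame.iloc[::-1].reset_index(drop=True))
        np.testing.assert_allclose(
            group_difference(m, d1)["delta"], -group_difference(m, d2)["delta"]
        )

    def test_empty_group_flagged_not_fabricated(self):
        x = np.nan
        m = _matrix([[1, 1, 1, x, x, x]], self.samples)
        diff = group_difference(m, self._bio_design())
        assert np.isnan(diff.loc["P0", "delta"])


class TestBuildMatrix:
    def test_heavy_standard_orientation(self, six_sample_design):
        rec = ProteinRecord(
            protein_ids=["P1"], ratio_hl={s: 2.0 for s in six_sample_design.samples}
        )
        m = build_matrix([rec], six_sample_design)
        assert np.allclose(m.data.to_numpy(), -1.0)
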