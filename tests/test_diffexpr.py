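import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from supersilac import (
    DifferentialExpression,
    ImputationParams,
    QuantMatrix,
    call_de,
    exclusive_detection,
    impute_downshift,
    permutation_significance,
    student_t,
    volcano_table,
)
from supersilac.io import SampleDesign


def _bio_design(n_a=3, n_b=3, groups=("MM", "sPCL")):
    rows = []
    for g, n in zip(groups, (n_a, n_b)):
        for b in range(1, n + 1):
            rows.append(
                {"sample_id": f"{g}_b{b}", "group": g,
                 "biological_replicate": b, "technical_replicate": 1}
            )
    return SampleDesign(pd.DataFrame(rows))


def _qm(data, design):
    return QuantMatrix(
        pd.DataFrame(np.asarray(data, dtype=float),
                     index=[f"P{i}" for i in range(len(data))],
                     columns=design.samples)
    )


class TestImputeDownshift:
    def test_no_missing_is_identity(self):
        d = _bio_design()
        m = _qm(np.arange(12.0).reshape(2, 6), d)
        out, mask = impute_downshift(m, seed=0)
        pd.testing.assert_frame_equal(out.data, m.data)
        assert not mask.to_numpy().any()

    def test_moments_of_imputed_values(self):
        # mu=0, sigma=1 matrix with ~10^4 missing cells: draws should have
        # mean -1.5 and SD 0.5 in matrix-SD units
        rng = np.random.default_rng(42)
        values = rng.standard_normal((10000, 6))
        missing = rng.random(values.shape) < 0.2
        values[missing] = np.nan
        d = _bio_design()
        m = QuantMatrix(pd.DataFrame(values, columns=d.samples))
        mu = np.nanmean(values)
        sigma = np.nanstd(values, ddof=1)
        out, mask = impute_downshift(m, ImputationParams(1.5, 0.5), seed=1)
        drawn = out.data.to_numpy()[mask.to_numpy()]
        assert drawn.mean() == pytest.approx(mu - 1.5 * sigma, abs=0.02 * sigma)
        assert drawn.std(ddof=1) == pytest.approx(0.5 * sigma, abs=0.02 * sigma)
        # observed cells untouched
        assert np.array_equal(mask.to_numpy(), missing)
        np.testing.assert_array_equal(out.data.to_numpy()[~missing], values[~missing])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((50, 6))
        values[rng.random(values.shape) < 0.3] = np.nan
        d = _bio_design()
        m = QuantMatrix(pd.DataFrame(values, columns=d.samples))
        a, _ = impute_downshift(m, seed=7)
        b, _ = impute_downshift(m, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_zero_sigma_errors(self):
        d = _bio_design()
        m = _qm(np.ones((3, 6)), d)
        m.data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="standard deviation"):
            impute_downshift(m, seed=0)


class TestStudentT:
    def test_null_identity(self):
        t, p = student_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            student_t([0, 0, 0], [1, 1, 1])

    def test_matches_pooled_variance_formula(self):
        # hand evaluation of the pooled-variance formula, frozen:
        # mean diff 3.0, sp2 = (1.82+1.14)/4 = 0.74, t = 3/sqrt(0.74*2/3)
        t, p = student_t([1.1, 1.9, 3.0], [4.2, 5.1, 5.7])
        assert t == pytest.approx(4.271210980886246, rel=1e-12)
        assert p == pytest.approx(0.012937672902420051, rel=1e-9)


def brute_force_permutation_flags(values, n_a, alpha):
    """Independent oracle: enumerate every label assignment, pool |t|,
    flag proteins whose pooled tail fraction is below alpha."""
    n = values.shape[1]
    obs = np.array(
        [stats.ttest_ind(row[n_a:], row[:n_a], equal_var=True).statistic for row in values]
    )
    null = []
    for combo in itertools.combinations(range(n), n_a):
        rest = [j for j in range(n) if j not in combo]
        for row in values:
            null.append(stats.ttest_ind(row[rest], row[list(combo)], equal_var=True).statistic)
    null = np.abs(np.array(null))
    emp_p = np.array([(null >= abs(t)).mean() for t in obs])
    return emp_p < alpha, emp_p


class TestPermutationSignificance:
    def test_three_vs_three_enumerates_twenty(self):
        d = _bio_design()
        rng = np.random.default_rng(0)
        m = _qm(rng.normal(size=(10, 6)), d)
        res = permutation_significance(m, d, seed=0)
        assert res.exhaustive and res.n_assignments == 20

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, seed):
        d = _bio_design()
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(50, 6))
        # plant one strong, completely separated effect
        values[0, :3] -= 3.0
        values[0, 3:] += 3.0
        m = _qm(values, d)
        res = permutation_significance(m, d, alpha=0.05, seed=seed)
        oracle_sig, oracle_p = brute_force_permutation_flags(values, 3, 0.05)
        np.testing.assert_array_equal(res.sig.to_numpy(), oracle_sig)
        np.testing.assert_allclose(res.empirical_p.to_numpy(), oracle_p, atol=1e-12)
        assert res.sig.iloc[0]  # the planted separation is flagged

    def test_null_flag_rate_near_alpha(self):
        d = _bio_design()
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            m = _qm(rng.normal(size=(300, 6)), d)
            rates.append(permutation_significance(m, d, alpha=0.05, seed=seed).sig.mean())
        rate = np.mean(rates)
        se = np.sqrt(0.05 * 0.95 / (300 * 10))
        assert abs(rate - 0.05) < 3 * se + 0.01  # pooled nulls are protein-correlated

    def test_incomplete_matrix_rejected(self):
        d = _bio_design()
        values = np.random.default_rng(0).normal(size=(5, 6))
        values[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            permutation_significance(_qm(values, d), d, seed=0)


class TestCallDE:
    def _table(self, delta, p):
        return pd.DataFrame({"delta": delta, "p_value": p})

    @pytest.mark.parametrize(
        "delta,p,expected",
        [
            (4.406, 8.13e-5, True),   # strong effect, tiny p
            (0.50, 0.001, False),     # below fold cutoff
            (1.0, 0.20, False),       # fails p
            (0.58, 0.049, True),      # boundary: inclusive fold, strict p
            (0.58, 0.05, False),
        ],
    )
    def test_threshold_semantics(self, delta, p, expected):
        out = call_de(self._table([delta], [p]))
        assert bool(out["sig_p_fc"].iloc[0]) is expected

    def test_monotone_in_cuts(self):
        rng = np.random.default_rng(5)
        t = self._table(rng.normal(scale=1.5, size=200), rng.random(200))
        base = call_de(t, 0.58, 0.05)["sig_p_fc"]
        stricter_fc = call_de(t, 1.0, 0.05)["sig_p_fc"]
        stricter_p = call_de(t, 0.58, 0.01)["sig_p_fc"]
        assert not (stricter_fc & ~base).any()
        assert not (stricter_p & ~base).any()

    def test_fdr_flag_requires_permutation(self):
        t = self._table([2.0, 2.0], [0.001, 0.001])
        perm = pd.Series([True, False], index=t.index)
        out = call_de(t, perm_sig=perm)
        assert list(out["sig_fdr"]) == [True, False]


class TestExclusiveDetection:
    def test_all_vs_none_rule(self):
        d = _bio_design()
        x = np.nan
        m = _qm(
            [
                [x, x, x, 20, 21, 20],   # sPCL-exclusive (SELPLG pattern)
                [20, 20, 20, 20, 21, 20],  # both groups
                [x, 20, 20, x, x, x],     # 2/3 vs 0 -> only under relaxation
            ],
            d,
        )
        strict = exclusive_detection(m, d)
        assert strict["sPCL"] == ["P0"]
        assert strict["MM"] == []
        relaxed = exclusive_detection(m, d, min_present=2)
        assert relaxed["MM"] == ["P2"]
        assert relaxed["sPCL"] == ["P0"]


class TestVolcanoTable:
    def test_log_arithmetic_and_boundary(self):
        t = pd.DataFrame(
            {"delta": [1.0, 0.0], "p_value": [0.01, 1.0],
             "sig_p_fc": [True, False], "sig_fdr": [True, False]}
        )
        v = volcano_table(t)
        assert v["neg_log10_p"].iloc[0] == pytest.approx(2.0)
        assert v["neg_log10_p"].iloc[1] == 0.0
        assert bool(v["sig_p_fc"].iloc[0])

    def test_empty_input(self):
        assert volcano_table(pd.DataFrame()).empty


class TestModelResults:
    def test_fit_reproducible_bit_for_bit(self, small_experiment):
        from supersilac import filter_records, prepare_matrix

        records, design, _, _ = small_experiment
        records, _ = filter_records(records)
        m, bd = prepare_matrix(records, design, scope="any")
        model = DifferentialExpression(m, bd)
        r1 = model.fit(seed=5)
        r2 = model.fit(seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_both_arms_emitted_and_summary(self, small_experiment):
        from supersilac import filter_records, prepare_matrix

        records, design, _, _ = small_experiment
        records, _ = filter_records(records)
        m, bd = prepare_matrix(records, design, scope="any")
        res = DifferentialExpression(m, bd).fit(seed=5)
        for col in ("delta", "fold_change", "t_stat", "p_value", "sig_p_fc",
                    "sig_fdr", "p_value_raw", "sig_p_fc_raw", "n_imputed"):
            assert col in res.table.columns
        assert res.table["sig_fdr"].sum() <= res.table["sig_p_fc"].sum()
        text = res.summary()
        assert "permutation" in text and str(res.n_sig_p_fc) in text

    def test_vacuous_thresholds_flag_everything(self, small_experiment):
        from supersilac import filter_records, prepare_matrix

        records, design, _, _ = small_experiment
        records, _ = filter_records(records)
        m, bd = prepare_matrix(records, design, scope="any")
        res = DifferentialExpression(m, bd, log2_cut=0.0, p_cut=1.0).fit(seed=5)
        tested = res.table["p_value"].notna()
        assert res.table.loc[tested, "sig_p_fc"].all()
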