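"""Statistics battery against brute-force and pingouin oracles."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from dtuemp.stats import (
    icc,
    normality_check,
    partial_correlation,
    rank_inverse_normal,
    spearman,
)


class TestSpearman:
    def test_monotone_pairing_is_one(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 11.0])
        res = spearman(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)
        assert res.label == "strong"

    def test_reversed_is_minus_one(self):
        res = spearman([1, 2, 3], [3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_pearson_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 12).astype(float)  # heavy ties
        y = rng.integers(0, 4, 12).astype(float) + 0.5 * x
        res = spearman(x, y)
        # oracle: rank both with mid-ranks, then plain Pearson
        rho_oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.statistic == pytest.approx(rho_oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman(x, y).statistic
        assert spearman(np.exp(x), y).statistic == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).statistic == pytest.approx(base, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_qualitative_cutoffs(self):
        # moderate band is [0.35, 0.67)
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.normal(size=15), rng.normal(size=15)
            res = spearman(x, y)
            expected = (
                "weak" if abs(res.statistic) < 0.35
                else "moderate" if abs(res.statistic) < 0.67
                else "strong"
            )
            assert res.label == expected


class TestICC:
    def test_identical_methods_give_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        res = icc(x, x.copy())
        assert res.statistic == pytest.approx(1.0)
        assert res.label == "excellent"

    def test_constant_offset_penalised(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc(x, x + 10.0)
        # absolute-agreement form: the offset enters the denominator
        assert res.statistic < 0.5

    def test_matches_pingouin_two_way_random_single(self):
        rng = np.random.default_rng(6)
        a = rng.normal(10, 3, size=10)
        b = a + rng.normal(0, 1, size=10) + 0.5
        res = icc(a, b)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 2),
                "rater": np.tile(["A", "B"], 10),
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        oracle = pg.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        # two-way random effects, absolute agreement, single measures
        row = "ICC(A,1)" if "ICC(A,1)" in oracle.index else "ICC2"
        assert res.statistic == pytest.approx(oracle.loc[row, "ICC"], abs=1e-8)

    def test_matches_anova_mean_squares_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=10)
        b = 0.8 * a + rng.normal(0, 0.3, size=10)
        res = icc(a, b)
        # brute-force two-way ANOVA on the 10x2 table
        data = np.column_stack([a, b])
        n, k = data.shape
        msr = k * np.sum((data.mean(1) - data.mean()) ** 2) / (n - 1)
        msc = n * np.sum((data.mean(0) - data.mean()) ** 2) / (k - 1)
        mse = (
            np.sum((data - data.mean(1)[:, None] - data.mean(0) + data.mean()) ** 2)
            / ((n - 1) * (k - 1))
        )
        oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_zero_subject_variance_rejected(self):
        with pytest.raises(ValueError, match="between-subject"):
            icc([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])


class TestNormalityCheck:
    def test_symmetric_fixture_has_zero_skewness(self):
        values = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 2)
        skew, _, _ = normality_check(values)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_normal_samples_pass(self):
        passes, skews = 0, []
        for seed in range(100):
            v = np.random.default_rng(seed).normal(size=500)
            skew, _, ok = normality_check(v)
            passes += ok
            skews.append(abs(skew))
        assert passes >= 90
        assert np.mean(np.array(skews) < 0.3) >= 0.95

    def test_exponential_samples_fail(self):
        fails = 0
        for seed in range(100):
            v = np.random.default_rng(seed).exponential(size=500)
            _, _, ok = normality_check(v)
            fails += not ok
        assert fails >= 95

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check(np.ones(20))


class TestRankInverseNormal:
    def test_three_point_hand_example(self):
        # Blom quantiles for n=3: (1-3/8)/3.25, (2-3/8)/3.25, (3-3/8)/3.25
        out = rank_inverse_normal([10.0, 20.0, 30.0])
        expected = sps.norm.ppf([0.625 / 3.25, 1.625 / 3.25, 2.625 / 3.25])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, [-0.8694, 0.0, 0.8694], atol=2e-4)

    def test_order_preserved(self):
        rng = np.random.default_rng(8)
        v = rng.exponential(size=50)
        out = rank_inverse_normal(v)
        assert spearman(v, out).statistic == pytest.approx(1.0)

    def test_skew_removed_from_heavy_tailed_input(self):
        rng = np.random.default_rng(9)
        v = rng.lognormal(size=200)
        out = rank_inverse_normal(v)
        assert abs(sps.skew(out, bias=False)) <= 0.15

    def test_ties_share_values(self):
        out = rank_inverse_normal([1.0, 1.0, 2.0, 3.0])
        assert out[0] == out[1]


class TestPartialCorrelation:
    def test_orthogonal_covariates_reduce_to_pearson(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=24)
        y = 0.6 * x + rng.normal(size=24) * 0.5
        x -= x.mean()
        y -= y.mean()
        # build covariates orthogonal to both x and y (and the intercept)
        raw = rng.normal(size=(24, 3))
        basis = np.column_stack([np.ones(24), x, y])
        q, _ = np.linalg.qr(basis)
        cov = raw - q @ (q.T @ raw)
        res = partial_correlation(x, y, cov, transform_nonnormal_y=False)
        pearson = np.corrcoef(x, y)[0, 1]
        assert res.statistic == pytest.approx(pearson, abs=1e-12)

    def test_identical_variables_give_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        cov = rng.normal(size=(20, 3))
        res = partial_correlation(x, x.copy(), cov, transform_nonnormal_y=False)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_matches_two_regression_oracle_and_pingouin(self):
        rng = np.random.default_rng(12)
        n = 20
        cov = np.column_stack(
            [rng.normal(70, 5, n), rng.binomial(1, 0.5, n), rng.normal(25, 3, n)]
        )
        x = 0.1 * cov[:, 0] + rng.normal(size=n)
        y = -0.5 * x + 0.05 * cov[:, 2] + rng.normal(size=n)
        res = partial_correlation(x, y, cov, transform_nonnormal_y=False)
        # oracle 1: explicit double regression residuals
        design = np.column_stack([np.ones(n), cov])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(oracle, abs=1e-10)
        # oracle 2: pingouin
        df = pd.DataFrame(
            {"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1], "c3": cov[:, 2]}
        )
        pg_res = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2", "c3"])
        p_col = "p_val" if "p_val" in pg_res.columns else "p-val"
        assert res.statistic == pytest.approx(pg_res["r"].item(), abs=1e-8)
        assert res.p_value == pytest.approx(pg_res[p_col].item(), abs=1e-8)

    def test_nonnormal_outcome_is_rank_transformed(self):
        rng = np.random.default_rng(13)
        n = 40
        x = rng.normal(size=n)
        y = np.exp(2.5 * x + rng.normal(size=n))  # heavily skewed outcome
        cov = rng.normal(size=(n, 3))
        res = partial_correlation(x, y, cov, transform_nonnormal_y=True)
        manual = partial_correlation(
            x, rank_inverse_normal(y), cov, transform_nonnormal_y=False
        )
        assert res.statistic == pytest.approx(manual.statistic, abs=1e-12)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=20), rng.normal(size=20)
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]), transform_nonnormal_y=False)

    def test_statistic_and_p_in_range(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            x, y = rng.normal(size=15), rng.normal(size=15)
            cov = rng.normal(size=(15, 3))
            res = partial_correlation(x, y, cov, transform_nonnormal_y=False)
            assert -1.0 <= res.statistic <= 1.0
            assert 0.0 <= res.p_value <= 1.0
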