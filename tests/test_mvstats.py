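"""Standardization, correlation screens, CCA, Wilks' lambda, attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazecca import (
    CanonicalCorrelation,
    CohortSimParams,
    DegenerateColumnError,
    InsufficientSampleError,
    InvalidParameterError,
    attribute_percent,
    cca_fit,
    correlation_screen,
    generate_cohort,
    wilks_lambda,
    zscore_normalize,
)


def grid_search_r1(X, Y, n_angles=2000):
    """Brute-force first canonical correlation for p = q = 2: maximize
    corr(Xb, Ya) over a grid of unit vectors parameterized by angle."""
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    Cxx = Xc.T @ Xc
    Cyy = Yc.T @ Yc
    Cxy = Xc.T @ Yc
    th = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    B = np.stack([np.cos(th), np.sin(th)])  # 2 x n
    num = np.abs(B.T @ Cxy @ B)             # n x n: b' Cxy a
    den = np.sqrt(np.einsum("ij,jk,ki->i", B.T, Cxx, B))[:, None] * np.sqrt(
        np.einsum("ij,jk,ki->i", B.T, Cyy, B)
    )[None, :]
    return float((num / den).max())


class TestZScoreNormalize:
    def test_symmetric_three_points(self):
        sm = zscore_normalize(np.array([[1.0], [2.0], [3.0]]), ["v"])
        assert np.allclose(sm.values[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        sm = zscore_normalize(rng.normal(size=(100, 3)))
        again = zscore_normalize(sm.values)
        assert np.allclose(again.values, sm.values, atol=1e-10)

    def test_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        sm = zscore_normalize(rng.normal(5.0, 3.0, size=(60, 4)))
        assert np.allclose(sm.values.mean(0), 0.0, atol=1e-10)
        assert np.allclose(sm.values.std(0, ddof=1), 1.0, atol=1e-10)

    def test_constant_column_names_the_column(self):
        data = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(DegenerateColumnError, match="flat"):
            zscore_normalize(data, ["ok", "flat"])

    def test_back_transformation_metadata_stored(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(7.0, 2.0, size=(50, 2))
        sm = zscore_normalize(raw)
        assert np.allclose(sm.values * sm.column_sds + sm.column_means, raw)


class TestCorrelationScreen:
    def test_self_report_identity_diagonal(self):
        rng = np.random.default_rng(3)
        rep = correlation_screen(rng.normal(size=(80, 4)))
        assert np.allclose(np.diag(rep.r.to_numpy()), 1.0)

    def test_perfectly_correlated_pair(self):
        x = np.arange(50.0)
        rep = correlation_screen(
            np.column_stack([x, 2.0 * x + 1.0 + np.arange(50) * 0.0 + np.random.default_rng(0).normal(0, 1e-9, 50)])
        )
        assert rep.r.iloc[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert rep.p_values.iloc[0, 1] < 1e-12

    def test_monte_carlo_bivariate_correlation(self):
        # corr(x, y) = 0.5 when y = rho*x + sqrt(1-rho^2)*e
        rng = np.random.default_rng(2024)
        n = 10000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        rep = correlation_screen(np.column_stack([x, y]))
        assert rep.r.iloc[0, 1] == pytest.approx(0.5, abs=0.03)

    def test_partial_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(120, 4)), columns=list("abcd"))
        df["b"] += 0.5 * df["a"]
        df["c"] += 0.3 * df["a"]
        rep = correlation_screen(df, kind="partial")
        ref = pingouin.partial_corr(df, x="b", y="c", covar=["a", "d"])
        assert rep.r.loc["b", "c"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert rep.p_values.loc["b", "c"] == pytest.approx(
            float(ref["p_val"].iloc[0]), abs=1e-8
        )

    def test_partial_insufficient_sample_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(InsufficientSampleError):
            correlation_screen(rng.normal(size=(6, 4)), kind="partial")

    def test_cross_screen_shape_and_range(self):
        rng = np.random.default_rng(7)
        rep = correlation_screen(
            rng.normal(size=(100, 10)), rng.normal(size=(100, 4))
        )
        assert rep.r.shape == (10, 4)
        assert (rep.r.abs() <= 1).all().all()
        assert ((rep.p_values >= 0) & (rep.p_values <= 1)).all().all()


class TestCanonicalCorrelation:
    def test_y_equals_x_all_correlations_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        res = cca_fit(X, X.copy())
        assert np.allclose(res.corr, 1.0, atol=1e-8)

    def test_independent_sets_near_zero(self):
        rng = np.random.default_rng(9)
        res = cca_fit(rng.normal(size=(5000, 4)), rng.normal(size=(5000, 3)))
        assert res.corr[0] < 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_first_correlation_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 2))
        Y = 0.6 * X + rng.normal(size=(50, 2))
        res = cca_fit(X, Y)
        oracle = grid_search_r1(X, Y)
        assert res.corr[0] == pytest.approx(oracle, abs=5e-4)

    def test_matches_statsmodels_cancorr(self):
        smc = pytest.importorskip("statsmodels.multivariate.cancorr")
        rng = np.random.default_rng(10)
        X = rng.normal(size=(120, 5))
        Y = X[:, :2] @ rng.normal(size=(2, 3)) + rng.normal(size=(120, 3))
        res = cca_fit(X, Y)
        ref = smc.CanCorr(Y, X).cancorr
        assert np.allclose(res.corr, ref, atol=1e-6)

    def test_score_invariants(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 6))
        Y = X[:, :3] + rng.normal(size=(200, 3))
        res = cca_fit(X, Y)
        m = res.n_pairs
        assert m == 3
        assert np.all(np.diff(res.corr) <= 1e-10)  # descending
        for k in range(m):
            assert res.x_scores[:, k].std(ddof=1) == pytest.approx(1.0, abs=1e-8)
            assert res.y_scores[:, k].std(ddof=1) == pytest.approx(1.0, abs=1e-8)
            r = np.corrcoef(res.x_scores[:, k], res.y_scores[:, k])[0, 1]
            assert r == pytest.approx(res.corr[k], abs=1e-8)
            for j in range(k + 1, m):
                assert np.corrcoef(res.x_scores[:, k], res.x_scores[:, j])[0, 1] == pytest.approx(0.0, abs=1e-6)
        # sign convention: largest-magnitude X-side entry positive
        for k in range(m):
            j = np.argmax(np.abs(res.x_weights[:, k]))
            assert res.x_weights[j, k] > 0

    def test_r1_bounds_cross_correlations(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(300, 5))
        Y = 0.4 * X[:, :2] + rng.normal(size=(300, 2))
        res = cca_fit(X, Y)
        cross = np.corrcoef(np.hstack([X, Y]), rowvar=False)[:5, 5:]
        assert res.corr[0] >= np.abs(cross).max() - 1e-8

    def test_scale_invariance_of_r_and_percentages(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(100, 4))
        Y = 0.5 * X[:, :2] + rng.normal(size=(100, 2))
        res1 = cca_fit(X, Y)
        X2 = X.copy()
        X2[:, 1] *= 1234.5
        Y2 = Y.copy()
        Y2[:, 0] *= -0.002
        res2 = cca_fit(X2, Y2)
        assert np.allclose(res1.corr, res2.corr, atol=1e-8)
        a1, a2 = res1.attribution(), res2.attribution()
        assert np.allclose(a1.x_side_percent, a2.x_side_percent, atol=1e-8)
        assert np.allclose(a1.y_side_percent, a2.y_side_percent, atol=1e-8)

    def test_insufficient_sample_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(InsufficientSampleError):
            cca_fit(rng.normal(size=(10, 8)), rng.normal(size=(10, 4)))

    def test_summary_mentions_dimensions_and_pairs(self):
        rng = np.random.default_rng(15)
        res = cca_fit(rng.normal(size=(60, 3)), rng.normal(size=(60, 2)))
        text = res.summary()
        assert "n = 60, p = 3, q = 2" in text
        assert "Wilks" in text


class TestWilksLambda:
    def test_no_association_gives_one(self):
        lam, chi2, df, p = wilks_lambda(np.zeros(4), n=216, p=10, q=4)
        assert lam == 1.0
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_correlation_gives_zero_and_infinite_statistic(self):
        lam, chi2, df, p = wilks_lambda(np.array([1.0]), n=50, p=1, q=1)
        assert lam == 0.0
        assert np.isinf(chi2)
        assert p == 0.0

    def test_product_formula_on_reported_coefficients(self):
        R = np.array([0.581, 0.344, 0.313, 0.103])
        lam, chi2, df, p = wilks_lambda(R, n=216, p=10, q=4)
        direct = np.prod(1.0 - R**2)
        assert lam == pytest.approx(direct, rel=1e-12)
        assert df == 40

    def test_monotone_in_starting_pair(self):
        R = np.array([0.581, 0.344, 0.313, 0.103])
        lams = [wilks_lambda(R, 216, 10, 4, k)[0] for k in (1, 2, 3, 4)]
        assert np.all(np.diff(lams) >= 0)

    def test_out_of_range_correlations_rejected(self):
        with pytest.raises(InvalidParameterError):
            wilks_lambda(np.array([1.2]), 50, 2, 2)


class TestAttribution:
    def test_three_to_one_weights(self):
        rng = np.random.default_rng(16)
        res = cca_fit(rng.normal(size=(50, 2)), rng.normal(size=(50, 2)))
        res.x_weights[:, 0] = [3.0, 1.0]
        att = res.attribution(pair=1)
        assert np.allclose(att.x_side_percent.to_numpy(), [75.0, 25.0])

    def test_equal_weights_equal_shares(self):
        rng = np.random.default_rng(17)
        res = cca_fit(rng.normal(size=(50, 4)), rng.normal(size=(50, 4)))
        res.y_weights[:, 0] = [1.0, -1.0, 1.0, -1.0]
        att = attribute_percent(res, pair=1)
        assert np.allclose(att.y_side_percent.to_numpy(), 25.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_sides_sum_to_hundred_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 3))
        Y = 0.3 * X[:, :2] + rng.normal(size=(40, 2))
        att = cca_fit(X, Y).attribution()
        assert att.x_side_percent.sum() == pytest.approx(100.0, abs=1e-6)
        assert att.y_side_percent.sum() == pytest.approx(100.0, abs=1e-6)
        assert (att.x_side_percent >= 0).all()

    def test_pair_out_of_range_rejected(self):
        rng = np.random.default_rng(18)
        res = cca_fit(rng.normal(size=(50, 3)), rng.normal(size=(50, 2)))
        with pytest.raises(InvalidParameterError):
            res.attribution(pair=3)

    def test_planted_dominant_variable_has_max_attribution(self):
        params = CohortSimParams(
            n_participants=500,
            planted_weights_x=(0.9, 0.1, 0.2, 0.1, 0.1, 0.1, 0.2, 0.1, 0.1, 0.01),
            noise_sd=0.5,
            seed=2718,
        )
        X, Y, truth = generate_cohort(params)
        att = cca_fit(X, Y).attribution()
        assert att.x_side_percent.idxmax() == "age"
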