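"""Univariable MR estimators against independent closed-form oracles."""

import numpy as np
import pytest

from mrmediate import (
    UnivariableMR,
    cochran_q,
    egger,
    ivw,
    mean_f_statistic,
    steiger_filter,
    wald_ratios,
    weighted_median,
)
from mrmediate.simulate import reverse_causation_dataset

from conftest import make_dataset


def wls_origin_oracle(bx, by, w):
    """Closed-form weighted regression through the origin."""
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sqrt(1.0 / np.sum(w * bx**2))
    return beta, se


def wls_intercept_oracle(bx, by, w):
    """Closed-form weighted regression with intercept (normal equations)."""
    X = np.column_stack([np.ones_like(bx), bx])
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * by))
    cov = np.linalg.inv(XtWX)
    return coef, np.sqrt(np.diag(cov))


class TestWaldRatios:
    def test_arithmetic(self):
        d = make_dataset([0.2], [0.1], se_y=[0.02])
        t = wald_ratios(d)
        assert t.at[0, "ratio"] == pytest.approx(0.5)
        assert t.at[0, "se"] == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        d = make_dataset([0.2], [0.0])
        assert wald_ratios(d).at[0, "ratio"] == 0.0

    def test_matches_elementwise_division(self, fixture20):
        t = wald_ratios(fixture20)
        bx = fixture20.beta_X[:, 0]
        np.testing.assert_allclose(t["ratio"], fixture20.beta_Y / bx, atol=0)
        np.testing.assert_allclose(t["se"], fixture20.se_Y / np.abs(bx), atol=0)

    def test_zero_exposure_beta_excluded(self):
        d = make_dataset([0.2, 0.0, 0.1], [0.1, 0.05, 0.04])
        t = wald_ratios(d)
        assert len(t) == 2
        assert t.attrs["n_excluded_zero_beta_x"] == 1


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        d = make_dataset([0.2], [0.1], se_y=[0.02])
        res = ivw(d, "fe")
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_all_zero_outcome(self):
        d = make_dataset([0.1, 0.2, 0.15], [0.0, 0.0, 0.0])
        assert ivw(d).beta == 0.0

    def test_matches_closed_form_oracle(self, fixture20):
        bx, by = fixture20.beta_X[:, 0], fixture20.beta_Y
        w = 1.0 / fixture20.se_Y**2
        beta_o, se_o = wls_origin_oracle(bx, by, w)
        res_fe = ivw(fixture20, "fe")
        assert res_fe.beta == pytest.approx(beta_o, abs=1e-10)
        assert res_fe.se == pytest.approx(se_o, abs=1e-10)
        res_mre = ivw(fixture20, "mre")
        scale = max(1.0, np.sqrt(res_mre.Q / (len(by) - 1)))
        assert res_mre.se == pytest.approx(se_o * scale, abs=1e-10)

    def test_mre_se_never_below_fe(self, fixture20):
        assert ivw(fixture20, "mre").se >= ivw(fixture20, "fe").se

    def test_order_invariance(self, fixture20):
        perm = np.random.default_rng(0).permutation(fixture20.n_snps)
        res1 = ivw(fixture20)
        res2 = ivw(fixture20.subset(perm))
        assert res1.beta == pytest.approx(res2.beta, abs=1e-12)
        assert res1.Q == pytest.approx(res2.Q, abs=1e-10)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.01 + 0.4 * bx
        res = egger(make_dataset(bx, by))
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.beta == pytest.approx(0.4, abs=1e-12)
        assert res.Q == pytest.approx(0.0, abs=1e-20)

    def test_matches_closed_form_oracle(self, fixture20):
        sign = np.where(fixture20.beta_X[:, 0] >= 0, 1, -1)
        bx = fixture20.beta_X[:, 0] * sign
        by = fixture20.beta_Y * sign
        w = 1.0 / fixture20.se_Y**2
        coef, ses = wls_intercept_oracle(bx, by, w)
        res = egger(fixture20)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.beta == pytest.approx(coef[1], abs=1e-10)
        scale = max(1.0, np.sqrt(res.Q / (fixture20.n_snps - 2)))
        assert res.se == pytest.approx(ses[1] * scale, abs=1e-10)
        assert res.intercept_se == pytest.approx(ses[0] * scale, abs=1e-10)

    def test_zero_intercept_matches_ivw_with_equal_weights(self):
        """Through-origin data, equal weights: Egger slope ~ IVW slope."""
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.2, 30)
        by = 0.4 * bx + rng.normal(0, 0.01, 30)
        d = make_dataset(bx, by, se_y=np.full(30, 0.01))
        res_e, res_i = egger(d), ivw(d, "fe")
        # same weights; slopes differ only through the fitted intercept
        assert res_e.beta == pytest.approx(res_i.beta, abs=3 * res_e.se)

    def test_too_few_instruments(self):
        with pytest.raises(ValueError, match="insufficient"):
            egger(make_dataset([0.1, 0.2], [0.04, 0.08]))


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        d = make_dataset(bx, 0.7 * bx)
        assert weighted_median(d, n_boot=100, seed=1).beta == pytest.approx(0.7)

    def test_interpolation_hits_middle_knot(self):
        # equal weights, ratios {0.1, 0.2, 0.9} -> cumulative midpoints
        # {1/6, 1/2, 5/6}; p = 0.5 lands exactly on the middle ratio
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.02, 0.09])
        d = make_dataset(bx, by, se_y=np.full(3, 0.01))
        assert weighted_median(d, n_boot=100, seed=1).beta == pytest.approx(0.2)

    def test_bootstrap_se_reproducible(self, fixture20):
        a = weighted_median(fixture20, n_boot=200, seed=42)
        b = weighted_median(fixture20, n_boot=200, seed=42)
        assert a.se == b.se


class TestCochranQ:
    def test_identical_ratios_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        d = make_dataset(bx, 0.5 * bx)
        Q, df, p = cochran_q(d)
        assert Q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_two_snp_arithmetic(self):
        # ratios 0 and 1 with unit weights at beta_hat = 0.5 -> Q = 0.5
        d = make_dataset([1.0, 1.0], [0.0, 1.0], se_y=[1.0, 1.0])
        Q, df, _ = cochran_q(d, beta_hat=0.5)
        assert Q == pytest.approx(0.5)
        assert df == 1


class TestMeanF:
    def test_single_snp(self):
        d = make_dataset([0.1], [0.05], se_x=[0.02])
        assert mean_f_statistic(d) == pytest.approx(25.0)

    def test_zero_betas(self):
        d = make_dataset([0.0, 0.0], [0.0, 0.0])
        assert mean_f_statistic(d) == 0.0


class TestSteiger:
    def test_correct_direction_retained(self):
        d = make_dataset([0.1], [0.01], se_x=[0.005], se_y=[0.01])
        res, filtered = steiger_filter(d)
        assert res.direction_correct.all()
        assert filtered.n_snps == 1

    def test_equal_r2_retained(self):
        d = make_dataset([0.1], [0.1], se_x=[0.01], se_y=[0.01])
        res, filtered = steiger_filter(d)
        assert filtered.n_snps == 1  # test cannot reject equality

    def test_reverse_snps_removed(self):
        removed_frac = []
        for seed in range(20):
            data, reverse_ids = reverse_causation_dataset(seed=seed)
            res, filtered = steiger_filter(data)
            kept = set(filtered.snp_ids)
            removed = [s for s in reverse_ids if s not in kept]
            removed_frac.append(len(removed) / len(reverse_ids))
        assert np.mean(removed_frac) >= 0.9

    def test_missing_n_is_error(self):
        d = make_dataset([0.1], [0.05], n_x=2, n_y=2)
        with pytest.raises(ValueError, match="sample size"):
            steiger_filter(d)


class TestModelObject:
    def test_fit_dispatch_and_summary(self, fixture20):
        model = UnivariableMR(fixture20)
        res = model.fit("ivw_mre")
        assert "IVW" in res.summary()
        assert res.ci_low <= res.beta <= res.ci_high
        table = model.fit_all(n_boot=50, seed=0)
        assert set(table["method"]) == {"ivw_fe", "ivw_mre", "egger", "weighted_median"}

    def test_multi_exposure_rejected(self):
        d = make_dataset(np.ones((4, 2)) * 0.1, np.full(4, 0.05))
        with pytest.raises(ValueError, match="single exposure"):
            UnivariableMR(d)

    def test_unknown_method(self, fixture20):
        with pytest.raises(ValueError, match="unknown method"):
            UnivariableMR(fixture20).fit("magic")
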