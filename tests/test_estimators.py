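import numpy as np
import pytest
from scipy import stats

from pqtlmr.estimators import (
    InsufficientInstrumentsError,
    UndefinedEstimateError,
    conmix,
    egger,
    ivw,
    ivw_correlated,
    presso,
    select_primary,
    wald_ratio,
)
from tests.conftest import make_pairs


class TestWaldRatio:
    def test_direct_formula(self):
        est = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_null_outcome(self):
        est = wald_ratio(0.5, 0.05, 0.0, 0.02)
        assert est.theta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_zero_exposure_is_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            wald_ratio(0.0, 0.05, 0.1, 0.02)

    def test_second_order_se_exceeds_first_order(self):
        """The second-order delta SE adds the exposure-noise term."""
        bx, sx, by, sy = 0.5, 0.05, 0.1, 0.02
        first = wald_ratio(bx, sx, by, sy)
        second = wald_ratio(bx, sx, by, sy, second_order=True)
        expected = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        assert second.se == pytest.approx(expected)
        assert second.se > first.se

    def test_odds_ratio_consistency(self):
        est = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.odds_ratio == pytest.approx(np.exp(est.theta))
        lo, hi = est.or_ci
        assert lo == pytest.approx(np.exp(est.ci_low))
        assert hi == pytest.approx(np.exp(est.ci_high))


class TestIVW:
    def test_single_pair_equals_wald(self):
        pairs = make_pairs([0.5], 0.05, [0.1], 0.02)
        est, het = ivw(pairs)
        w = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.theta == pytest.approx(w.theta, abs=1e-12)
        assert est.se == pytest.approx(w.se, abs=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-12)

    def test_exact_proportional_data_zero_heterogeneity(self):
        bx = np.array([0.2, 0.3, 0.4, 0.5])
        pairs = make_pairs(bx, 0.02, 0.3 * bx, [0.01, 0.02, 0.015, 0.03])
        est_f, het_f = ivw(pairs, mode="fixed")
        est_m, het_m = ivw(pairs, mode="mre")
        assert est_f.theta == pytest.approx(0.3, abs=1e-12)
        assert het_f.q == pytest.approx(0.0, abs=1e-12)
        assert het_f.i2 == 0.0
        assert est_m.se == pytest.approx(est_f.se, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        """IVW equals a weighted least-squares fit through the origin."""
        import statsmodels.api as sm
        bx = rng.normal(0.3, 0.1, 5)
        by = 0.25 * bx + rng.normal(0, 0.02, 5)
        sy = rng.uniform(0.01, 0.05, 5)
        pairs = make_pairs(bx, 0.02, by, sy)
        est, _ = ivw(pairs, mode="fixed")
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert est.theta == pytest.approx(fit.params[0], abs=1e-10)

    def test_auto_mode_rule(self):
        three = make_pairs([0.2, 0.3, 0.4], 0.02, [0.1, 0.2, 0.1], 0.02)
        four = make_pairs([0.2, 0.3, 0.4, 0.5], 0.02, [0.1, 0.2, 0.1, 0.2], 0.02)
        assert ivw(three)[0].method == "ivw_fixed"
        assert ivw(four)[0].method == "ivw_mre"

    def test_mre_se_never_below_fixed(self, rng):
        bx = rng.normal(0.3, 0.1, 8)
        by = rng.normal(0, 0.1, 8)
        pairs = make_pairs(bx, 0.02, by, 0.02)
        assert ivw(pairs, mode="mre")[0].se >= ivw(pairs, mode="fixed")[0].se - 1e-15

    def test_scale_equivariance(self, rng):
        bx = rng.normal(0.3, 0.1, 6)
        by = rng.normal(0.1, 0.05, 6)
        sy = rng.uniform(0.01, 0.05, 6)
        base, _ = ivw(make_pairs(bx, 0.02, by, sy), mode="fixed")
        k = 3.7
        exp_scaled, _ = ivw(make_pairs(k * bx, k * 0.02, by, sy), mode="fixed")
        out_scaled, _ = ivw(make_pairs(bx, 0.02, k * by, k * sy), mode="fixed")
        assert exp_scaled.theta == pytest.approx(base.theta / k)
        assert out_scaled.theta == pytest.approx(k * base.theta)

    def test_all_zero_exposure_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            ivw(make_pairs([0.0, 0.0], 0.02, [0.1, 0.2], 0.02))


class TestCorrelatedIVW:
    def test_identity_ld_reduces_to_fixed(self, rng):
        bx = rng.normal(0.3, 0.1, 4)
        by = rng.normal(0.1, 0.05, 4)
        sy = rng.uniform(0.01, 0.05, 4)
        pairs = make_pairs(bx, 0.02, by, sy)
        est = ivw_correlated(pairs, np.eye(4))
        fixed, _ = ivw(pairs, mode="fixed")
        assert est.theta == pytest.approx(fixed.theta, abs=1e-10)
        assert est.se == pytest.approx(fixed.se, abs=1e-10)

    def test_duplicate_instruments_add_no_information(self):
        """Two near-perfectly correlated copies behave like one instrument."""
        single = make_pairs([0.5], 0.05, [0.1], 0.02)
        w = wald_ratio(0.5, 0.05, 0.1, 0.02)
        eps = 1e-6
        dup = make_pairs([0.5, 0.5], 0.05, [0.1, 0.1], 0.02)
        ld = np.array([[1.0, 1 - eps], [1 - eps, 1.0]])
        est = ivw_correlated(dup, ld, ridge=0.0)
        assert est.theta == pytest.approx(w.theta, rel=1e-6)
        assert est.se == pytest.approx(w.se, rel=1e-3)
        del single

    def test_matches_matrix_algebra_oracle(self, rng):
        """GLS estimate equals independently coded explicit-inverse algebra."""
        k = 4
        a = rng.normal(size=(k, k))
        r = a @ a.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        bx = rng.normal(0.3, 0.1, k)
        by = rng.normal(0.1, 0.05, k)
        sy = rng.uniform(0.02, 0.06, k)
        pairs = make_pairs(bx, 0.02, by, sy)
        est = ivw_correlated(pairs, r)
        omega_inv = np.linalg.inv(np.einsum("j,k,jk->jk", sy, sy, r))
        theta = (bx @ omega_inv @ by) / (bx @ omega_inv @ bx)
        se = (bx @ omega_inv @ bx) ** -0.5
        assert est.theta == pytest.approx(theta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
        pairs = make_pairs(bx, 0.02, 0.01 + 0.2 * bx, [0.01, 0.02, 0.015, 0.03, 0.02])
        est, pleio = egger(pairs)
        assert pleio.egger_intercept == pytest.approx(0.01, abs=1e-12)
        assert est.theta == pytest.approx(0.2, abs=1e-12)

    def test_no_pleiotropy_equal_weights_reduces_to_regression(self):
        bx = np.array([0.2, 0.35, 0.5])
        pairs = make_pairs(bx, 0.02, 0.25 * bx, 0.02)
        est, pleio = egger(pairs)
        assert pleio.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert est.theta == pytest.approx(0.25, abs=1e-12)

    def test_orientation_invariance(self, rng):
        """Jointly flipping any pair's allele coding leaves the fit unchanged."""
        bx = rng.normal(0.3, 0.15, 6)
        by = 0.02 + 0.2 * bx + rng.normal(0, 0.01, 6)
        sy = rng.uniform(0.01, 0.03, 6)
        base_est, base_pleio = egger(make_pairs(bx, 0.02, by, sy))
        sign = np.array([1, -1, 1, -1, -1, 1.0])
        flip_est, flip_pleio = egger(make_pairs(bx * sign, 0.02, by * sign, sy))
        assert flip_est.theta == pytest.approx(base_est.theta, abs=1e-12)
        assert flip_pleio.egger_intercept == pytest.approx(base_pleio.egger_intercept, abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_pairs([0.2, 0.3], 0.02, [0.1, 0.2], 0.02))


class TestPresso:
    def pairs_with_outlier(self, rng, shift_sds=10.0):
        bx = rng.normal(0.5, 0.1, 10)
        sy = np.full(10, 0.02)
        by = 0.2 * bx + rng.normal(0, sy)
        by[4] += shift_sds * sy[4]
        return make_pairs(bx, 0.02, by, sy)

    def test_planted_outlier_recovered(self, rng):
        pr = presso(self.pairs_with_outlier(rng), seed=11)
        assert 4 in pr.outliers
        assert pr.p_global <= 0.05
        assert pr.theta_outlier_corrected is not None
        # removing the outlier moves the estimate back toward the truth
        assert abs(pr.theta_outlier_corrected - 0.2) < abs(pr.theta_raw - 0.2)

    def test_deterministic_under_seed(self, rng):
        pairs = self.pairs_with_outlier(rng)
        a = presso(pairs, seed=42)
        b = presso(pairs, seed=42)
        assert a == b

    def test_monte_carlo_resolution(self, rng):
        pr = presso(self.pairs_with_outlier(rng, shift_sds=0.0), n_sim=200, seed=3)
        assert pr.p_global >= 1 / 201

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            presso(make_pairs([0.2, 0.3, 0.4], 0.02, [0.1, 0.2, 0.1], 0.02), seed=0)


class TestConmix:
    def test_homogeneous_instruments(self):
        bx = np.array([0.4, 0.5, 0.6, 0.45])
        pairs = make_pairs(bx, 0.01, 0.3 * bx, 0.004)
        res = conmix(pairs, psi=0.5)
        assert res.estimate.theta == pytest.approx(0.3, abs=0.01)
        assert res.valid == (0, 1, 2, 3)
        assert res.estimate.ci_low <= res.estimate.theta <= res.estimate.ci_high

    def test_two_cluster_profile_is_bimodal(self):
        """Half the instruments at theta=0.3, half at 0: the profile has two
        local maxima and the estimate sits at the likelihood-dominant one."""
        bx = np.full(8, 0.5)
        ratios = np.array([0.3, 0.3, 0.3, 0.3, 0.3, 0.0, 0.0, 0.0])
        pairs = make_pairs(bx, 0.01, ratios * bx, 0.005)
        res = conmix(pairs, psi=0.3)
        assert res.estimate.theta == pytest.approx(0.3, abs=0.02)
        assert set(res.valid) == {0, 1, 2, 3, 4}
        prof = res.profile_loglik
        interior = (prof[1:-1] > prof[:-2]) & (prof[1:-1] > prof[2:])
        grid_maxima = res.theta_grid[1:-1][interior]
        assert any(abs(g - 0.3) < 0.05 for g in grid_maxima)
        assert any(abs(g - 0.0) < 0.05 for g in grid_maxima)

    def test_fine_grid_approaches_wald(self):
        """Two copies of one instrument: the estimate matches the Wald ratio
        as the grid refines."""
        pairs = make_pairs([0.5, 0.5], 0.02, [0.11, 0.11], 0.02)
        w = wald_ratio(0.5, 0.02, 0.11, 0.02)
        res = conmix(pairs, psi=0.5, n_grid=20001)
        assert res.estimate.theta == pytest.approx(w.theta, abs=1e-3)

    def test_config_errors(self):
        pairs = make_pairs([0.5, 0.4], 0.02, [0.1, 0.1], 0.02)
        with pytest.raises(ValueError, match="psi"):
            conmix(pairs, psi=-1.0)
        with pytest.raises(ValueError, match="grid"):
            conmix(pairs, theta_grid=np.array([]))


class TestSelectPrimary:
    def test_dispatch_rule(self):
        one = make_pairs([0.5], 0.05, [0.1], 0.02)
        est, het = select_primary(one)
        assert est.method == "wald" and het is None
        three = make_pairs([0.2, 0.3, 0.4], 0.02, [0.1, 0.2, 0.1], 0.02)
        assert select_primary(three)[0].method == "ivw_fixed"
        four = make_pairs([0.2, 0.3, 0.4, 0.5], 0.02, [0.1, 0.2, 0.1, 0.2], 0.02)
        assert select_primary(four)[0].method == "ivw_mre"

    def test_empty_errors(self):
        with pytest.raises(InsufficientInstrumentsError):
            select_primary(make_pairs([], [], [], []))


def test_pvalues_are_two_sided():
    est = wald_ratio(0.5, 0.05, 0.1, 0.02)
    z = est.theta / est.se
    assert est.pvalue == pytest.approx(2 * stats.norm.sf(abs(z)))
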