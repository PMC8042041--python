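import numpy as np
import pandas as pd
import pytest

from conftest import make_pairs, std_pairs_from
from mrkit import (
    EstimationError,
    ParameterError,
    SimConfig,
    egger,
    imrp,
    ivw,
    pleiotropy_test,
    to_odds_ratio,
    wald_ratio,
)
from oracles import egger_oracle, ivw_oracle


class TestWaldRatio:
    def test_direct_ratio(self):
        est = wald_ratio({"gamma": 0.02, "se_gamma": 0.01, "Gamma": 0.04, "se_Gamma": 0.01})
        assert est.theta == pytest.approx(2.0)

    def test_null_numerator(self):
        est = wald_ratio({"gamma": 0.02, "se_gamma": 0.01, "Gamma": 0.0, "se_Gamma": 0.01})
        assert est.theta == 0.0

    def test_delta_method_limit(self):
        est = wald_ratio({"gamma": -0.02, "se_gamma": 0.0, "Gamma": 0.04, "se_Gamma": 0.01})
        assert est.se == pytest.approx(0.01 / 0.02, rel=1e-12)

    def test_zero_gamma_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio({"gamma": 0.0, "se_gamma": 0.01, "Gamma": 0.1, "se_Gamma": 0.01})


class TestIVW:
    def test_single_instrument_equals_wald(self):
        pairs = make_pairs([0.02], [0.05], 0.01, 0.02)
        assert ivw(pairs).theta == pytest.approx(wald_ratio(pairs.iloc[0]).theta, rel=1e-14)

    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(1)
        g = rng.normal(0, 0.02, 25)
        pairs = make_pairs(g, 0.5 * g, 0.001, 0.01)
        assert ivw(pairs).theta == pytest.approx(0.5, rel=1e-13)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = int(rng.integers(2, 50))
            g = rng.normal(0, 0.02, m)
            sG = rng.uniform(0.005, 0.05, m)
            G = 0.3 * g + rng.normal(0, sG)
            pairs = make_pairs(g, G, 0.001, sG)
            est = ivw(pairs)
            theta_o, se_o = ivw_oracle(g, G, sG)
            assert est.theta == pytest.approx(theta_o, abs=1e-10)
            assert est.se == pytest.approx(se_o, abs=1e-10)

    def test_degenerate_instruments_rejected(self):
        with pytest.raises(EstimationError):
            ivw(make_pairs([0.0, 0.0], [0.1, 0.1], 0.01, 0.01))

    def test_mre_weights_inflate_se_only(self):
        rng = np.random.default_rng(3)
        g = rng.normal(0, 0.05, 40)
        G = 0.3 * g + rng.normal(0, 0.05, 40)  # gross overdispersion
        pairs = make_pairs(g, G, 0.001, 0.01)
        fe, re = ivw(pairs), ivw(pairs, weights="mre")
        assert re.theta == fe.theta
        assert re.se > fe.se


class TestEgger:
    def test_exact_affine_recovery(self):
        rng = np.random.default_rng(4)
        g = np.abs(rng.normal(0, 0.02, 30))
        pairs = make_pairs(g, 0.01 + 0.4 * g, 0.001, 0.01)
        est = egger(pairs)
        assert est.theta == pytest.approx(0.4, rel=1e-10)
        assert est.intercept == pytest.approx(0.01, rel=1e-10)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = int(rng.integers(3, 50))
            g = rng.normal(0, 0.02, m)
            sG = rng.uniform(0.005, 0.05, m)
            G = 0.02 + 0.3 * g + rng.normal(0, sG)
            est = egger(make_pairs(g, G, 0.001, sG))
            slope, slope_se, inter, inter_se = egger_oracle(g, G, sG)
            assert est.theta == pytest.approx(slope, abs=1e-10)
            assert est.se == pytest.approx(slope_se, abs=1e-10)
            assert est.intercept == pytest.approx(inter, abs=1e-10)
            assert est.intercept_se == pytest.approx(inter_se, abs=1e-10)

    def test_balanced_pleiotropy_null_intercept(self):
        rng = np.random.default_rng(6)
        m = 500
        g = np.abs(rng.normal(0, 0.05, m))
        alpha = rng.normal(0, 0.02, m)  # balanced, InSIDE holds
        G = 0.4 * g + alpha + rng.normal(0, 0.01, m)
        est = egger(make_pairs(g, G, 0.001, np.full(m, np.sqrt(0.01**2 + 0.02**2))))
        assert abs(est.intercept) < 3 * est.intercept_se

    def test_directional_pleiotropy_recovered(self):
        rng = np.random.default_rng(7)
        m = 500
        g = np.abs(rng.normal(0, 0.05, m))
        G = 0.03 + 0.4 * g + rng.normal(0, 0.01, m)
        est = egger(make_pairs(g, G, 0.001, 0.01))
        assert abs(est.theta - 0.4) < 3 * est.se
        assert abs(est.intercept - 0.03) < 3 * est.intercept_se

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            egger(make_pairs([0.01, 0.02], [0.01, 0.02], 0.001, 0.01))


def test_sign_equivariance_of_all_estimators():
    std, _ = std_pairs_from(SimConfig(m=40, theta_true=0.3, sigma_gamma=0.05, seed=13))
    flipped_both = std.assign(gamma=-std["gamma"], Gamma=-std["Gamma"])
    flipped_out = std.assign(Gamma=-std["Gamma"])
    for fn in (ivw, egger, lambda d: imrp(d)[0]):
        base = fn(std).theta
        assert fn(flipped_both).theta == pytest.approx(base, rel=1e-10)
        assert fn(flipped_out).theta == pytest.approx(-base, rel=1e-10)


class TestPleiotropyTest:
    def test_zero_residual(self):
        pairs = make_pairs([0.02], [0.01], 0.005, 0.01)
        res = pleiotropy_test(pairs, theta=0.5)
        assert res.loc[0, "t_stat"] == pytest.approx(0.0, abs=1e-15)
        assert res.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_null_effect_reduces_to_outcome_z(self):
        pairs = make_pairs([0.02], [0.03], 0.005, 0.01)
        res = pleiotropy_test(pairs, theta=0.0, rho_overlap=0.0)
        assert res.loc[0, "t_stat"] == pytest.approx(0.03 / 0.01, rel=1e-12)

    def test_bonferroni_implies_nominal(self):
        rng = np.random.default_rng(8)
        m = 200
        g = rng.normal(0, 0.02, m)
        G = 0.3 * g + rng.normal(0, 0.01, m)
        G[:5] += 0.2
        res = pleiotropy_test(make_pairs(g, G, 0.001, 0.01), theta=0.3)
        assert (res["flagged_bonferroni"] <= res["flagged_nominal"]).all()
        assert res["flagged_bonferroni"].sum() >= 5

    def test_type_one_error_near_nominal(self):
        std, truth = std_pairs_from(
            SimConfig(m=4000, theta_true=0.3, sigma_gamma=0.05, seed=14)
        )
        res = pleiotropy_test(std, theta=truth.theta_true)
        rate = res["flagged_nominal"].mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 4000)

    def test_overlap_correction_changes_variance(self):
        pairs = make_pairs([0.02], [0.03], 0.01, 0.01)
        t0 = pleiotropy_test(pairs, theta=0.5, rho_overlap=0.0).loc[0, "t_stat"]
        t1 = pleiotropy_test(pairs, theta=0.5, rho_overlap=0.5).loc[0, "t_stat"]
        assert t0 != t1

    def test_invalid_overlap_rejected(self):
        pairs = make_pairs([0.02], [0.03], 0.01, 0.01)
        with pytest.raises(ParameterError):
            pleiotropy_test(pairs, theta=0.5, rho_overlap=1.5)


class TestIMRP:
    def test_noiseless_data_fixed_point(self):
        std, truth = std_pairs_from(
            SimConfig(m=60, theta_true=0.4, sigma_gamma=0.05, noise_scale=0.0, seed=101)
        )
        est, _ = imrp(std)
        assert est.converged
        assert est.iterations <= 2
        assert est.excluded_snps == []
        assert est.theta == pytest.approx(0.4, rel=1e-10)

    def test_clean_data_only_binomial_false_positives(self, clean_pairs):
        std, truth = clean_pairs
        est, _ = imrp(std)
        assert est.converged
        # no pleiotropy planted: exclusions are the test's 5% false positives
        m = len(std)
        assert len(est.excluded_snps) <= 0.05 * m + 3 * np.sqrt(m * 0.05 * 0.95)
        base = ivw(std)
        assert abs(est.theta - base.theta) < base.se  # well within sampling error
        assert abs(est.theta - truth.theta_true) < 3 * est.se

    def test_planted_outliers_all_excluded(self):
        cfg = SimConfig(
            m=100, theta_true=0.3, sigma_gamma=0.05, pleio_fraction=0.10,
            pleio_mode="directional", pleio_mean=0.096, pleio_sd=1e-4, seed=15,
        )
        std, truth = std_pairs_from(cfg)
        est, _ = imrp(std)
        assert set(truth.invalid_ids) <= set(est.excluded_snps)
        false_pos = set(est.excluded_snps) - set(truth.invalid_ids)
        assert len(false_pos) <= 11  # binomial(90, 0.05) mean + 3 sd
        assert abs(est.theta - truth.theta_true) < 3 * est.se

    def test_alpha_zero_disables_exclusion(self, clean_pairs):
        std, _ = clean_pairs
        est, _ = imrp(std, alpha_pleio=0.0)
        assert est.excluded_snps == []
        assert est.n_snps_used == len(std)
        # matches IVW run with the same overlap-corrected weights
        from mrkit.estimators import pleiotropy_variance

        w = 1.0 / pleiotropy_variance(std["se_gamma"], std["se_Gamma"], est.theta)
        theta_ref = np.sum(w * std["gamma"] * std["Gamma"]) / np.sum(w * std["gamma"] ** 2)
        assert est.theta == pytest.approx(theta_ref, abs=1e-10)

    def test_rerun_from_retained_set_is_stable(self, clean_pairs):
        std, _ = clean_pairs
        est, _ = imrp(std)
        retained = std[~std["snp"].isin(est.excluded_snps)].reset_index(drop=True)
        est2, _ = imrp(retained)
        assert est2.theta == pytest.approx(est.theta, rel=1e-9)

    def test_all_excluded_raises(self, clean_pairs):
        std, _ = clean_pairs
        with pytest.raises(EstimationError):
            imrp(std, alpha_pleio=1.0)


class TestOddsRatio:
    def test_null_effect(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)  # symmetric in log scale

    def test_degenerate_se(self):
        assert to_odds_ratio(np.log(2), 0.0) == pytest.approx((2.0, 2.0, 2.0))

    def test_worked_example(self):
        or_, lo, hi = to_odds_ratio(0.5, 0.1)
        assert or_ == pytest.approx(np.exp(0.5), rel=1e-12)
        assert lo == pytest.approx(np.exp(0.5 - 1.959964 * 0.1), rel=1e-12)
        assert hi == pytest.approx(np.exp(0.5 + 1.959964 * 0.1), rel=1e-12)
        # matches the conventional rounded reporting (1.65, 1.36-2.01)
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (1.65, 1.36, 2.01)

    def test_estimates_carry_consistent_or(self, clean_pairs):
        std, _ = clean_pairs
        for est in (ivw(std), egger(std), imrp(std)[0]):
            assert est.ci_low <= est.odds_ratio <= est.ci_high
            assert est.odds_ratio == pytest.approx(np.exp(est.theta), rel=1e-12)
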