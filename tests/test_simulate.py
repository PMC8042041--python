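import numpy as np
import pandas as pd
import pytest

from conftest import std_pairs_from
from mrkit import ParameterError, SimConfig, ivw, pleiotropy_test, simulate
from mrkit.simulate import (
    back_transform,
    exposure_from_standardized,
    outcome_from_standardized,
)
from mrkit.standardize import standardize_exposure, standardize_outcome


def test_determinism_byte_identical():
    cfg = SimConfig(m=50, theta_true=0.3, pleio_fraction=0.2, k_cohorts=2, seed=21)
    a_exp, a_out, _, a_truth = simulate(cfg)
    b_exp, b_out, _, b_truth = simulate(SimConfig(**vars(cfg)))
    for a, b in zip(a_exp + a_out, b_exp + b_out):
        assert a.df.to_csv() == b.df.to_csv()
    assert a_truth.invalid_ids == b_truth.invalid_ids
    np.testing.assert_array_equal(a_truth.alpha, b_truth.alpha)


def test_invalid_instrument_count_is_rounded_fraction():
    for pf, m in [(0.1, 100), (0.25, 129), (0.0, 50), (1.0, 30)]:
        _, _, _, truth = simulate(SimConfig(m=m, pleio_fraction=pf, seed=1))
        assert len(truth.invalid_ids) == round(pf * m)
        assert np.count_nonzero(truth.alpha) <= round(pf * m)


def test_noiseless_identifiability():
    std, truth = std_pairs_from(SimConfig(m=40, theta_true=0.37, noise_scale=0.0, seed=2))
    assert ivw(std).theta == pytest.approx(0.37, rel=1e-12)


def test_null_effect_uncorrelated_moments():
    cfg = SimConfig(m=10_000, theta_true=0.0, seed=3)
    std, _ = std_pairs_from(cfg)
    r = np.corrcoef(std["gamma"], std["Gamma"])[0, 1]
    assert abs(r) < 3 / np.sqrt(len(std))


def test_overlap_correlates_sampling_errors():
    cfg = SimConfig(m=20_000, theta_true=0.0, rho_overlap=0.8, seed=4)
    exp, out, _, truth = simulate(cfg)
    std, _ = std_pairs_from(cfg)
    g_err = std["gamma"].to_numpy() - truth.gamma_true
    G_err = std["Gamma"].to_numpy() - (truth.theta_true * truth.gamma_true + truth.alpha)
    r = np.corrcoef(g_err, G_err)[0, 1]
    assert r == pytest.approx(0.8, abs=3 / np.sqrt(cfg.m))


class TestBackTransform:
    def test_round_trip_max_error(self):
        rng = np.random.default_rng(5)
        n = 1000
        gamma = rng.normal(0, 0.02, n)
        maf = rng.uniform(0.01, 0.5, n)
        ns = rng.integers(1_000, 1_000_000, n).astype(float)

        beta, se = exposure_from_standardized(gamma, ns, maf=maf)
        g2, sg2 = standardize_exposure(beta, se, ns)
        assert np.max(np.abs(g2 - gamma)) < 1e-12

        Gamma = rng.normal(0, 0.02, n)
        se_G = rng.uniform(1e-4, 1e-2, n)
        betaY, seY = outcome_from_standardized(Gamma, se_G, maf)
        G2, sG2 = standardize_outcome(betaY, seY, maf)
        assert np.max(np.abs(G2 - Gamma)) < 1e-12
        assert np.max(np.abs(sG2 - se_G)) < 1e-12

    def test_zero_preserved(self):
        beta, _ = exposure_from_standardized(0.0, 1000, maf=0.3)
        assert beta == 0.0

    def test_inverse_of_worked_example(self):
        # forward: beta 0.02, se 0.004, n 1e5 -> gamma 0.0158114
        beta, se = exposure_from_standardized(0.0158113883, 100_000, se=0.004)
        assert beta == pytest.approx(0.02, rel=1e-9)
        assert se == 0.004

    def test_dispatcher_roles(self):
        b_out, s_out = back_transform(0.01, 0.002, 0.3, 10_000, role="outcome")
        assert (b_out, s_out) == outcome_from_standardized(0.01, 0.002, 0.3)
        b_exp, _ = back_transform(0.01, None, 0.3, 10_000, role="exposure")
        g, _ = standardize_exposure(*exposure_from_standardized(0.01, 10_000, maf=0.3), 10_000)
        assert g == pytest.approx(0.01, rel=1e-12)
        with pytest.raises(ParameterError):
            back_transform(0.01, 0.002, 0.3, 10_000, role="trait")

    def test_maf_domain(self):
        with pytest.raises(ParameterError):
            outcome_from_standardized(0.1, 0.01, 0.6)


def test_pleiotropy_rejection_power_monotone_in_pleio_sd():
    rates = []
    for sd in (0.005, 0.02, 0.08):
        cfg = SimConfig(m=3000, theta_true=0.3, pleio_fraction=0.5,
                        pleio_sd=sd, sigma_gamma=0.05, seed=6)
        std, truth = std_pairs_from(cfg)
        res = pleiotropy_test(std, theta=truth.theta_true)
        flagged = res.set_index("snp")["flagged_nominal"]
        rates.append(flagged.loc[truth.invalid_ids].mean())
    assert rates[0] < rates[1] < rates[2]
    # at 8x the noise SD most draws are detectable, but alpha ~ N(0, sd^2)
    # always leaves some mass near zero
    assert rates[2] > 0.7


def test_config_validation():
    with pytest.raises(ParameterError):
        SimConfig(pleio_fraction=1.5).validate()
    with pytest.raises(ParameterError):
        SimConfig(maf_range=(0.0, 0.5)).validate()
    with pytest.raises(ParameterError):
        SimConfig(pleio_mode="weird").validate()
    with pytest.raises(ParameterError):
        SimConfig(rho_overlap=1.0).validate()


def test_palindromic_injection_produces_palindromic_alleles():
    exp, _, _, _ = simulate(SimConfig(m=100, palindromic_fraction=0.3, seed=7))
    df = exp[0].df
    pal = ((df["ea"] == "A") & (df["oa"] == "T")) | ((df["ea"] == "T") & (df["oa"] == "A"))
    pal |= ((df["ea"] == "C") & (df["oa"] == "G")) | ((df["ea"] == "G") & (df["oa"] == "C"))
    assert pal.sum() == 30


def test_ld_blocks_emitted():
    _, _, ld, truth = simulate(SimConfig(m=12, ld_blocks=(4, 0.6), seed=8))
    ids = truth.snp_ids
    assert ld.r2(ids[0], ids[1]) == 0.6  # same block
    assert ld.r2(ids[0], ids[4]) == 0.0  # different blocks
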