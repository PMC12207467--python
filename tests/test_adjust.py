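"""Adjustment chain: exact inversion, jackknife pseudovalues, mean shifts."""

import math

import numpy as np
import pytest

from partbias.adjust import (
    RawEstimates,
    adjust_pair,
    adjust_single,
    adjusted_genetic_covariance,
    adjusted_h2,
    adjusted_rg_participation,
    adjusted_rho_e,
    compute_mean_shift,
    jackknife_adjust,
    raw_genetic_covariance,
)
from partbias.forward import (
    ModelParams,
    apparent_h2,
    apparent_rg_participation,
    apparent_rg_two_phenotypes,
    compose_rho,
)
from partbias.trunc import mean_shift_from_rho, selection_constants


def random_params(rng, alpha=None, hx2=None):
    while True:
        try:
            return ModelParams(
                hx2=hx2 if hx2 is not None else rng.uniform(0.02, 0.95),
                hy2=rng.uniform(0.02, 0.95),
                rho_g=rng.uniform(-0.9, 0.9),
                rho_e=rng.uniform(-0.9, 0.9),
                alpha=alpha if alpha is not None else rng.uniform(0.02, 0.99),
            )
        except ValueError:
            continue


def forward_then_adjust(p: ModelParams) -> dict:
    c = selection_constants(p.alpha)
    delta = mean_shift_from_rho(compose_rho(p), c)
    return adjust_single(apparent_h2(p), apparent_rg_participation(p),
                         p.hx2, delta, p.alpha)


class TestChainSteps:
    def test_raw_covariance_fixture(self):
        c = selection_constants(0.055)
        got = raw_genetic_covariance(-0.06616, 0.125, 0.22963, c)
        assert got == pytest.approx(-0.010591, abs=2e-5)

    def test_raw_covariance_trivial(self):
        c = selection_constants(0.3)
        assert raw_genetic_covariance(0.0, 0.2, 0.4, c) == 0.0
        c1 = selection_constants(1.0)
        assert raw_genetic_covariance(0.5, 0.2, 0.4, c1) == pytest.approx(
            0.5 * math.sqrt(0.2 * 0.4))

    def test_adjusted_covariance_fixture(self):
        c = selection_constants(0.055)
        got = adjusted_genetic_covariance(-0.010591, 0.45786, 0.125, c)
        assert got == pytest.approx(0.039529, abs=2e-5)
        c1 = selection_constants(1.0)
        assert adjusted_genetic_covariance(0.3, 0.1, 0.2, c1) == pytest.approx(0.3)

    def test_adjusted_h2_no_selection(self):
        c = selection_constants(1.0)
        assert adjusted_h2(0.37, 0.2, 0.1, 0.3, c) == pytest.approx(0.37)

    def test_perfect_correlation_limit(self):
        assert adjusted_rg_participation(0.4, 0.4, 0.4) == pytest.approx(1.0)

    def test_rho_e_trivial_cases(self):
        assert adjusted_rho_e(0.0, 0.0, 0.2, 0.3) == 0.0
        rho = 0.5 * math.sqrt(0.2 * 0.3)
        assert adjusted_rho_e(rho, 0.5, 0.2, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_domain_errors(self):
        c = selection_constants(0.1)
        with pytest.raises(ValueError):
            raw_genetic_covariance(0.1, 0.0, 0.5, c)
        with pytest.raises(ValueError):
            adjusted_rg_participation(0.1, 0.0, 0.5)
        with pytest.raises(ValueError):
            adjusted_rho_e(0.1, 0.1, 1.0, 0.5)


class TestExactInversion:
    def test_single_phenotype_500_random_systems(self):
        rng = np.random.default_rng(10)
        for _ in range(500):
            p = random_params(rng)
            res = forward_then_adjust(p)
            assert res["hy2_tilde"] == pytest.approx(p.hy2, abs=1e-10)
            assert res["rho_g_tilde"] == pytest.approx(p.rho_g, abs=1e-10)
            assert res["rho_e_tilde"] == pytest.approx(p.rho_e, abs=1e-10)

    def test_simulation_fixture_recovers_truth(self):
        p = ModelParams(hx2=0.125, hy2=0.2, rho_g=0.25, rho_e=0.5, alpha=0.055)
        res = forward_then_adjust(p)
        assert res["hy2_tilde"] == pytest.approx(0.2, abs=1e-12)
        assert res["rho_G_hat"] == pytest.approx(-0.010591, abs=2e-5)
        assert res["rho_G_tilde"] == pytest.approx(p.rho_G, abs=1e-12)

    def test_pair_round_trip(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            alpha = rng.uniform(0.02, 0.99)
            hx2 = rng.uniform(0.05, 0.9)
            p1 = random_params(rng, alpha=alpha, hx2=hx2)
            p2 = random_params(rng, alpha=alpha, hx2=hx2)
            phi = rng.uniform(-0.9, 0.9)
            c = selection_constants(alpha)
            res = adjust_pair(
                apparent_h2(p1), apparent_h2(p2),
                apparent_rg_participation(p1), apparent_rg_participation(p2),
                mean_shift_from_rho(compose_rho(p1), c),
                mean_shift_from_rho(compose_rho(p2), c),
                apparent_rg_two_phenotypes(p1, p2, phi),
                hx2, alpha,
            )
            assert res["phi_g_tilde"] == pytest.approx(phi, abs=1e-10)
            assert res["y1"]["hy2_tilde"] == pytest.approx(p1.hy2, abs=1e-10)
            assert res["y2"]["hy2_tilde"] == pytest.approx(p2.hy2, abs=1e-10)

    def test_pair_fixture(self):
        # unadjusted ~0.458 adjusts back to 0.5 with exact inputs
        kw = dict(hx2=0.125, alpha=0.055, rho_g=0.25, rho_e=0.5)
        p1 = ModelParams(hy2=0.5, **kw)
        p2 = ModelParams(hy2=0.2, **kw)
        c = selection_constants(0.055)
        res = adjust_pair(
            apparent_h2(p1), apparent_h2(p2),
            apparent_rg_participation(p1), apparent_rg_participation(p2),
            mean_shift_from_rho(compose_rho(p1), c),
            mean_shift_from_rho(compose_rho(p2), c),
            apparent_rg_two_phenotypes(p1, p2, 0.5), 0.125, 0.055,
        )
        assert res["phi_g_tilde"] == pytest.approx(0.5, abs=1e-10)


class TestAdjustmentDirection:
    def test_sign_preserved_in_moderate_regime(self):
        rng = np.random.default_rng(12)
        n_checked = 0
        for _ in range(200):
            p = random_params(rng, alpha=0.055, hx2=0.125)
            if abs(p.rho_g) < 0.1 or abs(compose_rho(p)) > 0.6:
                continue
            rg_pb = apparent_rg_participation(p)
            if abs(rg_pb) < abs(rg_pb - p.rho_g):
                continue  # adjustment shift exceeds the estimate itself
            res = forward_then_adjust(p)
            assert np.sign(res["rho_g_tilde"]) == np.sign(rg_pb)
            n_checked += 1
        assert n_checked > 20

    def test_same_sign_shifts_amplify(self):
        # when the apparent rg and the mean shift agree in sign, the adjusted
        # magnitude is at least the apparent one (the empirical
        # underestimation direction)
        rng = np.random.default_rng(13)
        n_checked = 0
        for _ in range(300):
            p = random_params(rng, alpha=0.055, hx2=0.125)
            if not (0.05 < p.rho_g < 0.8 and 0.0 < p.rho_e < 0.8):
                continue
            rg_pb = apparent_rg_participation(p)
            rho = compose_rho(p)
            if rg_pb <= 0 or rho <= 0 or rho > 0.5:
                continue
            res = forward_then_adjust(p)
            assert abs(res["rho_g_tilde"]) >= abs(rg_pb) - 1e-9
            n_checked += 1
        assert n_checked > 10

    def test_out_of_range_flagged_not_clamped(self):
        res = adjust_single(hy2_hat=1.4, rho_g_hat=0.9, hx2_hat=0.5,
                            delta_hat=2.5, alpha=0.02)
        assert res["hy2_tilde"] > 1.0 or "hy2_tilde_out_of_range" not in res["flags"] \
            or res["hy2_tilde"] < 0.0
        if not (0 <= res["hy2_tilde"] <= 1):
            assert "hy2_tilde_out_of_range" in res["flags"]


class TestJackknife:
    def test_identical_blocks_zero_se(self):
        raw = RawEstimates(hy2_hat=0.3, rho_g_hat=0.2, hx2_hat=0.125,
                           delta_hat=0.5, alpha=0.055,
                           jackknife={"hy2_hat": np.full(10, 0.3),
                                      "rho_g_hat": np.full(10, 0.2)})
        adj = jackknife_adjust(raw)
        assert adj.se_hy2_tilde == pytest.approx(0.0, abs=1e-12)
        assert adj.se_rho_g_tilde == pytest.approx(0.0, abs=1e-12)

    def test_identity_chain_reproduces_plain_jackknife(self):
        # the pseudovalue machinery applied at alpha=1 (no-op adjustment)
        # reproduces the textbook jackknife of the raw series
        rng = np.random.default_rng(14)
        loo = 0.3 + 0.02 * rng.standard_normal(10)
        raw = RawEstimates(hy2_hat=0.3, rho_g_hat=0.0, hx2_hat=0.125,
                           delta_hat=0.0, alpha=1.0,
                           jackknife={"hy2_hat": loo})
        adj = jackknife_adjust(raw)
        B = 10
        p = B * 0.3 - (B - 1) * loo
        assert adj.hy2_tilde == pytest.approx(p.mean(), abs=1e-12)
        assert adj.se_hy2_tilde == pytest.approx(
            math.sqrt(p.var(ddof=1) / B), abs=1e-12)

    def test_hand_computed_linear_statistic(self):
        # jackknife of a mean equals its closed-form SE
        x = np.array([1.0, 2.0, 3.0, 4.0])
        B = 4
        full = x.mean()
        loo = np.array([(x.sum() - xi) / 3 for xi in x])
        raw = RawEstimates(hy2_hat=full, rho_g_hat=0.0, hx2_hat=0.125,
                           delta_hat=0.0, alpha=1.0,
                           jackknife={"hy2_hat": loo})
        adj = jackknife_adjust(raw)
        assert adj.hy2_tilde == pytest.approx(full)
        assert adj.se_hy2_tilde == pytest.approx(x.std(ddof=1) / 2, abs=1e-12)

    def test_mismatched_series_error(self):
        raw = RawEstimates(hy2_hat=0.3, rho_g_hat=0.2, hx2_hat=0.125,
                           delta_hat=0.5, alpha=0.055,
                           jackknife={"hy2_hat": np.zeros(10),
                                      "rho_g_hat": np.zeros(7)})
        with pytest.raises(ValueError):
            jackknife_adjust(raw)

    def test_pair_jackknife_runs(self):
        rng = np.random.default_rng(15)
        B = 20
        raw = RawEstimates(
            hy2_hat=0.5, rho_g_hat=0.1, hx2_hat=0.125, delta_hat=0.9,
            alpha=0.055, phi_g_hat=0.45, hy2_hat_2=0.25, rho_g_hat_2=-0.05,
            delta_hat_2=1.0,
            jackknife={"hy2_hat": 0.5 + 0.01 * rng.standard_normal(B),
                       "hy2_hat_2": 0.25 + 0.01 * rng.standard_normal(B),
                       "rho_g_hat": 0.1 + 0.01 * rng.standard_normal(B),
                       "rho_g_hat_2": -0.05 + 0.01 * rng.standard_normal(B),
                       "phi_g_hat": 0.45 + 0.01 * rng.standard_normal(B)})
        adj = jackknife_adjust(raw)
        assert adj.phi_g_tilde is not None
        assert adj.se_phi_g_tilde > 0


class TestMeanShift:
    def test_identical_cohorts_zero(self):
        rng = np.random.default_rng(16)
        y = rng.standard_normal(2000)
        assert compute_mean_shift(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(17)
        n = 1_000_000
        ref = rng.standard_normal(n)
        sam = rng.standard_normal(n) + 0.3
        se = math.sqrt(2 / n)
        assert abs(compute_mean_shift(sam, ref) - 0.3) < 3 * se

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(18)
        sam = rng.standard_normal(3000) + 0.4
        ref = rng.standard_normal(5000)
        d1 = compute_mean_shift(sam, ref, inverse_normal=True)
        d2 = compute_mean_shift(np.exp(sam), np.exp(ref), inverse_normal=True)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_covariate_correction_removes_composition_difference(self):
        # cohorts differ only through a covariate; correcting removes the shift
        rng = np.random.default_rng(19)
        n = 50_000
        cov_s = rng.standard_normal(n) + 1.0   # sample older, say
        cov_r = rng.standard_normal(n)
        sam = 0.5 * cov_s + rng.standard_normal(n)
        ref = 0.5 * cov_r + rng.standard_normal(n)
        raw_shift = compute_mean_shift(sam, ref)
        adj_shift = compute_mean_shift(sam, ref, sample_covariates=cov_s,
                                       reference_covariates=cov_r)
        assert abs(raw_shift) > 0.3
        assert abs(adj_shift) < 0.03

    def test_zero_sd_error(self):
        with pytest.raises(ValueError):
            compute_mean_shift(np.ones(10), np.zeros(10))

    def test_empty_cohort_error(self):
        with pytest.raises(ValueError):
            compute_mean_shift(np.array([]), np.zeros(10))

    def test_stratified_int_preserves_shift(self):
        rng = np.random.default_rng(20)
        n = 20_000
        strata_s = rng.integers(0, 2, n)
        strata_r = rng.integers(0, 2, n)
        sam = rng.standard_normal(n) + 0.3 + 0.5 * strata_s
        ref = rng.standard_normal(n) + 0.5 * strata_r
        d = compute_mean_shift(sam, ref, inverse_normal=True,
                               sample_strata=strata_s, reference_strata=strata_r)
        assert 0.1 < d < 0.5
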