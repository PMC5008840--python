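"""Stern-Volmer and double-log binding fits, mechanism classification."""

import numpy as np
import pytest

from fluorbind import (
    AntiQuenchingWarning,
    InsufficientDataError,
    SternVolmerResult,
    classify_mechanism,
    double_log_fit,
    generate_titration,
    hsa_preset,
    quench_curve,
    stern_volmer_fit,
)
from conftest import CONCENTRATIONS, intensities_on_double_log_line


def sv_result(ksv, temperature, tau0=1e-8):
    return SternVolmerResult(
        ksv=ksv, intercept=1.0, kq=ksv / tau0, tau0=tau0,
        r_corr=1.0, sd=0.0, n_points=8, temperature=temperature,
    )


class TestSternVolmer:
    def test_exact_line_recovers_published_slope(self):
        # F0/F = 1 + 1.5962e5 [D] at the 8 titration concentrations
        ratios = 1.0 + 1.5962e5 * CONCENTRATIONS
        res = stern_volmer_fit(CONCENTRATIONS, ratios, tau0=1e-8)
        assert res.ksv == pytest.approx(1.5962e5, rel=1e-10)
        assert res.kq == pytest.approx(1.5962e13, rel=1e-10)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)
        assert res.r_corr == pytest.approx(1.0)

    def test_no_quenching_gives_zero_slope(self):
        res = stern_volmer_fit(CONCENTRATIONS, np.ones_like(CONCENTRATIONS))
        assert res.ksv == pytest.approx(0.0, abs=1e-12)

    def test_kq_is_ksv_over_tau0_exactly(self):
        ratios = 1.0 + 7.7e4 * CONCENTRATIONS
        res = stern_volmer_fit(CONCENTRATIONS, ratios, tau0=2.5e-9)
        assert res.kq == res.ksv / 2.5e-9

    def test_matches_two_point_closed_form_on_minimal_input(self):
        d = np.array([0.0, 1e-5, 2e-5])
        y = 1.0 + 3e5 * d
        res = stern_volmer_fit(d, y)
        assert res.ksv == pytest.approx((y[-1] - y[0]) / (d[-1] - d[0]))

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            stern_volmer_fit([0.0, 1e-5], [1.0, 2.0])

    def test_negative_slope_warns_but_returns(self):
        ratios = 1.0 - 5e3 * CONCENTRATIONS
        with pytest.warns(AntiQuenchingWarning):
            res = stern_volmer_fit(CONCENTRATIONS, ratios)
        assert res.ksv < 0

    def test_recovers_generator_slope_within_5pct_at_1pct_noise(self):
        truth = hsa_preset(k_true=5e5, n_true=1.0, noise_sd=0.01,
                           inner_filter=False, seed=7)
        series, _, _ = generate_titration(truth)
        conc, f0, f = quench_curve(series)
        res = stern_volmer_fit(conc, f0 / f)
        # with n=1 the generating law is exactly Stern-Volmer with slope k_true
        assert res.ksv == pytest.approx(5e5, rel=0.05)


class TestDoubleLog:
    @pytest.mark.parametrize(
        "intercept, slope, k_expected, n_expected",
        [
            (5.8118, 1.1517, 6.4832e5, 1.15),   # albumin 298 K line
            (4.0638, 0.8897, 1.1582e4, 0.89),   # transferrin 310 K line
            (0.0, 1.0, 1.0, 1.0),               # identity line
        ],
    )
    def test_exact_line_recovery(self, intercept, slope, k_expected, n_expected):
        f = intensities_on_double_log_line(intercept, slope)
        res = double_log_fit(CONCENTRATIONS, 1000.0, f)
        assert res.log_k == pytest.approx(intercept, abs=1e-10)
        assert res.k == pytest.approx(k_expected, rel=5e-5)
        assert round(res.n_sites, 2) == n_expected
        assert res.k == 10.0 ** res.log_k  # exact identity
        assert res.n_points == 7  # zero-concentration point excluded

    def test_points_at_or_above_f0_dropped_with_warning(self):
        f = intensities_on_double_log_line(5.0, 1.0)
        f[1] = 1000.0  # F == F0: lg undefined
        with pytest.warns(UserWarning, match="dropped 1 point"):
            res = double_log_fit(CONCENTRATIONS, 1000.0, f)
        assert res.n_points == 6

    def test_too_few_usable_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            double_log_fit([0.0, 4e-6, 8e-6], 1000.0, [1000.0, 900.0, 1000.0])

    def test_noise_free_synthetic_recovery_to_ten_digits(self):
        truth = hsa_preset(noise_sd=0.0, inner_filter=False)
        series, _, _ = generate_titration(truth)
        conc, f0, f = quench_curve(series)
        res = double_log_fit(conc, f0, f)
        assert res.log_k == pytest.approx(np.log10(truth.k_true), abs=1e-10)
        assert res.n_sites == pytest.approx(truth.n_true, abs=1e-10)

    def test_parameter_recovery_median_under_10pct(self):
        # 100 synthetic titrations, K 1e5-1e6, n 0.9-1.2, 1% noise
        rng = np.random.default_rng(2024)
        rel_errors = []
        for seed in range(100):
            k_true = 10 ** rng.uniform(5, 6)
            n_true = rng.uniform(0.9, 1.2)
            truth = hsa_preset(k_true=k_true, n_true=n_true, noise_sd=0.01,
                               inner_filter=False, seed=seed)
            series, _, _ = generate_titration(truth)
            conc, f0, f = quench_curve(series)
            res = double_log_fit(conc, f0, f)
            rel_errors.append(abs(res.k - k_true) / k_true)
        assert np.median(rel_errors) < 0.10


class TestMechanism:
    def test_published_inputs_give_static(self):
        # K_SV falls 298 -> 310 K and K_q ~ 1e13 >> diffusion limit
        call = classify_mechanism([sv_result(1.5962e5, 298.0), sv_result(1.2165e5, 310.0)])
        assert call.call == "static"
        assert len(call.evidence) == 2

    def test_rising_ksv_with_low_kq_gives_dynamic(self):
        results = [
            sv_result(1.0e4, 298.0, tau0=1e-5),  # kq = 1e9 < limit
            sv_result(1.3e4, 310.0, tau0=1e-5),
        ]
        call = classify_mechanism(results)
        assert call.call == "dynamic"

    def test_conflicting_rules_give_indeterminate(self):
        results = [sv_result(1.0e5, 298.0), sv_result(1.2e5, 310.0)]  # kq ~ 1e13
        call = classify_mechanism(results)
        assert call.call == "indeterminate"
        assert any("dynamic" in e for e in call.evidence)
        assert any("static" in e for e in call.evidence)

    def test_equal_temperatures_rejected(self):
        from fluorbind import ValidationError

        with pytest.raises(ValidationError):
            classify_mechanism([sv_result(1e5, 298.0), sv_result(2e5, 298.0)])
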