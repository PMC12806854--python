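"""Pressure-VFT, activation volumes, Tait EOS and Tg(P) analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdyn.constants import R
from pepdyn.pressure import (
    PressureVFTModel,
    TgPressureModel,
    activation_volume,
    delta_eps_normalized,
    tait_density,
    tait_volume,
)

LN10 = np.log(10.0)


def _pvft(P, log10_f_inf, D_P, P0):
    return 10.0**log10_f_inf * np.exp(-D_P * P / (P0 - P))


class TestPressureVFT:
    def test_noiseless_recovery(self):
        P = np.arange(0.0, 301.0, 30.0)
        f = _pvft(P, 5.0, 2.0, 1000.0)
        fit = PressureVFTModel(f, P, T_K=330.0).fit()
        assert fit.converged
        assert fit.log10_f_inf == pytest.approx(5.0, abs=1e-5)
        assert fit.D_P == pytest.approx(2.0, rel=1e-4)
        assert fit.P0 == pytest.approx(1000.0, rel=1e-4)

    def test_arrhenius_fallback_slope(self):
        """Log-linear f(P): fallback recovers the slope to 4 digits."""
        P = np.arange(0.0, 301.0, 50.0)
        slope = 2.0e-3  # decades of tau per MPa
        f = 10.0 ** (4.0 - slope * P)
        fit = PressureVFTModel(f, P, T_K=300.0, form="arrhenius").fit()
        assert fit.slope == pytest.approx(slope, rel=1e-4)

    def test_noisy_P0_median_bias(self):
        """20 noisy replicates at ~1% frequency scatter (the typical
        precision of loss-peak frequencies from spectral fits): median P0
        bias below 10%."""
        P = np.arange(0.0, 301.0, 25.0)
        f0 = _pvft(P, 5.0, 2.0, 1000.0)
        est = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = f0 * 10.0 ** (0.005 * rng.standard_normal(len(P)))
            est.append(PressureVFTModel(f, P, T_K=330.0).fit().P0)
        assert abs(np.median(est) / 1000.0 - 1.0) < 0.10


class TestActivationVolume:
    def test_arrhenius_slope_unit_arithmetic(self):
        """slope 2e-3 decades/MPa at 300 K: 2.303*R*300*2e-3 J/mol/MPa
        = 11.49 cm^3/mol."""
        dv = activation_volume(2.0e-3, T_K=300.0)
        assert dv == pytest.approx(LN10 * R * 300.0 * 2.0e-3, rel=1e-12)
        assert dv == pytest.approx(11.49, abs=0.01)

    def test_closed_form_vs_finite_difference(self):
        """Pressure-VFT closed form agrees with the central-difference
        derivative of log10 tau(P) to better than 0.1% at several P."""
        P = np.arange(0.0, 301.0, 30.0)
        f = _pvft(P, 5.0, 2.0, 1000.0)
        fit = PressureVFTModel(f, P, T_K=330.0).fit()
        h = 0.01
        for p in (0.0, 100.0, 250.0):
            logtau = lambda pp: -np.log10(fit.predict(np.array([pp]))[0])
            num = LN10 * R * 330.0 * (logtau(p + h) - logtau(p - h)) / (2 * h)
            assert fit.activation_volume(p) == pytest.approx(num, rel=1e-3)

    def test_zero_pressure_limit(self):
        """dV#(P->0) = R*T*D_P/P0 exactly for the pressure-VFT form."""
        P = np.arange(0.0, 301.0, 30.0)
        fit = PressureVFTModel(_pvft(P, 5.0, 2.0, 1000.0), P, T_K=330.0).fit()
        assert fit.activation_volume(0.0) == pytest.approx(
            R * 330.0 * 2.0 / 1000.0, rel=1e-4
        )


class TestTait:
    def test_zero_pressure_identity(self):
        for t in (30.0, 70.0, 150.0):
            v0 = 0.788 + 4.92e-4 * t + 7.57e-7 * t**2
            assert float(tait_volume(t, 0.0)) == pytest.approx(v0, rel=1e-12)

    def test_printed_constants_at_70C(self):
        """Direct evaluation of the EOS polynomial at 70 degC, P = 0."""
        assert float(tait_volume(70.0, 0.0)) == pytest.approx(0.8262, abs=2e-4)
        assert float(tait_density(70.0, 0.0)) == pytest.approx(1.210, abs=1e-3)

    @given(t=st.floats(20.0, 200.0), p1=st.floats(0.0, 400.0), p2=st.floats(0.0, 400.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_decreasing_in_P(self, t, p1, p2):
        if abs(p1 - p2) < 1e-9:
            return
        plo, phi = sorted((p1, p2))
        assert float(tait_volume(t, phi)) < float(tait_volume(t, plo))

    @given(t=st.floats(20.0, 200.0), p=st.floats(0.0, 400.0))
    @settings(max_examples=30, deadline=None)
    def test_compression_bound(self, t, p):
        """0 <= 1 - V(P)/V(0) = 0.0894*ln(1+P/B(T)) exactly."""
        comp = 1.0 - float(tait_volume(t, p)) / float(tait_volume(t, 0.0))
        bound = 0.0894 * np.log(1.0 + p / (142.0 * np.exp(-4.3e-3 * t)))
        assert comp == pytest.approx(bound, abs=1e-12)
        assert comp >= 0.0


class TestTgPressure:
    def _tg(self, P, tg0=283.0, nu=3.1, mu=1210.0):
        return tg0 * (1.0 + (nu / mu) * P) ** (1.0 / nu)

    def test_noiseless_recovery_and_slope(self):
        P = np.arange(0.0, 351.0, 35.0)
        fit = TgPressureModel(self._tg(P), P).fit()
        assert fit.Tg0 == pytest.approx(283.0, abs=0.1)
        assert fit.nu == pytest.approx(3.1, rel=1e-3)
        assert fit.mu_MPa == pytest.approx(1210.0, rel=1e-3)
        assert fit.dTgdP0_K_per_GPa == pytest.approx(1000.0 * 283.0 / 1210.0, rel=1e-3)
        assert fit.dTgdP0_K_per_GPa == pytest.approx(234.0, abs=1.0)

    def test_initial_slope_is_analytic_derivative(self):
        """dTg/dP at P=0 equals Tg0/mu for any fitted parameter set."""
        P = np.arange(0.0, 351.0, 35.0)
        fit = TgPressureModel(self._tg(P, 300.0, 2.2, 1910.0), P).fit()
        h = 1e-4
        num = (fit.predict(np.array([h]))[0] - fit.predict(np.array([0.0]))[0]) / h
        assert num * 1000.0 == pytest.approx(fit.dTgdP0_K_per_GPa, rel=1e-4)

    def test_tabulated_consistency_alpha_star(self):
        """mu = 1910 MPa with an initial slope of 158 K/GPa implies
        Tg0 = 301.8 K, close to the 301 K ambient alpha* Tg of the n-hexyl
        heptamer."""
        tg0 = 158.0 * 1910.0 / 1000.0
        assert tg0 == pytest.approx(301.8, abs=0.1)
        assert abs(tg0 - 301.0) < 2.0

    def test_recovery_monte_carlo(self):
        """20 noisy synthetic sets: median Tg0 within 1 K, initial slope
        within 5%."""
        P = np.arange(0.0, 351.0, 25.0)
        tg_true = self._tg(P)
        tg0s, slopes = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fit = TgPressureModel(tg_true + 0.5 * rng.standard_normal(len(P)), P).fit()
            tg0s.append(fit.Tg0)
            slopes.append(fit.dTgdP0_K_per_GPa)
        assert abs(np.median(tg0s) - 283.0) < 1.0
        assert abs(np.median(slopes) / (1000.0 * 283.0 / 1210.0) - 1.0) < 0.05


class TestDeltaEpsNormalized:
    def test_constant_strength_monotone_decreasing(self):
        P = np.arange(0.0, 301.0, 20.0)
        out = delta_eps_normalized(np.full(len(P), 5.0), P, T_K=343.0)
        assert np.all(np.diff(out["delta_eps_over_rho"]) < 0)
        assert out["turnover_MPa"] is None

    def test_threshold_detector_near_120(self):
        """A hump peaking near 120 MPa is reported at ~120 MPa."""
        P = np.arange(0.0, 301.0, 10.0)
        rho = tait_density(343.0 - 273.15, P)
        target = 5.0 * (1.0 + 0.3 * np.exp(-((P - 120.0) / 80.0) ** 2))
        out = delta_eps_normalized(target * rho, P, T_K=343.0)
        assert out["turnover_MPa"] == pytest.approx(120.0, abs=20.0)

    def test_zero_strength_gives_zeros(self):
        P = np.arange(0.0, 301.0, 50.0)
        out = delta_eps_normalized(np.zeros(len(P)), P, T_K=343.0)
        np.testing.assert_allclose(out["delta_eps_over_rho"], 0.0)
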