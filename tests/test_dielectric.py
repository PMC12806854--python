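"""Havriliak–Negami evaluation, loss-peak closed form, and spectrum fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdyn.constants import EPS0
from pepdyn.dielectric import (
    HavriliakNegamiModel,
    HNProcess,
    derivative_loss,
    hn_eval,
    hn_loss_real,
    tau_max,
)
from pepdyn.series import MeasurementSeries
from pepdyn.synthetic import DielectricScenario, ProcessSpec, gen_dielectric


class TestHNEval:
    def test_debye_at_peak(self):
        """m = n = 1, omega*tau = 1: eps' - eps_inf = eps'' = delta_eps/2."""
        p = HNProcess(delta_eps=2.0, tau_hn=1.0, m=1.0, n=1.0)
        e = hn_eval(np.array([1.0]), p, eps_inf=3.0)
        assert e.real[0] - 3.0 == pytest.approx(1.0, abs=1e-12)
        assert e.imag[0] == pytest.approx(1.0, abs=1e-12)

    def test_cole_cole_half_at_peak(self):
        """m=0.5, n=1 at omega*tau=1: direct complex arithmetic gives
        (eps'-eps_inf, eps'') = (0.5, 0.2071) * delta_eps."""
        p = HNProcess(delta_eps=1.0, tau_hn=1.0, m=0.5, n=1.0)
        e = hn_eval(np.array([1.0]), p)
        # oracle: 1/(1 + i^0.5) evaluated directly
        oracle = 1.0 / (1.0 + 1j**0.5)
        assert e.real[0] == pytest.approx(oracle.real, abs=1e-12)
        assert e.imag[0] == pytest.approx(-oracle.imag, abs=1e-12)
        assert e.imag[0] == pytest.approx(0.2071, abs=1e-4)

    def test_conductivity_only(self):
        omega = np.logspace(-1, 3, 20)
        e = hn_eval(omega, [], eps_inf=2.0, sigma0=1e-10)
        np.testing.assert_allclose(e.imag, 1e-10 / (EPS0 * omega), rtol=1e-12)
        # slope of log eps'' vs log omega is exactly -1
        slope = np.diff(np.log10(e.imag)) / np.diff(np.log10(omega))
        np.testing.assert_allclose(slope, -1.0, atol=1e-12)

    def test_shape_bounds_rejected_before_evaluation(self):
        with pytest.raises(ValueError):
            HNProcess(delta_eps=1.0, tau_hn=1.0, m=0.15, n=1.0)
        with pytest.raises(ValueError):
            HNProcess(delta_eps=1.0, tau_hn=1.0, m=0.9, n=1.3)

    @given(m=st.floats(0.25, 1.0), lt=st.floats(-6, 2))
    @settings(max_examples=25, deadline=None)
    def test_cole_cole_symmetry(self, m, lt):
        """n = 1 loss is symmetric in log(omega) about omega = 1/tau."""
        tau = 10.0**lt
        p = HNProcess(delta_eps=1.0, tau_hn=tau, m=m, n=1.0)
        d = np.logspace(-2, 2, 9)
        _, up = hn_loss_real(d / tau, p)
        _, dn = hn_loss_real(1.0 / (d * tau), p)
        np.testing.assert_allclose(up, dn, rtol=1e-10)


class TestTauMax:
    def test_symmetric_case_identity(self):
        for m in (0.3, 0.6, 1.0):
            p = HNProcess(1.0, 2.5, m, 1.0)
            assert tau_max(p) == pytest.approx(2.5, rel=1e-12)

    def test_m1_n_half(self):
        """m=1, n=0.5, tau_hn=1: sin(pi/6)/sin(pi/3) = 0.5774 s, agreeing
        with grid maximization of the loss to 4 digits."""
        p = HNProcess(1.0, 1.0, 1.0, 0.5)
        assert tau_max(p) == pytest.approx(0.57735, rel=1e-4)
        omega = np.logspace(-3, 3, 200001)
        _, eps2 = hn_loss_real(omega, p)
        tau_grid = 1.0 / omega[np.argmax(eps2)]
        assert tau_max(p) == pytest.approx(tau_grid, rel=1e-4)

    def test_formula_vs_brute_force_20_draws(self):
        """Closed form within 0.5% of dense-grid loss maximization for random
        shapes inside the admissible region."""
        rng = np.random.default_rng(42)
        omega = np.logspace(-4, 4, 100001)
        for _ in range(20):
            m = rng.uniform(0.25, 1.0)
            n = rng.uniform(0.1, 1.0 / m)
            p = HNProcess(1.0, 1.0, m, n)
            _, eps2 = hn_loss_real(omega, p)
            tau_grid = 1.0 / omega[np.argmax(eps2)]
            assert tau_max(p) == pytest.approx(tau_grid, rel=5e-3)

    @given(m=st.floats(0.25, 1.0), n1=st.floats(0.1, 0.95), n2=st.floats(0.1, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_asymmetric_broadening_speeds_up_peak(self, m, n1, n2):
        """Stronger asymmetric broadening (smaller n) shifts the loss peak to
        higher frequency, so tau_max grows monotonically with n toward the
        symmetric limit tau_max = tau_hn at n = 1 (direction pinned by the
        brute-force maximization test above)."""
        n1, n2 = sorted((min(n1, 1 / m - 1e-9), min(n2, 1 / m - 1e-9)))
        if n2 - n1 < 1e-6:
            return
        t1 = tau_max(HNProcess(1.0, 1.0, m, n1))
        t2 = tau_max(HNProcess(1.0, 1.0, m, n2))
        assert t2 > t1
        assert t2 <= 1.0 + 1e-9


class TestDerivativeLoss:
    def _series(self, omega, eps1, eps2):
        return MeasurementSeries(
            x=omega / (2 * np.pi), y=eps1 + 1j * eps2, technique="dielectric",
            meta={"temperature_K": 300.0},
        )

    def test_broad_cole_cole_peak_position(self):
        p = HNProcess(1.0, 1.0, 0.3, 1.0)
        omega = np.logspace(-5, 5, 101)
        e1, e2 = hn_loss_real(omega, p, eps_inf=3.0)
        d = derivative_loss(self._series(omega, e1, e2))
        step = np.diff(np.log10(omega))[0]
        w_true = omega[np.argmax(e2)]
        w_deriv = omega[np.argmax(d.y)]
        assert abs(np.log10(w_deriv / w_true)) <= step + 1e-9

    def test_debye_height_pi_over_4(self):
        """For a Debye peak the derivative loss peaks at (pi/4)*delta_eps:
        d eps'/d ln w = -d_eps (w tau)^2... evaluated closed-form at w tau=1."""
        p = HNProcess(2.0, 1.0, 1.0, 1.0)
        omega = np.logspace(-4, 4, 161)
        e1, e2 = hn_loss_real(omega, p, eps_inf=3.0)
        d = derivative_loss(self._series(omega, e1, e2))
        # closed form: deps'/dlnw = -2 d_eps (wt)^2 / (1+(wt)^2)^2 -> max pi/4*d_eps
        assert d.y.max() == pytest.approx(np.pi / 4 * 2.0, rel=2e-2)
        assert d.y.max() > 2.0 / 2  # larger than delta_eps/2

    def test_constant_eps1_gives_zero(self):
        omega = np.logspace(0, 3, 31)
        d = derivative_loss(self._series(omega, np.full(31, 5.0), np.ones(31)))
        np.testing.assert_allclose(d.y, 0.0, atol=1e-12)

    def test_short_grid_rejected(self):
        omega = np.logspace(0, 1, 5)
        with pytest.raises(ValueError, match="7"):
            derivative_loss(self._series(omega, np.ones(5), np.ones(5)))


class TestSpectrumFit:
    def _two_process(self, noise=0.0, seed=0):
        sc = DielectricScenario(
            processes=[
                ProcessSpec("alpha", 2.0, -12, 1250, 238, m=0.85, n=0.7),
                ProcessSpec("alpha*", 4.0, -12, 1760, 245, m=0.75, n=0.6),
            ],
            T_grid_K=(330.0,),
            noise=noise,
            seed=seed,
            sigma0_S_m=1e-12,
        )
        return gen_dielectric(sc)[0]

    def test_zero_noise_recovery_within_1pct(self):
        s = self._two_process()
        truth = s.meta["truth"]["processes"]
        fit = HavriliakNegamiModel(s, n_processes=2).fit()
        assert fit.converged
        for p, t in zip(fit.processes, truth):
            assert tau_max(p) == pytest.approx(t["tau_max_s"], rel=0.01)
            assert p.delta_eps == pytest.approx(t["delta_eps"], rel=0.01)
            assert p.m == pytest.approx(t["m"], rel=0.01)
        assert fit.eps_inf == pytest.approx(3.0, rel=0.01)
        assert fit.sigma0 == pytest.approx(s.meta["truth"]["sigma0_S_m"], rel=0.01)

    def test_static_limit_invariant(self):
        """Sum of delta_eps + eps_inf reproduces the conduction-free eps'(0)."""
        s = self._two_process()
        fit = HavriliakNegamiModel(s, n_processes=2).fit()
        static = fit.eps_inf + sum(p.delta_eps for p in fit.processes)
        assert static == pytest.approx(3.0 + 2.0 + 4.0, rel=0.01)

    def test_noisy_tau_median_bias(self):
        """2% multiplicative noise, 20 seeds: median tau_max bias < 5%."""
        ratios = {"alpha": [], "alpha*": []}
        for seed in range(20):
            s = self._two_process(noise=0.02, seed=seed)
            truth = {t["name"]: t for t in s.meta["truth"]["processes"]}
            fit = HavriliakNegamiModel(s, n_processes=2).fit()
            for p in fit.processes:
                ratios[p.name].append(tau_max(p) / truth[p.name]["tau_max_s"])
        for name, r in ratios.items():
            assert abs(np.median(r) - 1.0) < 0.05, name

    def test_overparameterized_fit_flagged(self):
        """Fitting 2 processes to 1-process data collapses one strength or is
        flagged degenerate."""
        sc = DielectricScenario(
            processes=[ProcessSpec("alpha", 2.0, -12, 1250, 238, m=0.85, n=0.7)],
            T_grid_K=(330.0,),
            sigma0_S_m=0.0,
        )
        sc2 = DielectricScenario(processes=sc.processes, T_grid_K=(330.0,),
                                 sigma0_S_m=1e-30)
        s = gen_dielectric(sc2)[0]
        fit = HavriliakNegamiModel(s, n_processes=2, fit_conductivity=False).fit()
        min_de = min(p.delta_eps for p in fit.processes)
        total = sum(p.delta_eps for p in fit.processes)
        assert fit.degenerate or min_de < 1e-3 * total or min_de < 1e-3

    def test_derivative_objective_also_recovers(self):
        s = self._two_process()
        truth = s.meta["truth"]["processes"]
        fit = HavriliakNegamiModel(s, n_processes=2, objective="derivative").fit()
        for p, t in zip(fit.processes, truth):
            assert tau_max(p) == pytest.approx(t["tau_max_s"], rel=0.05)
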