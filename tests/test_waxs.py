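"""WAXS peak fitting, lattice geometry, fractions and chain-length laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdyn.synthetic import WAXSScenario, gen_waxs, preset
from pepdyn.thermal import ComponentFit
from pepdyn.waxs import (
    PeakAssignment,
    SigmoidModel,
    WAXSPatternModel,
    fractions_from_intensities,
    peak_geometry,
    sigmoid_fraction,
)


def _peak(q0, fwhm, role):
    return PeakAssignment(
        component=ComponentFit(center=q0, fwhm=fwhm, area=1.0, shape="pseudo-voigt"),
        role=role,
    )


class TestGeometry:
    def test_helical_pitch_from_q(self):
        """q = 12.6 nm^-1 corresponds to the 0.5 nm helical pitch."""
        geo = peak_geometry(_peak(12.6, 0.3, "pitch"))
        assert geo["d_nm"] == pytest.approx(0.499, abs=0.001)

    def test_hexagonal_intercylinder_distance(self):
        """q = 4.7 nm^-1 gives a = 4*pi/(sqrt(3)*q) = 1.544 nm."""
        geo = peak_geometry(_peak(4.7, 0.3, "hex10"))
        assert geo["a_hex_nm"] == pytest.approx(1.544, abs=0.001)

    def test_beta_spacings(self):
        assert peak_geometry(_peak(3.7, 0.3, "beta_lamellar"))["d_nm"] == pytest.approx(
            1.70, abs=0.01
        )
        assert peak_geometry(_peak(13.4, 0.3, "beta_interstrand"))[
            "d_nm"
        ] == pytest.approx(0.469, abs=0.001)

    def test_coherence_length_unit_case(self):
        geo = peak_geometry(_peak(4.7, 2.0 * np.pi, "hex10"))
        assert geo["L_nm"] == pytest.approx(1.0, rel=1e-12)

    @given(q0=st.floats(3.0, 15.0), w=st.floats(0.05, 2.0))
    @settings(max_examples=40, deadline=None)
    def test_closed_forms_exact(self, q0, w):
        geo = peak_geometry(_peak(q0, w, "hex10"))
        assert geo["d_nm"] == pytest.approx(2 * np.pi / q0, rel=1e-12)
        assert geo["L_nm"] == pytest.approx(2 * np.pi / w, rel=1e-12)
        assert geo["a_hex_nm"] == pytest.approx(geo["d_nm"] * 2 / np.sqrt(3), rel=1e-12)


class TestPatternFit:
    def test_hexagonal_family_located(self):
        """Hexagonal scenario: peaks recovered at q0*{1, sqrt3, sqrt4}
        within 1%."""
        fit = WAXSPatternModel(gen_waxs(WAXSScenario())).fit()
        for role, q_exp in [("hex10", 4.7), ("hex11", 4.7 * np.sqrt(3)),
                            ("hex20", 9.4)]:
            p = fit.peak(role)
            assert p is not None, role
            assert p.q0 == pytest.approx(q_exp, rel=0.01)

    def test_coherence_length_from_known_fwhm(self):
        """Single truth fwhm 0.4 nm^-1: fitted L = 2*pi/0.4 = 15.7 nm."""
        sc = WAXSScenario(peaks={"hex10": (4.7, 0.4, 60.0)}, hexagonal=False)
        fit = WAXSPatternModel(gen_waxs(sc)).fit()
        assert fit.peak("hex10").L_nm == pytest.approx(15.7, rel=0.02)

    def test_beta_only_pattern_reports_hex_absent(self):
        """The n-hexyl heptamer world has no hexagonal reflections; the
        fitted roles say so rather than force-fitting them."""
        fit = WAXSPatternModel(gen_waxs(preset("PBLG_7_nhexyl", "waxs"))).fit()
        assert "hex10" in fit.absent_roles
        assert fit.peak("beta_lamellar") is not None
        assert fit.peak("beta_interstrand") is not None

    def test_area_recovery_under_noise(self):
        """20 noisy patterns: primary-peak areas within 3% (median)."""
        errs = []
        for seed in range(20):
            s = gen_waxs(WAXSScenario(noise=0.01, seed=seed))
            fit = WAXSPatternModel(s).fit()
            truth = s.meta["truth"]["peaks"]
            for role in ("hex10", "beta_lamellar"):
                errs.append(abs(fit.peak(role).component.area
                                / truth[role]["area"] - 1.0))
        assert np.median(errs) < 0.03


class TestFractions:
    def test_alpha_only_pattern(self):
        sc = WAXSScenario(peaks={"hex10": (4.7, 0.3, 80.0), "pitch": (12.6, 0.25, 15.0)})
        fit = WAXSPatternModel(gen_waxs(sc)).fit()
        fr = fractions_from_intensities(fit)
        assert fr.f_alpha == 1.0

    def test_60_40_recovery(self):
        """Truth 0.60/0.40 from primary-peak intensities, within 0.02."""
        fit = WAXSPatternModel(gen_waxs(WAXSScenario(noise=0.005))).fit()
        fr = fractions_from_intensities(fit)
        assert fr.f_alpha == pytest.approx(0.60, abs=0.02)
        assert fr.f_alpha + fr.f_beta == pytest.approx(1.0, rel=1e-12)

    def test_equal_intensities_half(self):
        sc = WAXSScenario(
            peaks={"hex10": (4.7, 0.35, 50.0), "beta_lamellar": (3.7, 0.35, 50.0)},
            hexagonal=False,
        )
        fr = fractions_from_intensities(WAXSPatternModel(gen_waxs(sc)).fit())
        assert fr.f_alpha == pytest.approx(0.5, abs=0.01)

    def test_no_ordered_peaks_errors(self):
        sc = WAXSScenario(peaks={"pitch": (12.6, 0.25, 10.0)}, hexagonal=False)
        fit = WAXSPatternModel(gen_waxs(sc)).fit()
        with pytest.raises(ValueError, match="family"):
            fractions_from_intensities(fit)


class TestSigmoid:
    def test_printed_alpha_law_asymptote_and_n20(self):
        """The fitted alpha-helix chain-length law f = 1 - 0.4 exp(-(0.04 n)^3.2):
        asymptote 1, and f(20) = 0.755 by direct evaluation."""
        assert sigmoid_fraction(1e9, 1.0, 0.6, 0.04, 3.2) == pytest.approx(1.0)
        assert sigmoid_fraction(20.0, 1.0, 0.6, 0.04, 3.2) == pytest.approx(
            0.755, abs=0.001
        )

    def test_alpha_law_predicts_saturation_by_n40(self):
        """The alpha-fraction law reaches >= 0.99 for n >= 40 (pure-helix
        regime of the long chains)."""
        assert sigmoid_fraction(40.0, 1.0, 0.6, 0.04, 3.2) >= 0.99

    def test_roundtrip_recovery_within_10pct(self):
        """Noiseless points from the printed law: k and d recovered within
        10% (the fit is shallow; wide confidence expected)."""
        n = np.array([4.0, 6.0, 7.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0,
                      40.0, 60.0, 80.0, 100.0])
        f = sigmoid_fraction(n, 1.0, 0.6, 0.04, 3.2)
        fit = SigmoidModel(n, f).fit()
        assert fit.k == pytest.approx(0.04, rel=0.10)
        assert fit.d_shape == pytest.approx(3.2, rel=0.10)
        assert fit.A == pytest.approx(1.0, abs=0.02)

    def test_beta_branch_negative_exponent(self):
        """The beta-sheet law 0.4*(1 - exp(-(0.05 n)^-3.6)) decays with n
        through its negative shape exponent; fitted exactly as printed."""
        n = np.array([4.0, 6.0, 7.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0,
                      40.0, 60.0])
        f = sigmoid_fraction(n, 0.4, 0.0, 0.05, -3.6)
        # flat at 0.4 for small n (the exponent saturates), then decays
        assert np.all(np.diff(f) <= 1e-12) and f[0] > f[-1]
        fit = SigmoidModel(n, f, increasing=False).fit()
        assert fit.d_shape < 0
        assert fit.predict(n) == pytest.approx(f, abs=0.01)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="6"):
            SigmoidModel([1, 2, 3], [0.1, 0.2, 0.3])
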