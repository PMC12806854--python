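"""WAXS pattern analysis: peak fitting, lattice geometry, fractions, f(n) laws.

PBLG α-helices pack on a 2-D hexagonal lattice whose (10), (11) and (20)
reflections appear at q ratios 1 : sqrt(3) : sqrt(4), with the primary (10)
peak near 4.7 nm^-1; an extra sharp peak near 12.6 nm^-1 tracks the helical
pitch.  β-sheets contribute a lamellar peak near 3.7 nm^-1 and an
interstrand peak near 13.4 nm^-1.  All patterns carry a broad amorphous
halo near 14 nm^-1.

Closed-form geometry:  d = 2*pi/q0,  hexagonal intercylinder distance
a = (2/sqrt(3)) d = 4*pi/(sqrt(3) q0),  lateral coherence length
L = 2*pi/w with w the fitted fwhm.

Relative fractions use the integrated intensities of the primary Bragg
peak of each family (hex10 vs beta_lamellar); the halo and satellites are
excluded.  The chain-length evolution of the fractions follows a
generalized sigmoid  f(n) = A - (A - B) * exp(-(k n)^d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from ._fitting import BaseResults, fit_least_squares
from .series import MeasurementSeries
from .thermal import ComponentFit, SecondaryStructureFractions

__all__ = [
    "PeakAssignment",
    "DEFAULT_ROLE_WINDOWS",
    "pseudo_voigt",
    "peak_geometry",
    "WAXSPatternModel",
    "WAXSPatternResults",
    "fractions_from_intensities",
    "SigmoidModel",
    "SigmoidResults",
    "sigmoid_fraction",
]

#: role -> (q window in nm^-1, is_broad)
DEFAULT_ROLE_WINDOWS: dict[str, tuple[float, float]] = {
    "beta_lamellar": (3.0, 4.3),
    "hex10": (4.3, 5.2),
    "hex11": (7.4, 8.8),
    "hex20": (8.8, 10.2),
    "pitch": (12.0, 13.1),
    "beta_interstrand": (13.1, 13.9),
}

HALO_CENTER = 14.0  # nm^-1, amorphous / van der Waals correlations


@dataclass(frozen=True)
class PeakAssignment:
    """A fitted Bragg peak with its structural role and derived geometry."""

    component: ComponentFit
    role: str

    @property
    def q0(self) -> float:
        return self.component.center

    @property
    def d_nm(self) -> float:
        return 2.0 * np.pi / self.q0

    @property
    def L_nm(self) -> float:
        return 2.0 * np.pi / self.component.fwhm

    @property
    def a_hex_nm(self) -> float | None:
        if self.role != "hex10":
            return None
        return 4.0 * np.pi / (np.sqrt(3.0) * self.q0)


def pseudo_voigt(
    x: np.ndarray, center: float, fwhm: float, area: float, eta: float = 0.5
) -> np.ndarray:
    """Area-normalized pseudo-Voigt: eta*Lorentzian + (1-eta)*Gaussian."""
    hw = fwhm / 2.0
    lor = hw / (np.pi * ((x - center) ** 2 + hw**2))
    sig = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gau = np.exp(-0.5 * ((x - center) / sig) ** 2) / (sig * np.sqrt(2.0 * np.pi))
    return area * (eta * lor + (1.0 - eta) * gau)


def peak_geometry(peak: PeakAssignment) -> dict[str, float]:
    """Bragg spacing, coherence length and (hex10 only) the lattice constant."""
    out = {"d_nm": peak.d_nm, "L_nm": peak.L_nm}
    a = peak.a_hex_nm
    if a is not None:
        out["a_hex_nm"] = a
    return out


@dataclass
class WAXSPatternResults(BaseResults):
    """Joint background + halo + Bragg-peak fit of one powder pattern."""

    peaks: list[PeakAssignment] = field(default_factory=list)
    absent_roles: list[str] = field(default_factory=list)
    halo: ComponentFit | None = None
    background_poly: tuple[float, ...] = ()

    def peak(self, role: str) -> PeakAssignment | None:
        for p in self.peaks:
            if p.role == role:
                return p
        return None

    def summary(self) -> str:  # noqa: D102
        base = super().summary()
        lines = [base]
        for p in self.peaks:
            geo = peak_geometry(p)
            extra = f"  a_hex={geo['a_hex_nm']:.3f} nm" if "a_hex_nm" in geo else ""
            lines.append(
                f"  {p.role:<17} q0={p.q0:6.2f} nm^-1  d={p.d_nm:.3f} nm  "
                f"L={p.L_nm:.2f} nm{extra}"
            )
        if self.absent_roles:
            lines.append(f"  absent: {', '.join(self.absent_roles)}")
        return "\n".join(lines)


class WAXSPatternModel:
    """Fit a WAXS pattern as polynomial background + halo + role-tagged peaks.

    Peaks are first *detected* (prominence threshold on the
    background-flattened pattern) inside each role window; roles with no
    detected maximum are reported absent rather than force-fitted.
    """

    def __init__(
        self,
        series: MeasurementSeries,
        role_windows: dict[str, tuple[float, float]] | None = None,
        background_degree: int = 2,
        eta: float = 0.5,
    ) -> None:
        if series.technique != "waxs":
            raise ValueError("series must be a waxs pattern")
        if series.x.min() > 3.0 or series.x.max() < 15.0:
            raise ValueError("q range must cover ~2-20 nm^-1")
        self.series = series
        self.roles = dict(role_windows or DEFAULT_ROLE_WINDOWS)
        self.bg_degree = background_degree
        self.eta = eta

    def _detect(self) -> dict[str, float]:
        """Candidate peak centers per role from a smoothed, flattened trace."""
        q = self.series.x
        y = np.asarray(self.series.y, float)
        win = min(11, len(y) - (1 - len(y) % 2))
        smooth = savgol_filter(y, window_length=win, polyorder=3)
        # crude rolling-minimum baseline so broad features do not mask peaks
        base = np.polyval(np.polyfit(q, smooth, 1), q)
        flat = smooth - base
        pk, props = find_peaks(flat, prominence=0.02 * max(flat.max(), 1e-12))
        found: dict[str, float] = {}
        for role, (qlo, qhi) in self.roles.items():
            cand = [(props["prominences"][i], q[pk[i]])
                    for i in range(len(pk)) if qlo <= q[pk[i]] <= qhi]
            if cand:
                found[role] = max(cand)[1]
        return found

    def fit(self) -> WAXSPatternResults:
        q = self.series.x
        y = np.asarray(self.series.y, float)
        detected = self._detect()
        roles = list(detected)
        absent = [r for r in self.roles if r not in detected]

        narrow0, broad0 = 0.35, 4.0
        x0, lo, hi = [], [], []
        for role in roles:
            qc = detected[role]
            qlo, qhi = self.roles[role]
            amp0 = max(np.interp(qc, q, y) * narrow0, 1e-6)
            x0 += [qc, narrow0, amp0]
            lo += [qlo, 0.02, 1e-12]
            hi += [qhi, 1.5, np.inf]
        # halo: always present
        x0 += [HALO_CENTER, broad0, max(np.interp(HALO_CENTER, q, y) * broad0, 1e-6)]
        lo += [12.0, 2.0, 1e-12]
        hi += [16.5, 8.0, np.inf]
        nbg = self.bg_degree + 1
        x0 += [0.0] * nbg
        lo += [-np.inf] * nbg
        hi += [np.inf] * nbg
        x0 = np.asarray(x0)
        n_peaks = len(roles) + 1
        qmid = 0.5 * (q[0] + q[-1])

        def residual(th):
            model = np.zeros_like(q)
            for i in range(n_peaks):
                c, w, a = th[3 * i : 3 * i + 3]
                model += pseudo_voigt(q, c, w, a, self.eta)
            coeffs = th[3 * n_peaks :]
            model += np.polyval(coeffs, q - qmid)
            return model - y

        core = fit_least_squares(residual, x0, bounds=(lo, hi), max_nfev=40000)
        peaks = []
        for i, role in enumerate(roles):
            c, w, a = core.params[3 * i : 3 * i + 3]
            peaks.append(
                PeakAssignment(
                    component=ComponentFit(center=c, fwhm=w, area=max(a, 1e-12),
                                           shape="pseudo-voigt"),
                    role=role,
                )
            )
        hc, hw, ha = core.params[3 * len(roles) : 3 * len(roles) + 3]
        halo = ComponentFit(center=hc, fwhm=hw, area=max(ha, 1e-12),
                            shape="pseudo-voigt")
        names = [f"{r}_{p}" for r in roles + ["halo"] for p in ("q0", "fwhm", "area")]
        names += [f"bg_c{i}" for i in range(nbg)]
        return WAXSPatternResults(
            core=core,
            param_names=tuple(names),
            peaks=peaks,
            absent_roles=absent,
            halo=halo,
            background_poly=tuple(core.params[3 * n_peaks :]),
        )


def fractions_from_intensities(
    result: WAXSPatternResults,
    alpha_role: str = "hex10",
    beta_role: str = "beta_lamellar",
    sample: str = "",
) -> SecondaryStructureFractions:
    """Relative α/β fractions from the primary Bragg peak of each family."""
    pa = result.peak(alpha_role)
    pb = result.peak(beta_role)
    if pa is None and pb is None:
        raise ValueError("neither ordered-structure family present in the pattern")
    ia = 0.0 if pa is None else pa.component.area
    ib = 0.0 if pb is None else pb.component.area
    f_alpha = ia / (ia + ib)
    return SecondaryStructureFractions(
        f_alpha=f_alpha, f_beta=1.0 - f_alpha, technique="WAXS", sample=sample
    )


def sigmoid_fraction(n: np.ndarray, A: float, B: float, k: float, d: float) -> np.ndarray:
    """Generalized sigmoid f(n) = A - (A - B) * exp(-(k n)^d)."""
    n = np.asarray(n, dtype=float)
    return A - (A - B) * np.exp(-((k * n) ** d))


@dataclass
class SigmoidResults(BaseResults):
    """Fitted chain-length law for a secondary-structure fraction."""

    A: float = np.nan
    B: float = np.nan
    k: float = np.nan
    d_shape: float = np.nan
    at_bounds: bool = False

    def predict(self, n: np.ndarray) -> np.ndarray:
        return sigmoid_fraction(n, self.A, self.B, self.k, self.d_shape)


class SigmoidModel:
    """Fit f(n) = A - (A-B) exp(-(k n)^d) to (n, fraction) points.

    ``increasing=False`` selects a negative shape exponent (the β-sheet
    branch, which decays with n only through the (k n)^d < 0 form).
    """

    def __init__(self, n: np.ndarray, f: np.ndarray, increasing: bool = True) -> None:
        self.n = np.asarray(n, dtype=float)
        self.f = np.asarray(f, dtype=float)
        if len(self.n) != len(self.f):
            raise ValueError("n and f must have equal length")
        if len(self.n) < 6:
            raise ValueError("need at least 6 (n, f) points")
        self.increasing = increasing

    def fit(self) -> SigmoidResults:
        if self.increasing:
            x0 = np.array([max(self.f.max(), 0.9), self.f.min(), 0.05, 3.0])
            lo = [0.0, 0.0, 1e-3, 0.3]
            hi = [1.0, 1.0, 1.0, 10.0]
        else:
            x0 = np.array([max(self.f.max(), 0.35), self.f.min(), 0.05, -3.0])
            lo = [0.0, 0.0, 1e-3, -10.0]
            hi = [1.0, 1.0, 1.0, -0.3]

        def residual(th):
            return sigmoid_fraction(self.n, *th) - self.f

        core = fit_least_squares(residual, x0, bounds=(lo, hi), max_nfev=20000)
        at_bounds = bool(
            np.isclose(core.params[3], lo[3], atol=1e-6)
            or np.isclose(core.params[3], hi[3], atol=1e-6)
        )
        return SigmoidResults(
            core=core,
            param_names=("A", "B", "k", "d_shape"),
            A=float(core.params[0]),
            B=float(core.params[1]),
            k=float(core.params[2]),
            d_shape=float(core.params[3]),
            at_bounds=at_bounds,
        )
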