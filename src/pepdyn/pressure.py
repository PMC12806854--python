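"""Pressure-domain dynamics: pressure-VFT, activation volumes, Tait EOS, Tg(P).

Under isothermal compression the loss-peak frequency of a segmental process
follows the pressure analogue of the VFT law,

    f_max(P) = f_inf * exp( -D_P * P / (P0 - P) ),

with dimensionless strength D_P and ideal-glass pressure P0.  The apparent
activation volume is the pressure sensitivity of the relaxation time,

    dV# = 2.303 * R * T * (d log10(tau) / dP)_T ,

which for the pressure-VFT form is R*T*D_P*P0/(P0-P)^2 and for an
Arrhenius-in-P (log-linear) process is 2.303*R*T*slope.  With P in MPa and
R*T in J/mol the quotient J mol^-1 MPa^-1 is numerically cm^3 mol^-1.

Density under pressure comes from the Tait equation of state

    V(P,T) = V(0,T) * (1 - 0.0894 * ln(1 + P/B(T))),
    V(0,T) = A0 + A1*T + A2*T^2,   B(T) = B0*exp(-B1*T),   T in deg C,

and the pressure dependence of the glass temperature is parameterized as

    Tg(P) = Tg(0) * (1 + (nu/mu) * P)^(1/nu),   (dTg/dP)_{P->0} = Tg(0)/mu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ._fitting import BaseResults, fit_least_squares
from .constants import R

__all__ = [
    "TaitParams",
    "TAIT_PBLG",
    "tait_volume",
    "tait_density",
    "PressureVFTModel",
    "PressureVFTResults",
    "ArrheniusPressureResults",
    "activation_volume",
    "TgPressureModel",
    "TgPressureResults",
    "delta_eps_normalized",
]

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Tait equation of state
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TaitParams:
    """Tait EOS constants; temperatures in deg C by convention."""

    A0: float = 0.788        # cm^3 g^-1
    A1: float = 4.92e-4      # cm^3 g^-1 degC^-1
    A2: float = 7.57e-7      # cm^3 g^-1 degC^-2
    B0: float = 142.0        # MPa
    B1: float = 4.3e-3       # degC^-1
    C: float = 0.0894        # universal Tait constant

    def __post_init__(self) -> None:
        for f in ("A0", "A1", "A2", "B0", "B1", "C"):
            if getattr(self, f) <= 0:
                raise ValueError(f"Tait parameter {f} must be positive")


#: PBLG melt constants.
TAIT_PBLG = TaitParams()


def tait_volume(
    T_degC: float | np.ndarray,
    P_MPa: float | np.ndarray = 0.0,
    params: TaitParams = TAIT_PBLG,
) -> np.ndarray:
    """Specific volume V(P, T) in cm^3/g."""
    T = np.asarray(T_degC, dtype=float)
    P = np.asarray(P_MPa, dtype=float)
    v0 = params.A0 + params.A1 * T + params.A2 * T**2
    b = params.B0 * np.exp(-params.B1 * T)
    arg = 1.0 + P / b
    if np.any(arg <= 0):
        raise ValueError("1 + P/B(T) must be positive")
    return v0 * (1.0 - params.C * np.log(arg))


def tait_density(
    T_degC: float | np.ndarray,
    P_MPa: float | np.ndarray = 0.0,
    params: TaitParams = TAIT_PBLG,
) -> np.ndarray:
    """Density rho = 1/V in g/cm^3."""
    return 1.0 / tait_volume(T_degC, P_MPa, params)


# ---------------------------------------------------------------------------
# pressure-VFT and Arrhenius-in-P fits
# ---------------------------------------------------------------------------
@dataclass
class PressureVFTResults(BaseResults):
    """Fitted pressure-VFT isotherm f_max(P)."""

    log10_f_inf: float = np.nan
    D_P: float = np.nan
    P0: float = np.nan
    T_K: float = np.nan

    def predict(self, P_MPa: np.ndarray) -> np.ndarray:
        P = np.asarray(P_MPa, dtype=float)
        return 10.0 ** self.log10_f_inf * np.exp(-self.D_P * P / (self.P0 - P))

    def activation_volume(self, P_MPa: float = 0.0) -> float:
        return activation_volume(self, self.T_K, P_MPa)


@dataclass
class ArrheniusPressureResults(BaseResults):
    """Log-linear f_max(P) fallback for weakly pressure-dependent processes."""

    log10_f0: float = np.nan
    slope: float = np.nan  # d log10(tau) / dP, decades per MPa (positive)
    T_K: float = np.nan

    def predict(self, P_MPa: np.ndarray) -> np.ndarray:
        return 10.0 ** (self.log10_f0 - self.slope * np.asarray(P_MPa, float))

    def activation_volume(self, P_MPa: float = 0.0) -> float:
        return activation_volume(self, self.T_K, P_MPa)


class PressureVFTModel:
    """Fit one isothermal f_max(P) set.

    ``form="vft"`` fits the pressure-VFT law; ``form="arrhenius"`` the
    log-linear fallback used for the weakly pressure-dependent slow
    (macrodipole) processes.
    """

    def __init__(
        self,
        f_max_Hz: np.ndarray,
        P_MPa: np.ndarray,
        T_K: float,
        form: str = "vft",
    ) -> None:
        self.f = np.asarray(f_max_Hz, dtype=float)
        self.P = np.asarray(P_MPa, dtype=float)
        if len(self.f) != len(self.P):
            raise ValueError("f and P must have equal length")
        if len(self.f) < 4:
            raise ValueError("need at least 4 (P, f) points")
        if form not in ("vft", "arrhenius"):
            raise ValueError(f"unknown form {form!r}")
        self.T_K = float(T_K)
        self.form = form

    def fit(self) -> PressureVFTResults | ArrheniusPressureResults:
        logf = np.log10(self.f)
        P = self.P
        if self.form == "arrhenius":
            slope, intercept = np.polyfit(P, logf, 1)
            # exact linear LS; reuse the quadrature machinery for stderrs
            core = fit_least_squares(
                lambda th: th[0] - th[1] * P - logf,
                [intercept, -slope],
                bounds=([-np.inf, -np.inf], [np.inf, np.inf]),
            )
            return ArrheniusPressureResults(
                core=core,
                param_names=("log10_f0", "slope"),
                log10_f0=float(core.params[0]),
                slope=float(core.params[1]),
                T_K=self.T_K,
            )

        pmax = P.max()
        x0 = np.array([logf.max() + 0.5, 2.0, max(3.0 * pmax, 500.0)])
        lo = [logf.max() - 2.0, 1e-3, pmax * 1.05]
        hi = [logf.max() + 8.0, 100.0, 1e5]

        def residual(th):
            return th[0] - th[1] * P / ((th[2] - P) * LN10) - logf

        core = fit_least_squares(residual, x0, bounds=(lo, hi), max_nfev=10000)
        return PressureVFTResults(
            core=core,
            param_names=("log10_f_inf", "D_P", "P0"),
            log10_f_inf=float(core.params[0]),
            D_P=float(core.params[1]),
            P0=float(core.params[2]),
            T_K=self.T_K,
        )


def activation_volume(
    fit: PressureVFTResults | ArrheniusPressureResults | float,
    T_K: float,
    P_MPa: float = 0.0,
) -> float:
    """Apparent activation volume dV# in cm^3/mol at (T, P).

    ``fit`` may be a fitted isotherm or directly an Arrhenius slope
    d log10(tau)/dP in decades/MPa.
    """
    if isinstance(fit, PressureVFTResults):
        if P_MPa >= fit.P0:
            raise ValueError("P must be below P0")
        dlogtau_dP = fit.D_P * fit.P0 / (LN10 * (fit.P0 - P_MPa) ** 2)
    elif isinstance(fit, ArrheniusPressureResults):
        dlogtau_dP = fit.slope
    else:
        dlogtau_dP = float(fit)
    # 2.303 R T (J/mol) per MPa == cm^3/mol
    return LN10 * R * T_K * dlogtau_dP


# ---------------------------------------------------------------------------
# Tg(P)
# ---------------------------------------------------------------------------
@dataclass
class TgPressureResults(BaseResults):
    """Fitted Tg(P) = Tg0 * (1 + (nu/mu) P)^(1/nu)."""

    Tg0: float = np.nan
    nu: float = np.nan
    mu_MPa: float = np.nan
    at_bounds: bool = False

    @property
    def dTgdP0_K_per_GPa(self) -> float:
        """Initial slope (dTg/dP)_{P->0} in K/GPa (Tg0/mu with mu in MPa)."""
        return 1000.0 * self.Tg0 / self.mu_MPa

    def predict(self, P_MPa: np.ndarray) -> np.ndarray:
        P = np.asarray(P_MPa, dtype=float)
        return self.Tg0 * (1.0 + (self.nu / self.mu_MPa) * P) ** (1.0 / self.nu)

    def summary(self) -> str:  # noqa: D102
        return super().summary() + (
            f"\n  (dTg/dP)_P->0 = {self.dTgdP0_K_per_GPa:.1f} K/GPa"
            + ("   [parameter at bounds]" if self.at_bounds else "")
        )


class TgPressureModel:
    """Fit the empirical Tg(P) power law to (P, Tg) points."""

    def __init__(self, Tg_K: np.ndarray, P_MPa: np.ndarray) -> None:
        self.Tg = np.asarray(Tg_K, dtype=float)
        self.P = np.asarray(P_MPa, dtype=float)
        if len(self.Tg) != len(self.P):
            raise ValueError("Tg and P must have equal length")
        if len(self.Tg) < 4:
            raise ValueError("need at least 4 (P, Tg) points")
        if self.P.min() > 50.0:
            raise ValueError("need a point near P = 0 to anchor Tg(0)")

    def fit(self) -> TgPressureResults:
        x0 = np.array([self.Tg[np.argmin(self.P)], 3.0, 1500.0])
        lo = [100.0, 0.1, 50.0]
        hi = [600.0, 20.0, 1e5]

        def residual(th):
            tg0, nu, mu = th
            return tg0 * (1.0 + (nu / mu) * self.P) ** (1.0 / nu) - self.Tg

        core = fit_least_squares(residual, x0, bounds=(lo, hi), max_nfev=10000)
        tg0, nu, mu = core.params
        at_bounds = bool(
            np.any(np.isclose(core.params, lo, rtol=1e-6))
            or np.any(np.isclose(core.params, hi, rtol=1e-6))
        )
        return TgPressureResults(
            core=core,
            param_names=("Tg0", "nu", "mu_MPa"),
            Tg0=float(tg0),
            nu=float(nu),
            mu_MPa=float(mu),
            at_bounds=at_bounds,
        )


# ---------------------------------------------------------------------------
# normalized dielectric strength
# ---------------------------------------------------------------------------
def delta_eps_normalized(
    delta_eps: np.ndarray,
    P_MPa: np.ndarray,
    T_K: float,
    params: TaitParams = TAIT_PBLG,
) -> dict:
    """Delta_eps / rho along an isotherm, with a turnover detector.

    For segmental processes the density-normalized strength keeps rising
    with pressure (pressure creates relaxing defects); for the ordered
    α-helix / β-sheet macrodipole processes it rises only up to a threshold
    pressure and decreases above it.  The returned ``turnover_MPa`` is the
    pressure of the (smoothed) maximum when one exists in the interior of
    the window, else None.
    """
    delta_eps = np.asarray(delta_eps, dtype=float)
    P = np.asarray(P_MPa, dtype=float)
    if delta_eps.shape != P.shape:
        raise ValueError("delta_eps and P grids must match")
    rho = tait_density(T_K - 273.15, P, params)
    norm = delta_eps / rho
    turnover = None
    if len(norm) >= 5:
        win = min(5, len(norm) - (1 - len(norm) % 2))
        smooth = savgol_filter(norm, window_length=win, polyorder=2)
        i = int(np.argmax(smooth))
        if 0 < i < len(norm) - 1 and smooth[i] > smooth[0] and smooth[i] > smooth[-1]:
            turnover = float(P[i])
    return {"P_MPa": P, "delta_eps_over_rho": norm, "rho": rho, "turnover_MPa": turnover}
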