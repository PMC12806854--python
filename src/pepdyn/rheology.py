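"""Time–temperature superposition, WLF, van Gurp–Palmen and mesh analysis.

Isothermal G'(ω), G''(ω) sweeps are shifted onto a master curve at a
reference temperature, G*(ω, T) = b_T G*(a_T ω; Tref), by minimizing the
squared log-modulus mismatch in overlapping reduced-frequency windows.
The horizontal shift factors follow the WLF law

    log10 a_T = -C1 (T - Tref) / (C2 + T - Tref),

algebraically equivalent to a VFT law with B = C1*C2*ln(10) and
T0 = Tref - C2.

The van Gurp–Palmen plot of phase angle δ = atan(G''/G') against |G*|
exposes the elastic plateau: a δ-minimum at |G*| ≈ G_N^0 (plateau region)
and a second minimum near the glassy modulus (~1e9 Pa).  The plateau
modulus converts to the apparent entanglement ("mesh") parameters

    M_e = 4 rho R Tref / (5 G_N^0),   N_e = M_e / M0,
    d_mesh = (kB Tref / G_N^0)^(1/3)        [with omega_c * tau = 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import argrelmin

from ._fitting import BaseResults, fit_least_squares
from .constants import KB, M0_BLG, R
from .series import MeasurementSeries

__all__ = [
    "MasterCurve",
    "build_master_curve",
    "WLFModel",
    "WLFResults",
    "wlf_log_aT",
    "vgp_curve",
    "vgp_minima",
    "VGPMinima",
    "plateau_derived",
]

LN10 = np.log(10.0)


def wlf_log_aT(T: np.ndarray, C1: float, C2: float, Tref: float) -> np.ndarray:
    """log10 a_T of the WLF equation."""
    dT = np.asarray(T, dtype=float) - Tref
    return -C1 * dT / (C2 + dT)


@dataclass
class MasterCurve:
    """Reduced-frequency master curve plus the per-temperature shift factors."""

    omega: np.ndarray          # reduced angular frequency, rad/s
    G1: np.ndarray             # Pa
    G2: np.ndarray             # Pa
    Tref: float
    temperatures: np.ndarray
    log_aT: np.ndarray         # log10 horizontal shifts, aligned with temperatures
    b_T: np.ndarray            # vertical shifts (1 unless enabled)
    overlap_residual: float

    @property
    def aT(self) -> np.ndarray:
        return 10.0 ** self.log_aT


def _overlap_mismatch(
    lw1: np.ndarray, lg1: np.ndarray, lw2: np.ndarray, lg2: np.ndarray, shift: float
) -> float:
    """Squared mismatch between curve 2 shifted by ``shift`` and curve 1."""
    s2 = lw2 + shift
    lo = max(lw1.min(), s2.min())
    hi = min(lw1.max(), s2.max())
    if hi <= lo:
        return np.nan
    grid = np.linspace(lo, hi, 50)
    a = np.interp(grid, lw1, lg1)
    b = np.interp(grid, s2, lg2)
    return float(np.mean((a - b) ** 2))


def build_master_curve(
    sweeps: list[MeasurementSeries],
    Tref: float,
    allow_vertical: bool = False,
) -> MasterCurve:
    """Shift isothermal sweeps onto the Tref sweep (pairwise, order-invariant).

    Sweeps are processed in temperature order outward from Tref, so a
    shuffled input list yields an identical result.  Adjacent sweeps with no
    overlapping reduced-frequency window raise with the offending pair named.
    """
    if not sweeps:
        raise ValueError("no sweeps given")
    for s in sweeps:
        if s.technique != "rheo" or not s.is_complex:
            raise ValueError("sweeps must be complex-valued rheo series")
    temps = np.array([s.temperature for s in sweeps])
    if Tref not in temps:
        raise ValueError(f"Tref={Tref} K is not among the sweep temperatures")
    order = np.argsort(temps)
    sweeps = [sweeps[i] for i in order]
    temps = temps[order]

    logw = [np.log10(s.x) for s in sweeps]
    # shift on |G*| (log scale); using the modulus keeps G' and G'' consistent
    logg = [np.log10(np.abs(s.y)) for s in sweeps]

    iref = int(np.where(temps == Tref)[0][0])
    log_aT = np.zeros(len(sweeps))
    total_mis = 0.0
    # walk outward from the reference in both directions
    for seq in (range(iref + 1, len(sweeps)), range(iref - 1, -1, -1)):
        prev = iref
        for i in seq:
            def mis(s, i=i, prev=prev):
                m = _overlap_mismatch(
                    logw[prev] + log_aT[prev], logg[prev], logw[i], logg[i], s
                )
                return 1e9 if np.isnan(m) else m

            res = minimize_scalar(mis, bounds=(-12.0, 12.0), method="bounded")
            # a genuine overlap superposes to ~noise level; a large residual
            # means the curves share no common reduced-frequency window
            if mis(res.x) >= 0.01:
                raise ValueError(
                    f"no usable reduced-frequency overlap between sweeps at "
                    f"{temps[prev]:.1f} K and {temps[i]:.1f} K"
                )
            log_aT[i] = res.x
            total_mis += res.fun
            prev = i

    b_T = np.ones(len(sweeps))
    if allow_vertical:
        ref_lg = logg[iref]
        for i in range(len(sweeps)):
            if i == iref:
                continue
            s2 = logw[i] + log_aT[i]
            lo = max(logw[iref].min(), s2.min())
            hi = min(logw[iref].max(), s2.max())
            grid = np.linspace(lo, hi, 50)
            off = np.mean(np.interp(grid, logw[iref], ref_lg)
                          - np.interp(grid, s2, logg[i]))
            b_T[i] = 10.0 ** off

    omega_all = np.concatenate([s.x * 10.0 ** log_aT[i] for i, s in enumerate(sweeps)])
    g_all = np.concatenate([s.y * b_T[i] for i, s in enumerate(sweeps)])
    idx = np.argsort(omega_all)
    # collapse exact duplicates so the master grid stays strictly increasing
    omega_sorted = omega_all[idx]
    g_sorted = g_all[idx]
    keep = np.concatenate([[True], np.diff(omega_sorted) > 0])
    return MasterCurve(
        omega=omega_sorted[keep],
        G1=g_sorted[keep].real,
        G2=g_sorted[keep].imag,
        Tref=float(Tref),
        temperatures=temps,
        log_aT=log_aT,
        b_T=b_T,
        overlap_residual=float(total_mis),
    )


@dataclass
class WLFResults(BaseResults):
    """Fitted WLF constants at the stated reference temperature."""

    C1: float = np.nan
    C2: float = np.nan
    Tref: float = np.nan

    def predict(self, T: np.ndarray) -> np.ndarray:
        return wlf_log_aT(T, self.C1, self.C2, self.Tref)

    @property
    def vft_B(self) -> float:
        """Equivalent VFT activation parameter B = C1*C2*ln10 (K)."""
        return self.C1 * self.C2 * LN10

    @property
    def vft_T0(self) -> float:
        """Equivalent VFT Vogel temperature T0 = Tref - C2 (K)."""
        return self.Tref - self.C2


class WLFModel:
    """Fit log10 a_T(T) with the WLF equation (a_T(Tref) = 1 by construction)."""

    def __init__(self, log_aT: np.ndarray, T_K: np.ndarray, Tref: float) -> None:
        self.log_aT = np.asarray(log_aT, dtype=float)
        self.T = np.asarray(T_K, dtype=float)
        if len(self.log_aT) != len(self.T):
            raise ValueError("log_aT and T must have equal length")
        if len(self.T) < 3:
            raise ValueError("need at least 3 temperatures")
        self.Tref = float(Tref)

    def fit(self) -> WLFResults:
        x0 = np.array([8.0, 60.0])
        lo = [1e-3, 1.0]
        hi = [100.0, 500.0]

        def residual(th):
            return wlf_log_aT(self.T, th[0], th[1], self.Tref) - self.log_aT

        core = fit_least_squares(residual, x0, bounds=(lo, hi), max_nfev=10000)
        return WLFResults(
            core=core,
            param_names=("C1", "C2"),
            C1=float(core.params[0]),
            C2=float(core.params[1]),
            Tref=self.Tref,
        )


def vgp_curve(G1: np.ndarray, G2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """van Gurp–Palmen coordinates: (|G*| in Pa, δ in degrees), sorted by |G*|."""
    G1 = np.asarray(G1, dtype=float)
    G2 = np.asarray(G2, dtype=float)
    if np.any(G1 <= 0) or np.any(G2 < 0):
        raise ValueError("moduli must be positive")
    gabs = np.hypot(G1, G2)
    delta = np.degrees(np.arctan2(G2, G1))
    idx = np.argsort(gabs)
    return gabs[idx], delta[idx]


@dataclass
class VGPMinima:
    """δ-minima of a vGP curve; at most a plateau and a glassy minimum."""

    G_abs: np.ndarray
    delta: np.ndarray
    minima: list[dict] = field(default_factory=list)

    @property
    def plateau(self) -> dict | None:
        """Lower-|G*| minimum: the elastic-plateau signature (G at min ≈ G_N^0)."""
        return self.minima[0] if self.minima else None

    @property
    def glassy(self) -> dict | None:
        return self.minima[1] if len(self.minima) > 1 else None


def vgp_minima(G1: np.ndarray, G2: np.ndarray, smooth_window: int = 5) -> VGPMinima:
    """Locate δ-minima on the (smoothed) δ(log|G*|) curve.

    At most two are reported, ordered by |G*|: the plateau-region minimum
    (its modulus is the G_N^0 readout) and the glassy-region minimum.  A
    monotone δ yields an empty list; a flat δ≈0 elastic solid yields the
    single trivial minimum at the lowest modulus.
    """
    gabs, delta = vgp_curve(G1, G2)
    n = len(gabs)
    if n < 3:
        raise ValueError("need at least 3 points")
    win = max(3, min(smooth_window, n if n % 2 else n - 1))
    pad = win // 2
    padded = np.pad(delta, pad, mode="edge")
    sm = np.convolve(padded, np.ones(win) / win, mode="valid")
    interior = argrelmin(sm, order=2)[0]
    minima = [
        {"G_at_min_Pa": float(gabs[i]), "delta_min_deg": float(sm[i])}
        for i in interior
    ]
    if not minima and np.ptp(sm) < 0.5 and np.all(sm < 5.0):
        # essentially elastic: one trivial minimum at the low-modulus end
        i = int(np.argmin(sm))
        minima = [{"G_at_min_Pa": float(gabs[i]), "delta_min_deg": float(sm[i])}]
    minima.sort(key=lambda m: m["G_at_min_Pa"])
    if len(minima) > 2:
        # keep the deepest in each half of the log-modulus range
        mid = np.sqrt(minima[0]["G_at_min_Pa"] * minima[-1]["G_at_min_Pa"])
        low = [m for m in minima if m["G_at_min_Pa"] <= mid]
        high = [m for m in minima if m["G_at_min_Pa"] > mid]
        minima = [min(g, key=lambda m: m["delta_min_deg"]) for g in (low, high) if g]
        minima.sort(key=lambda m: m["G_at_min_Pa"])
    return VGPMinima(G_abs=gabs, delta=delta, minima=minima)


def plateau_derived(
    G_N0_Pa: float,
    rho_g_cm3: float,
    Tref_K: float,
    M0: float = M0_BLG,
) -> dict[str, float]:
    """Convert a plateau modulus to mesh parameters M_e, N_e and d_mesh.

    M_e = 4 rho R Tref / (5 G_N^0) (g/mol with rho in g/cm^3), N_e = M_e/M0,
    and the mesh size d = (kB Tref / G_N^0)^(1/3) in nm.
    """
    if min(G_N0_Pa, rho_g_cm3, Tref_K, M0) <= 0:
        raise ValueError("all inputs must be positive")
    rho_si = rho_g_cm3 * 1e3  # kg/m^3
    Me_kg = 4.0 * rho_si * R * Tref_K / (5.0 * G_N0_Pa)
    Me = Me_kg * 1e3  # g/mol
    Ne = Me / M0
    d_mesh_nm = (KB * Tref_K / G_N0_Pa) ** (1.0 / 3.0) * 1e9
    return {"M_e_g_mol": Me, "N_e": Ne, "d_mesh_nm": d_mesh_nm}
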