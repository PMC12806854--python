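"""Relaxation maps: VFT fits, glass temperatures, fragility, TM-DSC times.

Segmental relaxation times of glass-formers follow the super-Arrhenius
Vogel–Fulcher–Tammann law

    tau(T) = tau0 * exp( B / (T - T0) ),

with activation parameter B (K) and ideal glass temperature T0 (K).  The
operational glass temperature is defined by tau(Tg) = tau_ref (100 s for
ambient-pressure maps, 10 s under pressure), giving

    Tg = T0 + B / ln(tau_ref / tau0),

and the fragility (steepness index) at Tg is

    m* = B * Tg / (2.303 * (Tg - T0)^2).

TM-DSC contributes points to the same map through tau = P / (2*pi) with P
the modulation period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fitting import BaseResults, fit_least_squares

__all__ = [
    "VFTModel",
    "VFTResults",
    "DerivedDynamics",
    "vft_tau",
    "vft_derived",
    "tmdsc_tau",
]

LN10 = np.log(10.0)


def vft_tau(T: np.ndarray, log10_tau0: float, B: float, T0: float) -> np.ndarray:
    """Evaluate tau(T) in seconds; T strictly above T0."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= T0):
        raise ValueError("VFT undefined for T <= T0")
    return 10.0 ** log10_tau0 * np.exp(B / (T - T0))


@dataclass(frozen=True)
class DerivedDynamics:
    """Glass temperature and fragility derived from a VFT parameter set."""

    Tg_K: float
    fragility_mstar: float
    tau_ref_s: float


def vft_derived(
    log10_tau0: float, B: float, T0: float, tau_ref: float = 100.0
) -> DerivedDynamics:
    """Tg at tau(Tg)=tau_ref and the steepness index m* at that Tg."""
    tau0 = 10.0 ** log10_tau0
    if tau_ref <= tau0:
        raise ValueError("tau_ref must exceed tau0")
    Tg = T0 + B / np.log(tau_ref / tau0)
    mstar = B * Tg / (LN10 * (Tg - T0) ** 2)
    return DerivedDynamics(Tg_K=float(Tg), fragility_mstar=float(mstar), tau_ref_s=tau_ref)


def tmdsc_tau(period_s: float) -> float:
    """Relaxation time probed by one TM-DSC modulation period: P/(2*pi)."""
    if period_s <= 0:
        raise ValueError("period must be positive")
    return period_s / (2.0 * np.pi)


@dataclass
class VFTResults(BaseResults):
    """Fitted VFT law for one relaxation process."""

    log10_tau0: float = np.nan
    B: float = np.nan
    T0: float = np.nan
    tau0_fixed: bool = False

    def tg(self, tau_ref: float = 100.0) -> float:
        return vft_derived(self.log10_tau0, self.B, self.T0, tau_ref).Tg_K

    def fragility(self, tau_ref: float = 100.0) -> float:
        return vft_derived(self.log10_tau0, self.B, self.T0, tau_ref).fragility_mstar

    def predict(self, T: np.ndarray) -> np.ndarray:
        return vft_tau(T, self.log10_tau0, self.B, self.T0)

    def summary(self) -> str:  # noqa: D102
        base = super().summary()
        der = vft_derived(self.log10_tau0, self.B, self.T0)
        return base + (
            f"\n  Tg(tau=100 s) = {der.Tg_K:.2f} K   m* = {der.fragility_mstar:.1f}"
            + ("   [tau0 held fixed]" if self.tau0_fixed else "")
        )


class VFTModel:
    """Fit log10 tau(T) with the VFT law.

    Parameters
    ----------
    tau_s, T_K : arrays
        Relaxation times (s) and temperatures (K); >= 4 points spanning at
        least two decades in tau.
    fix_log10_tau0 : float, optional
        Hold log10(tau0) at the given value (the usual -12 or -14
        high-temperature-limit convention) and fit only B and T0.
    """

    def __init__(
        self,
        tau_s: np.ndarray,
        T_K: np.ndarray,
        fix_log10_tau0: float | None = None,
    ) -> None:
        self.tau = np.asarray(tau_s, dtype=float)
        self.T = np.asarray(T_K, dtype=float)
        if len(self.tau) != len(self.T):
            raise ValueError("tau and T must have equal length")
        if len(self.tau) < 4:
            raise ValueError("need at least 4 (T, tau) points for a VFT fit")
        span = np.log10(self.tau.max() / self.tau.min())
        if span < 2.0:
            raise ValueError(
                f"tau range spans only {span:.2f} decades; need >= 2 for VFT"
            )
        self.fix_log10_tau0 = fix_log10_tau0

    def fit(self) -> VFTResults:
        logtau = np.log10(self.tau)
        T = self.T
        fixed = self.fix_log10_tau0

        if fixed is None:
            x0 = np.array([-12.0, 1500.0, T.min() - 45.0])
            lo = [-18.0, 10.0, 0.0]
            hi = [-4.0, 1e4, T.min() - 1.0]

            def residual(th):
                return th[0] + th[1] / (LN10 * (T - th[2])) - logtau

        else:
            x0 = np.array([1500.0, T.min() - 45.0])
            lo = [10.0, 0.0]
            hi = [1e4, T.min() - 1.0]

            def residual(th):
                return fixed + th[0] / (LN10 * (T - th[1])) - logtau

        core = fit_least_squares(residual, x0, bounds=(lo, hi), max_nfev=10000)
        if fixed is None:
            l0, B, T0 = core.params
            names = ("log10_tau0", "B", "T0")
        else:
            B, T0 = core.params
            l0 = fixed
            names = ("B", "T0")
        return VFTResults(
            core=core,
            param_names=names,
            log10_tau0=float(l0),
            B=float(B),
            T0=float(T0),
            tau0_fixed=fixed is not None,
        )
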