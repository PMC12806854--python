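"""Havriliak–Negami analysis of broadband dielectric spectra.

The complex permittivity of a glass-forming polypeptide is modelled as a sum
of HN relaxation processes plus a dc-conductivity term,

    eps*(omega) = eps_inf + sum_k  d_eps_k / [1 + (i omega tau_k)^m_k]^n_k
                  + sigma0 / (i EPS0 omega),

with 0.2 < m <= 1 and 0 < m*n <= 1 (symmetric and asymmetric broadening).
``m = n = 1`` is the Debye limit; ``n = 1`` the symmetric Cole–Cole case.

The frequency of maximum loss of one HN process is known in closed form,
implemented in :func:`tau_max` and pinned in the test-suite against direct
maximization of the loss on a dense grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from ._fitting import BaseResults, fit_least_squares
from .constants import EPS0
from .series import MeasurementSeries

__all__ = [
    "HNProcess",
    "hn_eval",
    "tau_max",
    "derivative_loss",
    "HavriliakNegamiModel",
    "SpectrumFitResults",
]


@dataclass(frozen=True)
class HNProcess:
    """One Havriliak–Negami relaxation process.

    delta_eps : dielectric strength (unitless)
    tau_hn    : HN characteristic time, s
    m, n      : symmetric / asymmetric broadening exponents
    """

    delta_eps: float
    tau_hn: float
    m: float
    n: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.2 < self.m <= 1.0):
            raise ValueError(f"m={self.m} outside (0.2, 1]")
        if not (0.0 < self.m * self.n <= 1.0 + 1e-12):
            raise ValueError(f"m*n={self.m * self.n} outside (0, 1]")
        if self.tau_hn <= 0:
            raise ValueError("tau_hn must be positive")
        if self.delta_eps < 0:
            raise ValueError("delta_eps must be non-negative")

    @property
    def tau_max(self) -> float:
        return tau_max(self)

    @property
    def f_max(self) -> float:
        """Frequency of maximum loss, Hz."""
        return 1.0 / (2.0 * np.pi * self.tau_max)


def hn_eval(
    omega: np.ndarray,
    processes: list[HNProcess] | HNProcess,
    eps_inf: float = 0.0,
    sigma0: float = 0.0,
) -> np.ndarray:
    """Evaluate eps*(omega) = eps' + i*eps'' on an angular-frequency grid.

    ``omega`` in rad/s, strictly positive.  The imaginary part returned is
    the (positive) dielectric loss eps''; conductivity contributes
    sigma0/(EPS0*omega) to it.  ``sigma0`` in S/m.
    """
    eps1, eps2 = hn_loss_real(omega, processes, eps_inf, sigma0)
    return eps1 + 1j * eps2


def hn_loss_real(
    omega: np.ndarray,
    processes: list[HNProcess] | HNProcess,
    eps_inf: float = 0.0,
    sigma0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (eps', eps'') with eps'' >= 0 — the conventional plotting form."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    if isinstance(processes, HNProcess):
        processes = [processes]
    total = np.full_like(omega, eps_inf, dtype=complex)
    for p in processes:
        total += p.delta_eps / (1.0 + (1j * omega * p.tau_hn) ** p.m) ** p.n
    eps1 = total.real
    eps2 = -total.imag + sigma0 / (EPS0 * omega)
    return eps1, eps2


def tau_max(p: HNProcess) -> float:
    """Relaxation time at maximum loss of one HN process (closed form).

    tau_max = tau_hn * [ sin(pi*m*n / (2(1+n))) / sin(pi*m / (2(1+n))) ]^(1/m)

    For n = 1 the line shape is symmetric and tau_max = tau_hn.
    """
    arg = np.pi * p.m / (2.0 * (1.0 + p.n))
    return p.tau_hn * (np.sin(p.n * arg) / np.sin(arg)) ** (1.0 / p.m)


def derivative_loss(series: MeasurementSeries, window: int = 7, polyorder: int = 3) -> MeasurementSeries:
    """Conduction-free loss from the derivative of the real permittivity.

    For broad peaks  deps'/dln(omega) ≈ -(2/pi) eps'', so the returned
    quantity is  eps''_deriv = -(pi/2) * deps'/dln(omega), computed by
    Savitzky–Golay differentiation on the (assumed log-uniform) grid.  The
    dc-conductivity term has no real part and drops out by construction.
    """
    if len(series) < 7:
        raise ValueError("need at least 7 grid points for derivative loss")
    eps1 = series.y.real if series.is_complex else np.asarray(series.y, float)
    lnw = np.log(series.x)
    dln = np.mean(np.diff(lnw))
    window = min(window if window % 2 == 1 else window + 1, len(series) - (1 - len(series) % 2))
    deriv = savgol_filter(eps1, window_length=window, polyorder=polyorder,
                          deriv=1, delta=dln)
    out = -(np.pi / 2.0) * deriv
    return MeasurementSeries(
        x=series.x, y=out, technique="dielectric", meta=dict(series.meta)
    )


@dataclass
class SpectrumFitResults(BaseResults):
    """Fitted HN decomposition of one permittivity spectrum."""

    processes: list[HNProcess] = field(default_factory=list)
    sigma0: float = 0.0
    eps_inf: float = 0.0
    unresolved: list[str] = field(default_factory=list)
    degenerate: bool = False

    @property
    def tau_max(self) -> dict[str, float]:
        return {p.name: tau_max(p) for p in self.processes}

    def predict(self, omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return hn_loss_real(omega, self.processes, self.eps_inf, self.sigma0)

    def summary(self) -> str:  # noqa: D102 - inherited
        base = super().summary()
        extra = [
            f"  processes (by ascending tau_max): "
            + ", ".join(
                f"{p.name}: tau_max={tau_max(p):.3g}s d_eps={p.delta_eps:.3g}"
                for p in self.processes
            )
        ]
        if self.unresolved:
            extra.append(f"  unresolved: {self.unresolved}")
        if self.degenerate:
            extra.append("  flagged degenerate (collapsed process)")
        return "\n".join([base] + extra)


class HavriliakNegamiModel:
    """Fit a sum of HN processes + dc conductivity to one dielectric spectrum.

    Parameters
    ----------
    series : MeasurementSeries
        Dielectric spectrum; ``x`` in Hz, complex ``y`` = eps' + i*eps''.
    n_processes : int
        Number of HN processes (1–3).
    fit_conductivity : bool
        Include the sigma0/(EPS0*omega) term.
    objective : str
        ``"loss+real"`` (default): joint residual on log10 eps'' and eps'
        (the real part pins eps_inf, which the loss alone cannot).
        ``"loss"``: log10 eps'' only.  ``"derivative"``: log10 of the
        derivative-based loss (conduction-free target).
    names : sequence of str, optional
        Process labels assigned by ascending tau_max after the fit.
    """

    def __init__(
        self,
        series: MeasurementSeries,
        n_processes: int = 1,
        fit_conductivity: bool = True,
        objective: str = "loss+real",
        names: tuple[str, ...] | None = None,
        shape_init: tuple[float, float] = (0.85, 0.8),
    ) -> None:
        if series.technique != "dielectric":
            raise ValueError("series must be a dielectric spectrum")
        if not series.is_complex:
            raise ValueError("dielectric series must carry eps' and eps''")
        if not 1 <= n_processes <= 3:
            raise ValueError("n_processes must be 1..3")
        self.series = series
        self.n_processes = n_processes
        self.fit_conductivity = fit_conductivity
        if objective not in ("loss", "loss+real", "derivative"):
            raise ValueError(f"unknown objective {objective!r}")
        self.objective = objective
        self.names = names or ("alpha", "alpha*", "slow")[:n_processes]
        self.shape_init = shape_init
        self.omega = 2.0 * np.pi * series.x

    # -- initialization ----------------------------------------------------
    def _initial_guess(self) -> np.ndarray:
        eps2_d = derivative_loss(self.series).y
        eps1 = self.series.y.real
        # peak positions of the conduction-free loss seed the taus
        pk, _ = find_peaks(np.clip(eps2_d, 0, None))
        order = np.argsort(eps2_d[pk])[::-1] if len(pk) else np.array([], int)
        centers = list(self.omega[pk[order[: self.n_processes]]])
        while len(centers) < self.n_processes:
            # spread the remaining guesses over the window
            lo, hi = np.log10(self.omega[0]), np.log10(self.omega[-1])
            centers.append(10 ** np.random.default_rng(len(centers)).uniform(lo, hi))
        centers = sorted(centers, reverse=True)  # fast first
        d_eps_total = max(eps1[0] - eps1[-1], 0.2)
        m0, n0 = self.shape_init
        x0 = []
        for w_c in centers:
            x0 += [np.log10(d_eps_total / self.n_processes), -np.log10(w_c), m0, n0]
        x0.append(float(eps1[-1]))  # eps_inf
        if self.fit_conductivity:
            sig = max(self.series.y.imag[0] * EPS0 * self.omega[0], 1e-18)
            x0.append(np.log10(sig))
        return np.asarray(x0)

    def _unpack(self, theta: np.ndarray) -> tuple[list[HNProcess], float, float]:
        procs = []
        for k in range(self.n_processes):
            lde, lt, m, n = theta[4 * k : 4 * k + 4]
            procs.append(
                HNProcess(delta_eps=10.0 ** lde, tau_hn=10.0 ** lt, m=m, n=n)
            )
        eps_inf = theta[4 * self.n_processes]
        sigma0 = (
            10.0 ** theta[4 * self.n_processes + 1] if self.fit_conductivity else 0.0
        )
        return procs, eps_inf, sigma0

    def fit(self, x0: np.ndarray | None = None) -> SpectrumFitResults:
        if x0 is None:
            x0 = self._initial_guess()
        eps1_obs = self.series.y.real
        eps2_obs = np.clip(self.series.y.imag, 1e-12, None)
        if self.objective == "derivative":
            target = np.clip(derivative_loss(self.series).y, 1e-12, None)
        else:
            target = eps2_obs

        n_p = self.n_processes
        lo = [-4.0, -12.0, 0.2 + 1e-6, 1e-3] * n_p + [1.0]
        hi = [4.0, 6.0, 1.0, 1.0] * n_p + [20.0]
        if self.fit_conductivity:
            lo.append(-20.0)
            hi.append(2.0)
        x0 = np.clip(x0, lo, hi)

        def residual(theta: np.ndarray) -> np.ndarray:
            # enforce m*n <= 1 softly by clipping n inside the model eval
            procs = []
            for k in range(n_p):
                lde, lt, m, n = theta[4 * k : 4 * k + 4]
                n = min(n, 1.0 / m)
                procs.append(HNProcess(10.0 ** lde, 10.0 ** lt, m, n))
            eps_inf = theta[4 * n_p]
            sigma0 = 10.0 ** theta[4 * n_p + 1] if self.fit_conductivity else 0.0
            e1, e2 = hn_loss_real(self.omega, procs, eps_inf, sigma0)
            if self.objective == "derivative":
                # differentiate the model eps' exactly as the data was, so the
                # smoothed-derivative approximation cancels in the residual
                model_d = derivative_loss(
                    MeasurementSeries(
                        x=self.series.x, y=e1 + 1j * e2, technique="dielectric",
                        meta={"temperature_K": 0.0},
                    )
                ).y
                e2 = model_d
            res = np.log10(np.clip(e2, 1e-12, None)) - np.log10(target)
            if self.objective == "loss+real":
                scale = max(eps1_obs.max() - eps1_obs.min(), 1e-3)
                res = np.concatenate([res, (e1 - eps1_obs) / scale])
            return res

        core = fit_least_squares(residual, x0, bounds=(lo, hi), max_nfev=20000)
        procs, eps_inf, sigma0 = self._unpack(core.params)
        procs = [replace(p, n=min(p.n, 1.0 / p.m)) for p in procs]
        # label by ascending tau_max (fastest = first name)
        procs = sorted(procs, key=tau_max)
        procs = [replace(p, name=nm) for p, nm in zip(procs, self.names)]

        total_de = sum(p.delta_eps for p in procs)
        # degenerate: a process collapsed to (near) zero strength, or two
        # processes landed on indistinguishable timescales
        degenerate = n_p > 1 and (
            any(p.delta_eps < 0.03 * max(total_de, 1e-6) for p in procs)
            or any(
                abs(np.log10(tau_max(a) / tau_max(b))) < 0.3
                for i, a in enumerate(procs)
                for b in procs[i + 1 :]
            )
        )
        w_lo, w_hi = self.omega[0], self.omega[-1]
        unresolved = [
            p.name
            for p in procs
            if not (w_lo / 10.0 <= 1.0 / tau_max(p) <= w_hi * 10.0)
        ]
        names = []
        for k in range(n_p):
            names += [f"log10_delta_eps_{k}", f"log10_tau_hn_{k}", f"m_{k}", f"n_{k}"]
        names.append("eps_inf")
        if self.fit_conductivity:
            names.append("log10_sigma0")
        return SpectrumFitResults(
            core=core,
            param_names=tuple(names),
            processes=procs,
            sigma0=sigma0,
            eps_inf=eps_inf,
            unresolved=unresolved,
            degenerate=degenerate,
        )
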