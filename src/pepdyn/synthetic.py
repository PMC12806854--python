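"""Synthetic instrument data with known ground truth for every technique.

The full analysis chain is exercised end to end on generated data:
dielectric spectra as sums of HN processes (τ following VFT in temperature
and pressure-VFT in pressure) plus dc conductivity; reversing-c_p traces
with two logistic glass steps; WAXS patterns as pseudo-Voigt Bragg peaks
(hexagonal 1:sqrt3:sqrt4 family, β-sheet lamellar/interstrand peaks) on an
amorphous halo and polynomial background; Cα NMR resonances; and
thermorheologically simple G*(ω, T) obeying true WLF shifts with an elastic
plateau.

Every generator takes a seed, applies multiplicative Gaussian noise (the
instruments span decades of dynamic range), and attaches a machine-readable
``truth`` record to the returned series' metadata sidecar.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np


from .dielectric import HNProcess, hn_loss_real
from .rheology import wlf_log_aT
from .series import MeasurementSeries
from .waxs import pseudo_voigt

__all__ = [
    "ProcessSpec",
    "DielectricScenario",
    "DSCScenario",
    "WAXSScenario",
    "NMRScenario",
    "RheoScenario",
    "gen_dielectric",
    "gen_dsc",
    "gen_waxs",
    "gen_nmr",
    "gen_rheo",
    "PRESETS",
    "preset",
]


# ---------------------------------------------------------------------------
# dielectric
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ProcessSpec:
    """Ground-truth description of one relaxation process.

    tau(T, P) = 10^log10_tau0 * exp(B/(T-T0)) * exp(D_P*P/(P0-P)); the
    pressure factor is active only when (D_P, P0) are set.  delta_eps may be
    constant or decrease ~1/T via ``delta_eps_slope``.
    """

    name: str
    delta_eps: float
    log10_tau0: float
    B: float
    T0: float
    m: float = 0.85
    n: float = 0.7
    D_P: float | None = None
    P0_MPa: float | None = None
    delta_eps_slope: float = 0.0  # d(delta_eps)/dT, 1/K

    def __post_init__(self) -> None:
        if not (0.2 < self.m <= 1.0 and 0.0 < self.m * self.n <= 1.0):
            raise ValueError("HN shape outside 0.2 < m <= 1, 0 < m*n <= 1")

    def tau(self, T_K: float, P_MPa: float = 0.0) -> float:
        if T_K <= self.T0:
            raise ValueError(f"T={T_K} K <= T0={self.T0} K: VFT undefined")
        tau = 10.0 ** self.log10_tau0 * np.exp(self.B / (T_K - self.T0))
        if self.D_P is not None and self.P0_MPa is not None and P_MPa > 0:
            if P_MPa >= self.P0_MPa:
                raise ValueError("P >= P0: pressure-VFT undefined")
            tau *= np.exp(self.D_P * P_MPa / (self.P0_MPa - P_MPa))
        return float(tau)

    def strength(self, T_K: float) -> float:
        return max(self.delta_eps + self.delta_eps_slope * (T_K - 300.0), 1e-6)

    def hn(self, T_K: float, P_MPa: float = 0.0) -> HNProcess:
        return HNProcess(
            delta_eps=self.strength(T_K),
            tau_hn=self.tau(T_K, P_MPa),
            m=self.m,
            n=self.n,
            name=self.name,
        )


@dataclass
class DielectricScenario:
    """Stated world of one dielectric measurement campaign."""

    processes: list[ProcessSpec]
    eps_inf: float = 3.0
    sigma0_S_m: float = 1e-12       # dc conductivity at 300 K
    sigma0_Ea_K: float = 6000.0     # Arrhenius activation (in K) of sigma0
    T_grid_K: tuple[float, ...] = (300.0,)
    P_grid_MPa: tuple[float, ...] = (0.0,)
    f_grid_Hz: np.ndarray = field(
        default_factory=lambda: np.logspace(-2, 7, 46)
    )
    noise: float = 0.0              # relative (multiplicative Gaussian) sigma
    seed: int = 0
    sample: str = "synthetic"

    def sigma0(self, T_K: float) -> float:
        return self.sigma0_S_m * np.exp(-self.sigma0_Ea_K * (1.0 / T_K - 1.0 / 300.0))


def gen_dielectric(scenario: DielectricScenario) -> list[MeasurementSeries]:
    """Generate eps*(f) series for every (T, P) with attached ground truth."""
    if len(scenario.f_grid_Hz) == 0 or not scenario.T_grid_K:
        raise ValueError("empty grid")
    rng = np.random.default_rng(scenario.seed)
    out = []
    omega = 2.0 * np.pi * np.asarray(scenario.f_grid_Hz, dtype=float)
    for T in scenario.T_grid_K:
        for P in scenario.P_grid_MPa:
            procs = [p.hn(T, P) for p in scenario.processes]
            sig = scenario.sigma0(T)
            eps1, eps2 = hn_loss_real(omega, procs, scenario.eps_inf, sig)
            if scenario.noise > 0:
                eps1 = eps1 * (1.0 + scenario.noise * rng.standard_normal(len(eps1)))
                eps2 = eps2 * (1.0 + scenario.noise * rng.standard_normal(len(eps2)))
                eps2 = np.clip(eps2, 1e-12, None)
            truth = {
                "eps_inf": scenario.eps_inf,
                "sigma0_S_m": sig,
                "processes": [
                    {
                        "name": p.name,
                        "delta_eps": p.delta_eps,
                        "tau_hn_s": p.tau_hn,
                        "tau_max_s": p.tau_max,
                        "m": p.m,
                        "n": p.n,
                    }
                    for p in procs
                ],
            }
            out.append(
                MeasurementSeries(
                    x=np.asarray(scenario.f_grid_Hz, dtype=float),
                    y=eps1 + 1j * eps2,
                    technique="dielectric",
                    meta={
                        "temperature_K": float(T),
                        "pressure_MPa": float(P),
                        "sample": scenario.sample,
                        "truth": truth,
                    },
                )
            )
    return out


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------
@dataclass
class DSCScenario:
    """Two logistic glass steps on a linear baseline.

    Step widths are quoted as the fwhm of the resulting dc_p/dT peak; the
    logistic scale is w_fwhm / (4 * arccosh(sqrt(2))) so the derivative peak
    has exactly that fwhm.
    """

    steps: tuple[tuple[float, float, float], ...] = (
        (281.0, 8.0, 0.062),   # (Tg K, derivative-peak fwhm K, delta_cp J/g/K)
        (312.0, 8.0, 0.038),
    )
    baseline: tuple[float, float] = (1.2, 1.5e-3)  # cp = a + b*(T-230)
    # 0.1 K sampling: TM-DSC software emits a dense interpolated trace
    T_grid_K: np.ndarray = field(
        default_factory=lambda: np.arange(230.0, 350.0, 0.1)
    )
    modulation_period_s: float = 40.0
    noise: float = 0.0
    seed: int = 0
    sample: str = "synthetic"


_SECH2_FWHM = 4.0 * np.arccosh(np.sqrt(2.0))  # fwhm of d/dx logistic(x)


def gen_dsc(scenario: DSCScenario) -> MeasurementSeries:
    """Reversing-c_p trace with two glass steps and attached truth."""
    tgs = [s[0] for s in scenario.steps]
    if len(set(tgs)) != len(tgs):
        raise ValueError("glass steps must have distinct Tg values")
    rng = np.random.default_rng(scenario.seed)
    T = np.asarray(scenario.T_grid_K, dtype=float)
    a, b = scenario.baseline
    cp = a + b * (T - T[0])
    for tg, fwhm, dcp in scenario.steps:
        w = fwhm / _SECH2_FWHM
        cp = cp + dcp / (1.0 + np.exp(-(T - tg) / w))
    if scenario.noise > 0:
        cp = cp * (1.0 + scenario.noise * rng.standard_normal(len(cp)))
    total = sum(s[2] for s in scenario.steps)
    truth = {
        "steps": [
            {"Tg_K": tg, "fwhm_K": fw, "delta_cp": dc, "fraction": dc / total}
            for tg, fw, dc in scenario.steps
        ],
        "baseline": list(scenario.baseline),
    }
    return MeasurementSeries(
        x=T,
        y=cp,
        technique="dsc",
        meta={
            "modulation_period_s": scenario.modulation_period_s,
            "sample": scenario.sample,
            "truth": truth,
        },
    )


# ---------------------------------------------------------------------------
# WAXS
# ---------------------------------------------------------------------------
@dataclass
class WAXSScenario:
    """Bragg peaks over an amorphous halo and polynomial background.

    ``hexagonal=True`` emits (11) and (20) satellites of the hex10 peak at
    q0*sqrt(3) and q0*sqrt(4) with reduced intensity.
    """

    peaks: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "hex10": (4.7, 0.35, 60.0),          # (q0 nm^-1, fwhm, area)
            "beta_lamellar": (3.7, 0.40, 40.0),
            "pitch": (12.6, 0.25, 12.0),
        }
    )
    hexagonal: bool = True
    satellite_ratio: tuple[float, float] = (0.30, 0.18)
    halo: tuple[float, float, float] = (14.0, 4.5, 120.0)
    background: tuple[float, ...] = (2.0, -0.05)  # polyval coeffs in (q - 10)
    q_grid: np.ndarray = field(default_factory=lambda: np.arange(2.0, 20.0, 0.02))
    eta: float = 0.5
    noise: float = 0.0
    seed: int = 0
    sample: str = "synthetic"


def gen_waxs(scenario: WAXSScenario) -> MeasurementSeries:
    q = np.asarray(scenario.q_grid, dtype=float)
    peaks = dict(scenario.peaks)
    if scenario.hexagonal and "hex10" in peaks:
        q0, w, area = peaks["hex10"]
        r11, r20 = scenario.satellite_ratio
        peaks.setdefault("hex11", (q0 * np.sqrt(3.0), w * 1.3, area * r11))
        peaks.setdefault("hex20", (q0 * np.sqrt(4.0), w * 1.4, area * r20))
    for role, (q0, w, area) in peaks.items():
        if not (q[0] < q0 < q[-1]):
            raise ValueError(f"peak {role!r} at q0={q0} outside the grid")
        if w <= 0 or area <= 0:
            raise ValueError(f"peak {role!r} needs positive width and area")
    rng = np.random.default_rng(scenario.seed)
    y = np.polyval(scenario.background, q - 10.0)
    for q0, w, area in peaks.values():
        y = y + pseudo_voigt(q, q0, w, area, scenario.eta)
    hc, hw, ha = scenario.halo
    y = y + pseudo_voigt(q, hc, hw, ha, scenario.eta)
    if scenario.noise > 0:
        y = y * (1.0 + scenario.noise * rng.standard_normal(len(y)))
    truth = {
        "peaks": {r: {"q0": p[0], "fwhm": p[1], "area": p[2]} for r, p in peaks.items()},
        "halo": {"q0": hc, "fwhm": hw, "area": ha},
    }
    return MeasurementSeries(
        x=q, y=y, technique="waxs",
        meta={"sample": scenario.sample, "truth": truth},
    )


# ---------------------------------------------------------------------------
# NMR
# ---------------------------------------------------------------------------
@dataclass
class NMRScenario:
    """Cα-region 13C spectrum as Gaussian resonances."""

    resonances: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "alpha": (58.0, 1.8, 0.56),      # (ppm, fwhm, area)
            "beta": (53.0, 1.8, 0.34),
            "chain_end": (49.0, 1.5, 0.10),
        }
    )
    ppm_grid: np.ndarray = field(default_factory=lambda: np.arange(40.0, 70.0, 0.05))
    noise: float = 0.0
    seed: int = 0
    sample: str = "synthetic"


def gen_nmr(scenario: NMRScenario) -> MeasurementSeries:
    x = np.asarray(scenario.ppm_grid, dtype=float)
    rng = np.random.default_rng(scenario.seed)
    y = np.zeros_like(x)
    for name, (c, w, a) in scenario.resonances.items():
        if not (x[0] < c < x[-1]):
            raise ValueError(f"resonance {name!r} at {c} ppm outside the grid")
        sig = w / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y = y + a * np.exp(-0.5 * ((x - c) / sig) ** 2) / (sig * np.sqrt(2.0 * np.pi))
    if scenario.noise > 0:
        y = y + scenario.noise * y.max() * rng.standard_normal(len(y))
    truth = {
        "resonances": {
            r: {"ppm": p[0], "fwhm": p[1], "area": p[2]}
            for r, p in scenario.resonances.items()
        }
    }
    return MeasurementSeries(
        x=x, y=y, technique="nmr",
        meta={"sample": scenario.sample, "truth": truth},
    )


# ---------------------------------------------------------------------------
# rheology
# ---------------------------------------------------------------------------
@dataclass
class RheoScenario:
    """Thermorheologically simple G*(ω, T) with an elastic plateau.

    Master model at Tref (ω in rad/s):

        G*(ω) = G_N0 (iωτ_d)^c/(1+(iωτ_d)^c)
                + (G_g - G_N0)(iωτ_g)^p/(1+(iωτ_g)^p) + i ω η_hf

    The slow (domain) mode produces the terminal rise of the phase angle
    below the plateau; the half-exponent (p = 0.5) glassy ramp climbs to the
    glassy modulus while keeping tan δ <= 1 (so G' > G'' everywhere, the
    universal observation on these peptides); the small viscous floor η_hf
    turns δ back up past the glassy dispersion so the vGP curve shows both
    the plateau-region and the glassy-region δ-minima.  Per-temperature
    sweeps are the master function evaluated at a_T*ω with true WLF a_T.
    """

    G_N0_Pa: float = 2e5
    G_glass_Pa: float = 1e9
    tau_domain_s: float = 3e3
    tau_glass_s: float = 2.3e-7
    c_domain: float = 0.5
    p_glass: float = 0.5
    eta_hf_Pas: float = 0.2
    C1: float = 10.5
    C2: float = 75.0
    Tref_K: float = 343.0
    T_grid_K: tuple[float, ...] = (
        313.0, 318.0, 323.0, 333.0, 343.0, 353.0, 363.0, 373.0
    )
    omega_window: tuple[float, float] = (1e-1, 1e2)
    n_per_decade: int = 7
    noise: float = 0.0
    seed: int = 0
    sample: str = "synthetic"

    def master(self, omega: np.ndarray) -> np.ndarray:
        iw_d = (1j * omega * self.tau_domain_s) ** self.c_domain
        iw_g = (1j * omega * self.tau_glass_s) ** self.p_glass
        return (
            self.G_N0_Pa * iw_d / (1.0 + iw_d)
            + (self.G_glass_Pa - self.G_N0_Pa) * iw_g / (1.0 + iw_g)
            + 1j * omega * self.eta_hf_Pas
        )


def gen_rheo(scenario: RheoScenario) -> list[MeasurementSeries]:
    """Per-temperature frequency sweeps from the shifted master function."""
    if scenario.Tref_K not in scenario.T_grid_K:
        raise ValueError("Tref must be one of the sweep temperatures")
    rng = np.random.default_rng(scenario.seed)
    lo, hi = np.log10(scenario.omega_window[0]), np.log10(scenario.omega_window[1])
    npts = int((hi - lo) * scenario.n_per_decade) + 1
    omega = np.logspace(lo, hi, npts)
    out = []
    for T in scenario.T_grid_K:
        log_at = float(wlf_log_aT(T, scenario.C1, scenario.C2, scenario.Tref_K))
        g = scenario.master(omega * 10.0 ** log_at)
        g1, g2 = g.real, g.imag
        if scenario.noise > 0:
            g1 = g1 * (1.0 + scenario.noise * rng.standard_normal(len(g1)))
            g2 = g2 * (1.0 + scenario.noise * rng.standard_normal(len(g2)))
        truth = {
            "G_N0_Pa": scenario.G_N0_Pa,
            "C1": scenario.C1,
            "C2": scenario.C2,
            "Tref_K": scenario.Tref_K,
            "log_aT": log_at,
        }
        out.append(
            MeasurementSeries(
                x=omega,
                y=np.clip(g1, 1e-6, None) + 1j * np.clip(g2, 1e-9, None),
                technique="rheo",
                meta={
                    "temperature_K": float(T),
                    "sample": scenario.sample,
                    "truth": truth,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# preset library: the measured sample series, parameters from the study's
# tabulated VFT constants and secondary-structure fractions
# ---------------------------------------------------------------------------
def _dielectric_preset(
    sample: str,
    alpha: tuple[float, float, float],
    alpha_star: tuple[float, float, float] | None,
    de_alpha: float = 2.0,
    de_alpha_star: float = 4.0,
) -> DielectricScenario:
    procs = [
        ProcessSpec("alpha", de_alpha, alpha[0], alpha[1], alpha[2],
                    m=0.85, n=0.7, D_P=4.0, P0_MPa=1600.0)
    ]
    if alpha_star is not None:
        procs.append(
            ProcessSpec("alpha*", de_alpha_star, alpha_star[0], alpha_star[1],
                        alpha_star[2], m=0.75, n=0.6, D_P=2.5, P0_MPa=2400.0)
        )
    return DielectricScenario(
        processes=procs,
        T_grid_K=tuple(np.arange(310.0, 361.0, 5.0)),
        sample=sample,
    )


PRESETS: dict[str, dict] = {
    # fractions (DSC 62:38) and VFT rows follow the tabulated sample values
    "PBLG_7": {
        "dielectric": _dielectric_preset("PBLG_7", (-13.2, 1710.0, 230.0),
                                         (-12.0, 1735.0, 262.0)),
        # DSC step Tg values sit on the preset's own VFT lines at the
        # TM-DSC probe time P/(2 pi) so the cross-technique map is coherent
        "dsc": DSCScenario(
            steps=((283.0, 8.0, 0.062), (320.8, 8.0, 0.038)),
            sample="PBLG_7",
        ),
        "waxs": WAXSScenario(
            peaks={
                "hex10": (4.7, 0.35, 60.0),
                "beta_lamellar": (3.7, 0.40, 40.0),
                "pitch": (12.6, 0.25, 10.0),
            },
            sample="PBLG_7",
        ),
        "nmr": NMRScenario(sample="PBLG_7"),
        "rheo": RheoScenario(G_N0_Pa=2e5, sample="PBLG_7"),
    },
    "PBLG_7_nhexyl": {
        "dielectric": _dielectric_preset("PBLG_7_nhexyl", (-12.0, 1250.0, 238.0),
                                         (-12.0, 1760.0, 245.0)),
        "dsc": DSCScenario(
            steps=((280.4, 8.0, 0.036), (304.7, 8.0, 0.064)),
            sample="PBLG_7_nhexyl",
        ),
        # beta-only pattern: no hexagonal reflections at all
        "waxs": WAXSScenario(
            peaks={
                "beta_lamellar": (3.7, 0.45, 70.0),
                "beta_interstrand": (13.4, 0.40, 25.0),
            },
            hexagonal=False,
            sample="PBLG_7_nhexyl",
        ),
        "nmr": NMRScenario(
            resonances={
                "alpha": (58.0, 1.8, 0.19),
                "beta": (53.0, 1.8, 0.66),
                "chain_end": (49.0, 1.5, 0.15),
            },
            sample="PBLG_7_nhexyl",
        ),
        "rheo": RheoScenario(G_N0_Pa=1e7, G_glass_Pa=2e9, tau_domain_s=30.0,
                             tau_glass_s=2e-9, sample="PBLG_7_nhexyl"),
    },
    "PBLG_14": {
        "dielectric": _dielectric_preset("PBLG_14", (-12.0, 1280.0, 244.0),
                                         (-12.0, 1980.0, 260.0)),
        "dsc": DSCScenario(
            steps=((287.4, 8.0, 0.065), (327.2, 9.0, 0.035)),
            sample="PBLG_14",
        ),
        "waxs": WAXSScenario(
            peaks={
                "hex10": (4.7, 0.32, 65.0),
                "beta_lamellar": (3.7, 0.42, 35.0),
                "pitch": (12.6, 0.25, 10.0),
            },
            sample="PBLG_14",
        ),
        "nmr": NMRScenario(
            resonances={
                "alpha": (58.0, 1.8, 0.79),
                "beta": (53.0, 1.8, 0.16),
                "chain_end": (49.0, 1.5, 0.05),
            },
            sample="PBLG_14",
        ),
        "rheo": RheoScenario(G_N0_Pa=1e6, tau_domain_s=300.0, tau_glass_s=1e-8,
                             sample="PBLG_14"),
    },
    "PBLG_100": {
        "dielectric": _dielectric_preset("PBLG_100", (-12.0, 1240.0, 247.0), None),
        "dsc": DSCScenario(steps=((289.1, 8.0, 0.10),), sample="PBLG_100"),
        "waxs": WAXSScenario(
            peaks={
                "hex10": (4.7, 0.25, 90.0),
                "pitch": (12.6, 0.20, 18.0),
            },
            sample="PBLG_100",
        ),
        "nmr": NMRScenario(
            resonances={
                "alpha": (58.0, 1.6, 0.97),
                "beta": (53.0, 1.8, 0.02),
                "chain_end": (49.0, 1.5, 0.01),
            },
            sample="PBLG_100",
        ),
        "rheo": RheoScenario(G_N0_Pa=7e6, G_glass_Pa=2e9, tau_domain_s=30.0,
                             tau_glass_s=2e-9, sample="PBLG_100"),
    },
}


def preset(sample: str, technique: str, seed: int | None = None):
    """A deep copy of one preset scenario, optionally reseeded."""
    try:
        sc = copy.deepcopy(PRESETS[sample][technique])
    except KeyError as exc:
        raise KeyError(f"no preset for sample={sample!r} technique={technique!r}") from exc
    if seed is not None:
        sc.seed = seed
    return sc
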