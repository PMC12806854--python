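"""Multi-technique pipeline: generate, fit per probe, map, summarize.

The pipeline runs the per-technique analyses in dependency order on either
synthetic preset data or user-supplied series files, records every fit's
convergence status, and emits one JSON document per stage plus a combined
summary table (per sample: Tg_alpha, Tg_alpha_star, m*, f_alpha, f_beta,
L_alpha, L_beta, G_N0, M_e, N_e, d_mesh).  A stage failure is recorded and
its dependents are skipped — never silently defaulted.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .dielectric import HavriliakNegamiModel, tau_max
from .pressure import tait_density
from .relaxmap import VFTModel, tmdsc_tau, vft_derived
from .rheology import build_master_curve, plateau_derived, vgp_minima, WLFModel
from .series import MeasurementSeries, read_series
from .synthetic import PRESETS, gen_dielectric, gen_dsc, gen_nmr, gen_rheo, gen_waxs, preset
from .thermal import TwoTgModel, cp_derivative
from .nmr import CalphaModel
from .waxs import WAXSPatternModel, fractions_from_intensities, peak_geometry

__all__ = ["RunConfig", "run_pipeline", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"
log = logging.getLogger("pepdyn")

_STAGES = ("dielectric", "dsc", "waxs", "nmr", "rheo", "map")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "dielectric": {"objective": "loss+real", "fit_conductivity": True},
    "dsc": {"window": 101, "split_K": 300.0},
    "waxs": {"background_degree": 2},
    "nmr": {},
    "rheo": {"Tref_K": 343.0, "allow_vertical": False},
    "map": {"fix_log10_tau0": None, "tau_ref_s": 100.0},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with per-stage option blocks."""

    seed: int = 0
    samples: tuple[str, ...] = ("PBLG_7",)
    stages: tuple[str, ...] = _STAGES
    noise: float = 0.005
    input_dir: str | None = None  # read series files instead of generating
    options: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for st in self.stages:
            if st not in _STAGES:
                raise ValueError(f"unknown stage {st!r}; valid: {_STAGES}")
        for st, block in self.options.items():
            if st not in _DEFAULTS:
                raise ValueError(f"unknown option block {st!r}")
            unknown = set(block) - set(_DEFAULTS[st])
            if unknown:
                raise ValueError(f"unknown keys in {st!r} block: {sorted(unknown)}")
        if self.input_dir is None:
            for s in self.samples:
                if s not in PRESETS:
                    raise ValueError(f"unknown preset sample {s!r}")

    def opt(self, stage: str) -> dict[str, Any]:
        merged = dict(_DEFAULTS[stage])
        merged.update(self.options.get(stage, {}))
        return merged

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        known = {"seed", "samples", "stages", "noise", "input_dir"}
        top = {k: d.pop(k) for k in list(d) if k in known}
        options = d  # everything else must be a stage block (validated above)
        if "samples" in top:
            top["samples"] = tuple(top["samples"])
        if "stages" in top:
            top["stages"] = tuple(top["stages"])
        return cls(options=options, **top)


def _stage_seed(base: int, sample: str, stage: str) -> int:
    # stable across processes (builtin hash is salted per run)
    h = zlib.crc32(f"{sample}/{stage}".encode()) % 100003
    return (base * 1009 + h) % (2**31 - 1)


# ---------------------------------------------------------------------------
# per-stage analyses
# ---------------------------------------------------------------------------
def _fit_dielectric(series_list: list[MeasurementSeries], opts: dict) -> dict:
    results = []
    for s in series_list:
        n_truth = len(s.meta.get("truth", {}).get("processes", [])) or 2
        model = HavriliakNegamiModel(
            s,
            n_processes=min(n_truth, 3),
            fit_conductivity=opts["fit_conductivity"],
            objective=opts["objective"],
        )
        fit = model.fit()
        results.append(
            {
                "temperature_K": s.temperature,
                "pressure_MPa": s.pressure,
                "f_window_Hz": [float(s.x[0]), float(s.x[-1])],
                "converged": fit.converged,
                "eps_inf": fit.eps_inf,
                "sigma0_S_m": fit.sigma0,
                "processes": [
                    {
                        "name": p.name,
                        "delta_eps": p.delta_eps,
                        "tau_hn_s": p.tau_hn,
                        "tau_max_s": tau_max(p),
                        "m": p.m,
                        "n": p.n,
                    }
                    for p in fit.processes
                ],
                "unresolved": fit.unresolved,
                "degenerate": fit.degenerate,
            }
        )
        log.info("dielectric fit T=%.0fK converged=%s", s.temperature, fit.converged)
    return {"spectra": results}


def _fit_dsc(trace: MeasurementSeries, opts: dict) -> dict:
    deriv = cp_derivative(trace, window=opts["window"])
    fit = TwoTgModel(deriv, split_K=opts["split_K"]).fit()
    out: dict[str, Any] = {
        "converged": fit.converged,
        "single_tg": fit.single_tg,
        "modulation_period_s": trace.meta.get("modulation_period_s"),
        "tau_tmdsc_s": tmdsc_tau(float(trace.meta.get("modulation_period_s", 40.0))),
    }
    out["Tg_low_K"] = fit.low.center if fit.low else None
    out["Tg_high_K"] = fit.high.center if fit.high else None
    if fit.fractions is not None:
        out["f_alpha"] = fit.fractions.f_alpha
        out["f_beta"] = fit.fractions.f_beta
    return out


def _fit_waxs(pattern: MeasurementSeries, opts: dict) -> dict:
    fit = WAXSPatternModel(pattern, background_degree=opts["background_degree"]).fit()
    peaks = {}
    for p in fit.peaks:
        peaks[p.role] = {
            "q0_nm^-1": p.q0,
            "fwhm_nm^-1": p.component.fwhm,
            "area": p.component.area,
            **peak_geometry(p),
        }
    out: dict[str, Any] = {
        "converged": fit.converged,
        "peaks": peaks,
        "absent_roles": fit.absent_roles,
    }
    try:
        fr = fractions_from_intensities(fit, sample=str(pattern.meta.get("sample", "")))
        out["f_alpha"] = fr.f_alpha
        out["f_beta"] = fr.f_beta
    except ValueError as exc:
        out["fractions_error"] = str(exc)
    return out


def _fit_nmr(spectrum: MeasurementSeries, opts: dict) -> dict:
    fit = CalphaModel(spectrum).fit()
    return {
        "converged": fit.converged,
        "f_alpha": fit.fractions_chain_end_in_beta.f_alpha,
        "f_beta_incl_chain_ends": fit.fractions_chain_end_in_beta.f_beta,
        "f_beta": fit.f_beta,
        "f_chain_end": fit.f_chain_end,
        "components": {
            k: {"center_ppm": c.center, "fwhm_ppm": c.fwhm, "area": c.area}
            for k, c in fit.components.items()
        },
    }


def _fit_rheo(sweeps: list[MeasurementSeries], opts: dict) -> dict:
    mc = build_master_curve(sweeps, Tref=opts["Tref_K"],
                            allow_vertical=opts["allow_vertical"])
    wlf = WLFModel(mc.log_aT, mc.temperatures, mc.Tref).fit()
    vgp = vgp_minima(mc.G1, mc.G2)
    out: dict[str, Any] = {
        "Tref_K": mc.Tref,
        "log_aT": dict(zip(map(str, mc.temperatures), mc.log_aT)),
        "WLF": {"C1": wlf.C1, "C2": wlf.C2, "converged": wlf.converged},
        "vgp_minima": vgp.minima,
    }
    if vgp.plateau is not None:
        g_n0 = vgp.plateau["G_at_min_Pa"]
        rho = float(tait_density(mc.Tref - 273.15, 0.0))
        out["G_N0_Pa"] = g_n0
        out["rho_g_cm3"] = rho
        out.update(plateau_derived(g_n0, rho, mc.Tref))
    return out


def _fit_map(ds_result: dict, dsc_result: dict | None, opts: dict) -> dict:
    """VFT fits per dielectric process; TM-DSC points merged when available."""
    by_name: dict[str, list[tuple[float, float]]] = {}
    for spec_fit in ds_result["spectra"]:
        if not spec_fit["converged"] or spec_fit["degenerate"]:
            continue
        f_lo, f_hi = spec_fit["f_window_Hz"]
        tau_lo, tau_hi = 1.0 / (2 * np.pi * f_hi), 1.0 / (2 * np.pi * f_lo)
        for p in spec_fit["processes"]:
            if p["name"] in spec_fit["unresolved"]:
                continue  # tau_max left the measured window; not a map point
            if not (tau_lo <= p["tau_max_s"] <= tau_hi):
                continue  # loss peak itself outside the window: extrapolation
            by_name.setdefault(p["name"], []).append(
                (spec_fit["temperature_K"], p["tau_max_s"])
            )
    out: dict[str, Any] = {"processes": {}}
    for name, pts in by_name.items():
        T = np.array([p[0] for p in pts])
        tau = np.array([p[1] for p in pts])
        if dsc_result is not None and not dsc_result.get("single_tg", True):
            # merge the TM-DSC point (Tg_DSC, P/2pi) into the matching map
            tg_key = "Tg_low_K" if name == "alpha" else "Tg_high_K"
            tg = dsc_result.get(tg_key)
            if tg is not None:
                T = np.append(T, tg)
                tau = np.append(tau, dsc_result["tau_tmdsc_s"])
        try:
            fit = VFTModel(tau, T, fix_log10_tau0=opts["fix_log10_tau0"]).fit()
            der = vft_derived(fit.log10_tau0, fit.B, fit.T0, opts["tau_ref_s"])
            out["processes"][name] = {
                "converged": fit.converged,
                "log10_tau0": fit.log10_tau0,
                "B_K": fit.B,
                "T0_K": fit.T0,
                "Tg_K": der.Tg_K,
                "fragility_mstar": der.fragility_mstar,
                "n_points": len(T),
            }
        except ValueError as exc:
            out["processes"][name] = {"error": str(exc)}
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------
def _load_inputs(config: RunConfig, sample: str) -> dict[str, Any]:
    """Either generate preset scenarios or read series files for one sample."""
    if config.input_dir is not None:
        root = Path(config.input_dir) / sample
        data: dict[str, Any] = {}
        ds = sorted(root.glob("dielectric_*.csv"))
        if ds:
            data["dielectric"] = [read_series(p) for p in ds]
        for tech in ("dsc", "waxs", "nmr"):
            p = root / f"{tech}.csv"
            if p.exists():
                data[tech] = read_series(p)
        rh = sorted(root.glob("rheo_*.csv"))
        if rh:
            data["rheo"] = [read_series(p) for p in rh]
        return data

    data = {}
    for tech, gen in (
        ("dielectric", gen_dielectric),
        ("dsc", gen_dsc),
        ("waxs", gen_waxs),
        ("nmr", gen_nmr),
        ("rheo", gen_rheo),
    ):
        try:
            sc = preset(sample, tech, seed=_stage_seed(config.seed, sample, tech))
        except KeyError:
            continue
        sc.noise = config.noise
        data[tech] = gen(sc)
    return data


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the requested stages for every sample; optionally write JSON."""
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "samples": {},
    }
    for sample in config.samples:
        data = _load_inputs(config, sample)
        sres: dict[str, Any] = {}
        failed: set[str] = set()

        def _run(stage: str, fn, *args):
            if stage not in config.stages:
                return
            try:
                sres[stage] = fn(*args)
            except Exception as exc:  # recorded, dependents skipped
                log.warning("%s/%s failed: %s", sample, stage, exc)
                sres[stage] = {"error": str(exc)}
                failed.add(stage)

        if "dielectric" in config.stages and "dielectric" in data:
            _run("dielectric", _fit_dielectric, data["dielectric"],
                 config.opt("dielectric"))
        if "dsc" in config.stages and "dsc" in data:
            _run("dsc", _fit_dsc, data["dsc"], config.opt("dsc"))
        if "waxs" in config.stages and "waxs" in data:
            _run("waxs", _fit_waxs, data["waxs"], config.opt("waxs"))
        if "nmr" in config.stages and "nmr" in data:
            _run("nmr", _fit_nmr, data["nmr"], config.opt("nmr"))
        if "rheo" in config.stages and "rheo" in data:
            _run("rheo", _fit_rheo, data["rheo"], config.opt("rheo"))
        if "map" in config.stages:
            if "dielectric" in sres and "dielectric" not in failed:
                _run("map", _fit_map, sres["dielectric"], sres.get("dsc"),
                     config.opt("map"))
            else:
                sres["map"] = {"skipped": "dielectric stage missing or failed"}
        report["samples"][sample] = sres

    report["summary"] = _summary_table(report["samples"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample, sres in report["samples"].items():
            for stage, payload in sres.items():
                doc = {"schema_version": SCHEMA_VERSION, "sample": sample,
                       "stage": stage, "result": payload}
                (out / f"{sample}_{stage}.json").write_text(
                    json.dumps(doc, indent=1, sort_keys=True, default=float)
                )
        (out / "summary.json").write_text(
            json.dumps({"schema_version": SCHEMA_VERSION,
                        "summary": report["summary"]},
                       indent=1, sort_keys=True, default=float)
        )
    return report


def _summary_table(samples: dict[str, dict]) -> dict[str, dict]:
    table: dict[str, dict] = {}
    for sample, sres in samples.items():
        row: dict[str, Any] = {}
        mp = sres.get("map", {}).get("processes", {})
        if "alpha" in mp and "error" not in mp["alpha"]:
            row["Tg_alpha_K"] = mp["alpha"]["Tg_K"]
            row["mstar_alpha"] = mp["alpha"]["fragility_mstar"]
        if "alpha*" in mp and "error" not in mp["alpha*"]:
            row["Tg_alpha_star_K"] = mp["alpha*"]["Tg_K"]
            row["mstar_alpha_star"] = mp["alpha*"]["fragility_mstar"]
        dsc = sres.get("dsc", {})
        if "f_alpha" in dsc:
            row["f_alpha_DSC"] = dsc["f_alpha"]
            row["f_beta_DSC"] = dsc["f_beta"]
        wx = sres.get("waxs", {})
        if "f_alpha" in wx:
            row["f_alpha_WAXS"] = wx["f_alpha"]
            row["f_beta_WAXS"] = wx["f_beta"]
        pk = wx.get("peaks", {})
        if "hex10" in pk:
            row["L_alpha_nm"] = pk["hex10"]["L_nm"]
        if "beta_lamellar" in pk:
            row["L_beta_nm"] = pk["beta_lamellar"]["L_nm"]
        rh = sres.get("rheo", {})
        for k in ("G_N0_Pa", "M_e_g_mol", "N_e", "d_mesh_nm"):
            if k in rh:
                row[k] = rh[k]
        table[sample] = row
    return table
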