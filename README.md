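# pepdyn

Multi-probe analysis of α-helix and β-sheet dynamics in synthetic
polypeptides such as poly(γ-benzyl-L-glutamate) (PBLG).

Short PBLG chains stabilize both secondary structures at once: amorphous
segments interrupting the α-helices relax as a segmental **α process**, the
more constrained disordered segments inside β-sheet regions as a slower
**α\* process**, and at long times the **macrodipoles** of whole helices
(axial) and sheets (perpendicular) relax as "slow" processes.  `pepdyn`
implements the full analysis chain that turns raw 1-D instrument curves into
these quantities, for five probes:

| probe | input | extracted |
|---|---|---|
| dielectric spectroscopy | ε′, ε″(f) at (T, P) | Havriliak–Negami deconvolution, τ_max, Δε, σ₀ |
| relaxation mapping | τ(T), τ(P) | VFT / pressure-VFT fits, T_g, fragility m\*, activation volume ΔV<sup>#</sup>, T_g(P) |
| TM-DSC | reversing c_p(T) | two-Lorentzian dc_p/dT deconvolution → two T_g's, f_α/f_β |
| WAXS | I(q) | Bragg peaks, hexagonal lattice constant, coherence lengths, f_α/f_β, f(n) sigmoids |
| ¹³C solid-state NMR | I(ppm), dipolar couplings | Cα deconvolution → absolute fractions, order parameter S |
| rheology | G′, G″(ω, T) | tTs master curves, WLF, van Gurp–Palmen minima, G_N⁰ → M_e, N_e, mesh size |

A synthetic-data module generates every input with known ground truth, so
the whole chain is testable without instrument files.

## Core relations

Dielectric spectra are modelled as (ε₀ the vacuum permittivity)

    ε*(ω) = ε∞ + Σ_k Δε_k / [1 + (iωτ_k)^m_k]^n_k + σ₀/(iε₀ω),
    τ_max = τ_HN [ sin(πmn/(2(1+n))) / sin(πm/(2(1+n))) ]^(1/m),

segmental times follow the Vogel–Fulcher–Tammann law τ = τ₀ exp[B/(T−T₀)]
with T_g defined by τ(T_g) = 100 s and fragility
m\* = B·T_g / (2.303 (T_g−T₀)²); under pressure
f_max = f∞ exp[−D_P·P/(P₀−P)] and ΔV<sup>#</sup> = 2.303·R·T (∂log τ/∂P)_T.
Secondary-structure fractions come from component areas
(f_α = A_α/(A_α+A_β)); WAXS geometry uses d = 2π/q, a_hex = 4π/(√3 q),
L = 2π/fwhm.  The plateau modulus converts to mesh parameters via
M_e = 4ρRT_ref/(5G_N⁰) and d_mesh = (k_B T_ref/G_N⁰)^{1/3}.

## Worked example

```python
from pepdyn import HavriliakNegamiModel, VFTModel, vft_derived
from pepdyn.synthetic import preset, gen_dielectric

spectra = gen_dielectric(preset("PBLG_7", "dielectric", seed=1))
fit = HavriliakNegamiModel(spectra[4], n_processes=2).fit()
print(fit.summary())
```

prints (abbreviated):

```
SpectrumFitResults
  converged: True  residual norm: 1.324e-09  n: 92
  parameter             estimate       std err
  log10_delta_eps_0       0.30103      3.88e-11
  log10_tau_hn_0        -5.77356      2.83e-10
  ...
  processes (by ascending tau_max): alpha: tau_max=1.18e-06s d_eps=2, alpha*: tau_max=0.066s d_eps=4
```

i.e. at 330 K the amorphous-segment α process relaxes in ~1.2 µs while the
β-sheet-associated α\* process needs ~66 ms — nearly five decades slower at
the same temperature, the signature of the constrained sheet environment.
Feeding the τ_max(T) sets into `VFTModel(...).fit()` and `vft_derived`
yields the two glass temperatures (here 279 K and 316 K) and fragilities.

The same analyses run as a pipeline over all probes:

```bash
pepdyn run --seed 1 --sample PBLG_7 --out results/
```

which writes one JSON document per stage plus `summary.json` with, per
sample: Tg(α), Tg(α*), m*, f_α/f_β per probe, coherence lengths, G_N⁰, M_e,
N_e and the mesh size.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch and at run time, the
headline published values: the four tabulated glass temperatures obtained
by re-fitting VFT relaxation maps synthesized from the tabulated (τ₀, B,
T₀) rows; the hexagonal intercylinder distance from the 4.7 nm⁻¹ Bragg
peak; and the number of repeat units per elastic strand from the printed
plateau moduli with the Tait equation-of-state density at 343 K.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
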