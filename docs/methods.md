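# Methods

This note documents the models implemented in `pepdyn`, the choices made
where the underlying methodology leaves freedom, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Dielectric deconvolution

Permittivity spectra are fitted with a sum of 1–3 Havriliak–Negami (HN)
processes plus a dc-conductivity term,

    ε*(ω) = ε∞ + Σ_k Δε_k / [1 + (iωτ_HN,k)^m_k]^n_k + σ₀/(iε₀ω),

with the shape bounds 0.2 < m ≤ 1 and 0 < m·n ≤ 1 enforced at construction.
The conductivity exponent is fixed at 1 (pure dc).  The loss-peak time is
the closed form

    τ_max = τ_HN [ sin(πmn/(2(1+n))) / sin(πm/(2(1+n))) ]^(1/m),

whose printed typography is ambiguous in parts of the literature; the
convention used here is pinned by a test that maximizes ε″ on a dense grid
(< 0.5 % discrepancy over random admissible shapes).  A corollary the same
oracle fixes: τ_max *increases* with n at fixed (m, τ_HN) — stronger
asymmetric broadening (smaller n) pushes the loss peak to higher frequency.

**Objective.** ε″ alone carries no information about ε∞, so the default
objective is a joint residual: log₁₀ ε″ (equal weight per decade) plus the
scaled ε′ residual.  Two alternatives are selectable: `"loss"` (pure
log-loss, the historical convention) and `"derivative"`, which targets the
conduction-free derivative loss ε″_deriv = −(π/2)·dε′/dln ω.  In the
derivative objective the model's ε′ is differentiated by the *same*
Savitzky–Golay filter as the data, so the smoothing bias cancels in the
residual instead of biasing the parameters.

**Initialization and identity.** Process time constants are seeded from
peaks of the derivative loss; after fitting, processes are sorted by
ascending τ_max and labelled (α, α*, slow).  A fit is flagged *degenerate*
when a component's Δε falls below 3 % of the total or two components land
within 0.3 decades of each other; a process whose fitted τ_max leaves the
measured window by more than one decade is reported *unresolved*.  The
relaxation-map builder is stricter: it accepts only loss peaks that lie
strictly inside the measured frequency window, and skips degenerate fits
entirely.  Both rules exist because a two-process fit applied at a
temperature where one process has left the window will otherwise invent an
in-window surrogate for it.

## Relaxation maps, Tg and fragility

τ(T) sets are fitted with the VFT law log₁₀τ = log₁₀τ₀ + B/(ln10·(T−T₀)),
optionally with τ₀ held at the high-temperature-limit convention (10⁻¹²
or 10⁻¹⁴ s).  Derived quantities:

* T_g = T₀ + B/ln(τ_ref/τ₀), with τ_ref = 100 s for ambient-pressure maps
  and 10 s for pressure work (both exposed);
* fragility m\* = B·T_g/(2.303·(T_g−T₀)²), which collapses to
  log₁₀(τ_ref/τ₀) in the Arrhenius (T₀→0) limit.

TM-DSC points enter the same map as (T_g^DSC, P/2π) pairs.  Preconditions:
at least 4 points spanning at least 2 decades in τ; violations raise rather
than fit.

## Pressure domain

Isothermal f_max(P) sets use the pressure-VFT form
f = f∞·exp(−D_P·P/(P₀−P)) with a log-linear (Arrhenius-in-P) fallback for
the weakly pressure-dependent macrodipole processes.  The apparent
activation volume ΔV<sup>#</sup> = 2.303·R·T·(∂log₁₀τ/∂P)_T is evaluated
with the closed form R·T·D_P·P₀/(P₀−P)², verified against the numerical
derivative to < 0.1 %; with P in MPa, J mol⁻¹ MPa⁻¹ is numerically
cm³ mol⁻¹.  Because the analysis never measures near P₀, P₀ itself is
weakly identified (about −5 % median bias at 1 % frequency scatter over a
0–300 MPa window); ΔV<sup>#</sup>, which depends on the local slope, is far
better determined.  ΔV<sup>#</sup> is emitted both at P→0 and at
mid-window pressure, since either convention appears in practice.

Density under pressure comes from the Tait equation of state with the PBLG
melt constants (A₀ = 0.788 cm³ g⁻¹, A₁ = 4.92·10⁻⁴, A₂ = 7.57·10⁻⁷,
B₀ = 142 MPa, B₁ = 4.3·10⁻³; temperatures in °C inside this module only,
converted at the boundary).  T_g(P) is fitted with
T_g(P) = T_g(0)(1 + (ν/μ)P)^{1/ν}, free positive ν and μ, initial guesses
ν = 3, μ = 1500 MPa; the initial slope (dT_g/dP)_{P→0} = T_g(0)/μ is
reported in K GPa⁻¹.

## TM-DSC deconvolution

The reversing c_p trace is differentiated by Savitzky–Golay filtering
(default window 10 K at the generator's 0.1 K sampling, order 3) and the
derivative fitted with two Lorentzians plus a linear background (the
background is a config option; the methodology source is silent on it).
The lower-T_g component is assigned to α (helix-interrupting amorphous
segments), the higher to α* (sheet-associated), and
f_α = A_low/(A_low+A_high).

Two estimator choices depart from the naive implementation, both forced by
recovery experiments on the synthetic worlds:

* **Center initialization** uses the two tallest prominent maxima of an
  extra-smoothed derivative, with a fixed 300 K split only as fallback.  A
  fixed split mis-initializes samples whose both peaks fall on one side of
  it (the n-hexyl heptamer world has peaks at 278 and 296 K).
* **Shared width** (default `equal_width=True`): the two Lorentzians share
  one fwhm.  The two glass steps of one material have similar breadths,
  and with free widths the Lorentzian-tail/area trade-off at 0.5 % trace
  noise destabilizes the fraction estimate (median error ≈ 0.03 instead of
  ≈ 0.015).  Free widths remain available.

A result is flagged *single-Tg* when the smaller component's area is below
1 % of the total, when a component sits within its own width of the trace
edge, or when the two centers are closer than one linewidth — all three
are ways a one-step trace defeats a forced two-component fit.

## WAXS

Patterns are fitted jointly as a degree-2 polynomial background, a broad
pseudo-Voigt amorphous halo near 14 nm⁻¹, and pseudo-Voigt Bragg peaks
(η = 0.5 by default).  Peaks are *detected* first (prominence threshold
inside each role window: β-lamellar ≈ 3.7, hex(10) ≈ 4.7, hex(11), hex(20),
helix pitch ≈ 12.6, β-interstrand ≈ 13.4 nm⁻¹); roles with no detected
maximum are reported absent rather than force-fitted, which is what makes a
β-only pattern report the hexagonal family as missing.  Geometry is exact:
d = 2π/q₀, a_hex = 4π/(√3·q₀), L = 2π/fwhm with no instrumental-broadening
correction.  Relative fractions use the primary peak of each family
(hex(10) vs β-lamellar), satellites and halo excluded; both choices are
configurable.  Chain-length laws use the generalized sigmoid
f(n) = A − (A−B)e^{−(kn)^d}; the β-sheet branch uses a negative shape
exponent d, which makes the curve *flat then decaying* — it is implemented
exactly in that form and the fitted d is sign-constrained per branch.

## NMR

The Cα region is deconvoluted into three Gaussians (α-helix ≈ 58, β-sheet
≈ 53, chain-end ≈ 49 ppm) plus a flat baseline; Gaussian is the default
line shape for MAS solid-state spectra, pseudo-Voigt available through the
shared component type.  Fractions are dual-reported: with the chain-end
area counted into β (the tabulation convention) and separately, since the
convention shifts f by several percent.  The order parameter is the exact
ratio S = ⟨D_CH⟩/D_CH,static, errors out if the motionally averaged
coupling exceeds the static one, and is never rounded internally — with
D_static = 22.7 kHz, D = 19.7 kHz gives S = 0.868 (a published rounding to
0.88 is not reproduced because the reference coupling actually used there
is not stated).

## Macrodipole model

The defected-helix picture treats an α-helix as ideal helical stretches of
correlation length ξ carrying μ = 3.4 D·(ξ/0.15 nm), each reorienting on a
cone of half-angle θ.  The strength formula

    Δε = g·F · N_A·ρ/(3ε₀k_B·T·M₀) · (3.4 D)² · (ξ/0.15 nm) · sin²θ

is linear in ξ (one factor of ξ from μ², one inverse factor from the
number density of stretches) and is inverted exactly.  θ must come from
oriented-fiber scattering and is a required input (default 20° with a
warning in presets); g·F defaults to 1, matching the bare model, and is
exposed for the Kirkwood–Fröhlich/local-field corrected form.  Strength
ratios Δε_slow/Δε_segmental are classified by configurable bands:
sheet-like around 2, helix-like around 4, mixed above ≈ 5.

## Rheology

Master curves are built pairwise outward from T_ref, minimizing the squared
log|G*| mismatch over the overlap window; sweeps are processed in
temperature order so the result is independent of input order, and a pair
whose best alignment still misfits (RMS > 0.1 decades) raises with the gap
named.  Vertical shifts b_T default off.  WLF constants come from
log₁₀a_T = −C₁(T−T_ref)/(C₂+T−T_ref); the identities B = C₁C₂·ln10 and
T₀ = T_ref − C₂ connect them to the VFT parameters and are verified
numerically in the tests.

The van Gurp–Palmen curve δ(|G*|) is lightly smoothed (5-point window) and
local minima located; at most two are reported, the lower-|G*| one read as
the plateau (its modulus is the G_N⁰ estimate) and the higher as the glassy
minimum.  G_N⁰ converts to M_e = 4ρRT_ref/(5G_N⁰) with ρ from the Tait EOS
at T_ref (the density convention that reproduces the published repeat-unit
counts), N_e = M_e/M₀ with M₀ = 219.2 g mol⁻¹, and the mesh size
d = (k_B·T_ref/G_N⁰)^{1/3} from the fluctuation form with ω_cτ = 1
(implemented exactly as printed; its provenance is not derived here).

## Synthetic worlds

Each generator emits exactly the structure its analysis assumes, plus
multiplicative Gaussian noise (instrument responses span decades, so
relative noise is the right model) and a machine-readable truth record:

* **Dielectric**: HN sums with τ(T) on VFT lines, τ(P) on pressure-VFT
  lines, Arrhenius σ₀(T); default 46-point 10⁻²–10⁷ Hz grid.
* **DSC**: logistic glass steps on a linear baseline (c_p ≈ 1.2 J g⁻¹ K⁻¹);
  the step-width parameter is quoted as the fwhm of the resulting dc_p/dT
  peak.  Sampling is 0.1 K — TM-DSC software emits dense traces — which at
  0.5 % noise is what makes the ±0.02 fraction-recovery target attainable;
  a coarser 0.5 K world fails it for reasons of derivative SNR, not of the
  estimator.
* **WAXS**: pseudo-Voigt peaks; hexagonal scenarios auto-emit (11) and (20)
  satellites at q₀√3 and q₀√4.  **NMR**: Gaussian resonances.
* **Rheology**: a two-mode master function — a slow "domain" mode that
  produces the terminal rise of δ below the plateau, and a half-exponent
  (p = 0.5) Cole–Cole glassy ramp.  p = 0.5 is a deliberate choice: it
  keeps tan δ ≤ 1 identically, reproducing the solid-like G′ > G″ observed
  across all samples, while still reaching the glassy modulus.  A small
  viscous floor (iωη, η = 0.2 Pa s) turns δ back up past the glassy
  dispersion so both vGP minima exist inside the reduced-frequency window.
  Sweeps are the master function at a_T·ω with true WLF shifts
  (C₁ = 10.5, C₂ = 75 K, T_ref = 343 K, eight temperatures 313–373 K).

**Preset library.**  Presets named after the sample series carry the
tabulated VFT rows, fraction splits (62:38, 36:64, β-only, pure-α) and
plateau moduli (2·10⁵–10⁷ Pa).  Two self-consistency constructions are
deliberate: (i) each preset's DSC step temperatures sit on its own VFT
line at τ = P/2π, because the measured data show inter-probe T_g offsets of
up to ~14 K that would make ground-truth recovery impossible if transcribed
verbatim — this offset is therefore a real-data feature the synthetic world
does **not** emulate; (ii) in the heptamer preset the rheology glassy time
equals the dielectric α time at T_ref, mirroring the observed agreement
between mechanical and dielectric segmental timescales.

**What a green test establishes.**  Recovery tests prove the estimators
return the truth of *this* world at the stated noise; they do not establish
robustness to baseline drifts, electrode polarization, preferred
orientation in powder patterns, spinning sidebands, or thermorheological
complexity — none of which the generators produce.

## Numerical conventions

All fits run through bounded `scipy.optimize.least_squares`
(`lmfit`-style parameter handling was not available in the target
environment); standard errors come from s²(JᵀJ)⁻¹ with the pseudo-inverse,
so rank-deficient fits report large finite errors instead of raising, and
every Results object carries an explicit `converged` flag.  Canonical units
are Hz, K, MPa, Pa, nm⁻¹, ppm, s; all conversions happen at the I/O
boundary (the single exception is °C inside the Tait module, whose printed
constants demand it).  Series files are comment-annotated CSV, lossless to
12+ significant digits; pipeline JSON is written with sorted keys so runs
with equal config and seed are byte-identical.

## Known limitations

* Electrode polarization, Maxwell–Wagner relaxations and Kramers–Kronig
  transforms are out of scope; conductivity is pure dc.
* The coherence length uses the raw fitted fwhm (no Scherrer shape factor,
  no instrumental broadening).
* Only the empirical T_g(P) power law is implemented — no other
  super-Arrhenius or pressure parameterizations.
* The CO-region (172/176 ppm) of the ¹³C spectra is not quantified by
  default.
* β-sheet macrodipole moments are not computed from residue dipoles; only
  the strength-ratio classification covers sheets.
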